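import numpy as np
import pytest

from apescan.alignment import CodonAlignment
from apescan.codonmodel import uniform_frequencies
from apescan.simulate import SimulationSpec, simulate_codon_alignment
from apescan.trees import LabeledTree, great_ape_tree


@pytest.fixture(scope="session")
def ape_tree():
    return great_ape_tree()


@pytest.fixture(scope="session")
def three_taxon_tree():
    """Rooted trifurcation over 3 tips — small enough for brute force."""
    return LabeledTree(
        taxa=("a", "b", "c"),
        parent=(3, 3, 3, -1),
        lengths=(0.2, 0.3, 0.5, 0.0),
        branch_names={"a": 0, "b": 1, "c": 2},
        foreground=frozenset({"a"}),
    )


@pytest.fixture(scope="session")
def tiny_alignment():
    return CodonAlignment.from_strings({
        "a": "ATGAAATTT",
        "b": "ATGAAGTTC",
        "c": "ATGCCCTTT",
    })


@pytest.fixture(scope="session")
def uniform_pi():
    return uniform_frequencies()


@pytest.fixture(scope="session")
def selected_alignment(ape_tree):
    """One alignment simulated with strong selection on the human branch."""
    spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                          n_codons=200, omega2=8.0, seed=101)
    return simulate_codon_alignment(spec)
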