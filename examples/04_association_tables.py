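"""Reproduce the reference association tables with the exact Fisher test.

The 2×2 counts are the published per-branch PSG × multigene-family
tables (and the PSG × disease table) from the 14,397-ortholog great-ape
scan; the one-sided upper-tail p-values are recomputed here exactly.
"""

from apescan.association import ContingencyTable2x2, fisher_upper_tail, round3

multigene = {
    "H. sapiens": (23, 10793, 16, 3565),
    "P. troglodytes": (33, 10783, 7, 3574),
    "Hominini": (10, 10806, 1, 3580),
    "G. gorilla": (25, 10791, 6, 3575),
    "Homininae": (28, 10788, 11, 3570),
    "P. abelii": (23, 10793, 11, 3570),
    "Hominidae": (14, 10802, 6, 3575),
}
print(f"{'lineage':<16} {'PSG/multi':>10} {'PSG/single':>10} {'p':>7}")
for lineage, (a, b, c, d) in multigene.items():
    p = fisher_upper_tail(ContingencyTable2x2(a=a, b=b, c=c, d=d)).pvalue
    print(f"{lineage:<16} {a:>10} {c:>10} {round3(p):>7}")

a, b, c, d = 6, 33, 2690, 11668
p = fisher_upper_tail(ContingencyTable2x2(a=a, b=b, c=c, d=d)).pvalue
print(f"\ndisease genes among PSGs: {a}/{a + b} "
      f"(proportion {round3(a / (a + b))}); "
      f"among non-PSGs {c}/{c + d} (proportion {round3(c / (c + d))}); "
      f"one-sided p = {round3(p)}")
# large p-values mean no significant enrichment: PSGs are not
# over-represented in multigene families, nor among disease genes.
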