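"""Signed RSc quantitation on a toy two-sample count table.

RSc = (s_test + c)(T_ref - s_ref + c) / ((s_ref + c)(T_test - s_test + c))
with c = 1.25; values below 1 are reported as their negative inverse, so
+2 means two-fold up in the test sample and -2 two-fold up in the
reference. The pseudo-count keeps ratios finite for proteins seen in only
one sample.
"""

from spectracount import ProteinGroup, QuantConfig, compute_rsc, quantify_pair, summarize_partition

print("RSc(10 vs 5 spectra, totals 1000):",
      round(compute_rsc(10, 5, 1000, 1000), 4))
print("RSc(0 vs 20 spectra, totals 500):",
      round(compute_rsc(0, 20, 500, 500), 4), "(negative inverse branch)")


def group(protein, sample, count):
    return ProteinGroup(protein, frozenset({f"{protein}AK", f"{protein}CK"}),
                        {sample: count})


groups_a = [group("P1", "A", 10), group("P3", "A", 4)]
groups_b = [group("P1", "B", 40), group("P2", "B", 6), group("P3", "B", 4)]
for r in quantify_pair(groups_a, groups_b, QuantConfig()):
    print(f"{r.protein}: s_A={r.s_a} s_B={r.s_b} "
          f"RSc={r.rsc_signed:+.4f} -> {r.partition}")
print(summarize_partition(quantify_pair(groups_a, groups_b)))
# P2 is unique to B; P3's ratio 0.238 becomes -4.2, i.e. 4.2-fold down in B.
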