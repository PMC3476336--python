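"""How read depth and cross-sample dispersion set CNV detection power.

For a single-exon heterozygous deletion at reference:test ratio 10, the
expected posterior is swept over test depth in three dispersion regimes:
Rs = 1 (no technical noise), 1.6 (well-matched batch) and 2.5 (poorly
matched batch).  Dispersion is calibrated at 100 test reads and held
fixed along the sweep, so the curves show what extra depth alone buys.
"""

import numpy as np

from bbcnv.power import PowerScenario, hom_del_threshold, power_curve

sweep = np.arange(50, 501, 50)
print("expected posterior of a single-exon het deletion (ratio 10):")
print("reads:", "  ".join(f"{v:>6d}" for v in sweep))
for rs in (1.0, 1.6, 2.5):
    sc = PowerScenario(rs_target=rs, ref_test_ratio=10.0, test_reads=100.0)
    curve = power_curve(sc, values=sweep)
    row = "  ".join(f"{v:6.3f}" for v in curve.expected_posterior)
    print(f"Rs={rs:<4}", row)

print()
print("with no technical noise, ~300 reads give essentially certain "
      "detection; at Rs=2.5 no realistic depth helps (the posterior "
      "plateaus far below certainty).")

sc = PowerScenario(rs_target=1.6, cnv_type="hom-del")
thr = hom_del_threshold(sc, epsilon=0.01)
print(f"\nhomozygous deletion (background mapping 1%): detectable from "
      f"~{thr} expected test reads per exon")
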