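"""H-scores and exact paired statistics.

The H-score summarizes IHC staining as sum(intensity x percent cells),
0-300.  Small paired cohorts need exact tests: the signed-rank p comes
from full enumeration of the sign-flip null.
"""

from icipair import IntensityProfile, PairedSeries, delta_h, fisher_exact, h_score, paired_wilcoxon

profile = IntensityProfile(pct0=20, pct1=0, pct2=50, pct3=30)
print(f"H-score for 50% 2+ / 30% 3+ staining: {h_score(profile):.0f}")

absolute, percent = delta_h(pre=190.0, post=0.0)
print(f"abolished expression: {absolute:+.0f} absolute, {percent:+.0f}% change")

# six patients, HLA-I expression dropping in every one
hla = PairedSeries(pre=[300, 280, 250, 300, 230, 290], post=[230, 200, 180, 250, 150, 240])
p = paired_wilcoxon(hla)
print(f"uniform drop in n=6 pairs: exact two-sided p = {p:.5f} (2/2^6)")

# association between a stratum and an acquired event, 2x2 exact
p_assoc = fisher_exact(7, 5, 2, 17)
print(f"7/12 vs 2/19 event-positive: Fisher exact p = {p_assoc:.4f}")
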