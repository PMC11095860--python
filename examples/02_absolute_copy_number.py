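"""Purity-corrected absolute copy number from segmented log2 ratios.

A tumor at purity p carrying ACN copies of a gene produces a segment log2
ratio l = log2((p*ACN + 2(1-p))/2); the caller inverts this:
ACN = (2^(l+1) - 2(1-p)) / p.  At l = 0 purity cancels and ACN = 2.
"""

from icipair import Segment, absolute_copy_number, classify_acn, weighted_gene_log2

# three segments overlapping a gene at chr1:1,000-4,000
segments = [
    Segment("chr1", 1, 1000, 1.0),      # 1,000 bp at log2 = 1.0
    Segment("chr1", 1001, 4000, 0.0),   # 3,000 bp at log2 = 0.0
]
gene = ("chr1", 1, 4000)

l = weighted_gene_log2(segments, gene)
print(f"weighted gene log2 ratio : {l:.4f}")   # (1000*1 + 3000*0)/4000 = 0.25

for purity in (0.3, 0.5, 0.8):
    acn = absolute_copy_number(l, purity)
    print(f"purity {purity:.1f} -> ACN {acn:.3f} ({classify_acn(max(acn, 0.0))})")
# The same observed ratio implies a higher tumor copy number at lower
# purity: normal cells dilute the signal.

print(f"l=1.0, p=0.5 -> ACN {absolute_copy_number(1.0, 0.5):.1f} (hand check: (4-1)/0.5 = 6)")
print(f"l=0.0 is diploid at any purity: {absolute_copy_number(0.0, 0.37):.1f}")
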