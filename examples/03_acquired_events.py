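"""Call acquired alterations between matched pre/post biopsies.

An alteration is acquired when present post-treatment and absent
pre-treatment; an acquired mutation plus an acquired copy loss of the
same gene marks biallelic inactivation.
"""

from icipair import EventKey, PairedCase, SampleProfile, Variant, call_acquired, summarize
from icipair.copy_number import AcnCall

b2m_mut = EventKey("B2M", "SNV", "p.E94*")
kras = EventKey("KRAS", "SNV", "p.G12C")  # baseline driver, both samples

pre = SampleProfile(
    "pt1_pre", "pre",
    variants=[Variant(kras)],
    acn_calls=[AcnCall("B2M", 0.0, 0.6, 2.0, 2.0, "neutral")],
)
post = SampleProfile(
    "pt1_post", "post",
    variants=[Variant(kras), Variant(b2m_mut, functional_class="LOF")],
    acn_calls=[AcnCall("B2M", -0.35, 0.6, 1.0, 1.0, "heterozygous-deletion")],
)
pair = PairedCase("pt1", pre, post, therapy_category="ICI-mono",
                  best_response="PR", time_to_ar_months=11.0)

for finding in call_acquired(pair):
    print(f"{finding.gene:6s} {finding.finding_type:18s} biallelic={finding.biallelic}")
# B2M gains both a nonsense mutation and a heterozygous loss after
# therapy -> biallelic inactivation, the antigen-presentation escape
# pattern; the baseline KRAS driver is not reported (present in both).

summary = summarize([pair])
print(f"pairs with any acquired change: {summary['pct_with_any_change']}% "
      f"(of {summary['n_pairs']})")
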