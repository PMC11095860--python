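"""Acquired-alteration calling between matched pairs and the cohort
summaries / stratified tests built on it."""

import numpy as np
import pytest

from icipair.acquired import (
    PairedCase,
    SampleProfile,
    Variant,
    call_acquired,
    filter_variants,
    findings_frame,
    lost_events,
    oncoprint_matrix,
    stratify,
    summarize,
)
from icipair.copy_number import AcnCall, classify_acn
from icipair.lineage import EventKey

ACN_FOR_CATEGORY = {
    "neutral": 2.0,
    "heterozygous-deletion": 1.0,
    "homozygous-deletion": 0.2,
    "gain": 3.5,
    "high-amplification": 8.0,
}


def acn(gene, category):
    value = ACN_FOR_CATEGORY[category]
    assert classify_acn(value) == category
    return AcnCall(gene=gene, l=0.0, purity=0.5, acn_raw=value, acn=value,
                  category=category)


def profile(sample_id, timepoint, variants=(), acn_calls=()):
    return SampleProfile(
        sample_id=sample_id, timepoint=timepoint,
        variants=[Variant(e) if isinstance(e, EventKey) else e for e in variants],
        acn_calls=list(acn_calls),
    )


def pair(patient="P1", pre_variants=(), post_variants=(), pre_acn=(), post_acn=(),
         therapy="ICI-mono", time_to_ar=8.0, response="PR"):
    return PairedCase(
        patient_id=patient,
        pre=profile(f"{patient}_pre", "pre", pre_variants, pre_acn),
        post=profile(f"{patient}_post", "post", post_variants, post_acn),
        therapy_category=therapy, best_response=response,
        time_to_ar_months=time_to_ar,
    )


STK11_FS = EventKey("STK11", "indel", "p.K78fs")
B2M_NONSENSE = EventKey("B2M", "SNV", "p.E94*")
KRAS_G12C = EventKey("KRAS", "SNV", "p.G12C")


class TestFilterVariants:
    def test_chip_flag_removed(self):
        variants = [Variant(STK11_FS), Variant(KRAS_G12C, chip=True)]
        assert filter_variants(variants) == [Variant(STK11_FS)]

    def test_all_clean_identity(self):
        variants = [Variant(STK11_FS), Variant(KRAS_G12C)]
        assert filter_variants(variants) == variants

    def test_counts(self):
        variants = (
            [Variant(EventKey(f"G{i}", "SNV", f"p.A{i}T")) for i in range(6)]
            + [Variant(EventKey(f"B{i}", "SNV", "p.B1T"), benign=True) for i in range(3)]
            + [Variant(EventKey("C1", "SNV", "p.C1T"), chip=True)]
        )
        assert len(filter_variants(variants)) == 6


class TestCallAcquired:
    def test_unchanged_variant_not_acquired(self):
        p = pair(pre_variants=[STK11_FS], post_variants=[STK11_FS])
        assert call_acquired(p) == []

    def test_identical_profiles_no_findings(self):
        calls = [acn("B2M", "heterozygous-deletion"), acn("KRAS", "neutral")]
        p = pair(pre_variants=[STK11_FS], post_variants=[STK11_FS],
                 pre_acn=calls, post_acn=calls)
        assert call_acquired(p) == []

    def test_biallelic_b2m_mutation_plus_loss(self):
        p = pair(
            post_variants=[B2M_NONSENSE],
            pre_acn=[acn("B2M", "neutral")],
            post_acn=[acn("B2M", "heterozygous-deletion")],
        )
        findings = call_acquired(p)
        assert len(findings) == 2
        assert {f.finding_type for f in findings} == {"mutation", "heterozygous-loss"}
        assert all(f.biallelic for f in findings)

    def test_acquired_amplification_from_category_change(self):
        p = pair(pre_acn=[acn("KRAS", "neutral")],
                 post_acn=[acn("KRAS", "high-amplification")])
        findings = call_acquired(p)
        assert [f.finding_type for f in findings] == ["amplification"]
        assert findings[0].acn_call.acn == 8.0

    def test_het_to_hom_deletion_qualifies(self):
        p = pair(pre_acn=[acn("CDKN2A", "heterozygous-deletion")],
                 post_acn=[acn("CDKN2A", "homozygous-deletion")])
        assert [f.finding_type for f in call_acquired(p)] == ["homozygous-deletion"]

    def test_return_to_neutral_not_acquired(self):
        p = pair(pre_acn=[acn("PTEN", "heterozygous-deletion")],
                 post_acn=[acn("PTEN", "neutral")])
        assert call_acquired(p) == []

    def test_mutation_without_loss_not_biallelic(self):
        p = pair(post_variants=[STK11_FS],
                 pre_acn=[acn("STK11", "neutral")], post_acn=[acn("STK11", "neutral")])
        findings = call_acquired(p)
        assert len(findings) == 1 and not findings[0].biallelic

    def test_adding_event_preserves_existing_findings(self):
        base = pair(post_variants=[STK11_FS])
        more = pair(post_variants=[STK11_FS, B2M_NONSENSE])
        genes_base = {(f.gene, f.finding_type) for f in call_acquired(base)}
        genes_more = {(f.gene, f.finding_type) for f in call_acquired(more)}
        assert genes_base <= genes_more

    def test_reversions_reported_separately(self):
        p = pair(pre_variants=[STK11_FS, KRAS_G12C], post_variants=[KRAS_G12C])
        assert call_acquired(p) == []
        assert lost_events(p) == [STK11_FS]


class TestSummarize:
    def _toy_cohort(self, n=79, n_mut=22, n_cna=39, n_any=49, n_b2m=5):
        """Cohort with prescribed counts: pairs 0..n_mut-1 carry an
        acquired mutation (first n_b2m in B2M), CNAs overlap so that
        exactly n_any pairs have >= 1 change of any kind."""
        cna_start = n_any - n_cna
        cases = []
        for i in range(n):
            post_variants = []
            pre_acn, post_acn = [], []
            if i < n_mut:
                gene_event = B2M_NONSENSE if i < n_b2m else STK11_FS
                post_variants.append(gene_event)
            if cna_start <= i < cna_start + n_cna:
                pre_acn.append(acn("KEAP1", "neutral"))
                post_acn.append(acn("KEAP1", "heterozygous-deletion"))
            cases.append(pair(patient=f"P{i:03d}", post_variants=post_variants,
                              pre_acn=pre_acn, post_acn=post_acn))
        return cases

    def test_printed_percentage_identities(self):
        summary = summarize(self._toy_cohort())
        assert summary["n_pairs"] == 79
        assert summary["pct_with_any_change"] == 62.0
        assert summary["pct_with_acquired_mutation"] == 27.8
        assert summary["pct_with_acquired_cna"] == 49.4
        b2m = summary["gene_table"].query("gene == 'B2M' and finding_type == 'mutation'")
        assert float(b2m["frequency_pct"].iloc[0]) == 6.3

    def test_any_change_dominates_components(self):
        summary = summarize(self._toy_cohort())
        assert summary["pct_with_any_change"] >= max(
            summary["pct_with_acquired_mutation"], summary["pct_with_acquired_cna"]
        )

    def test_zero_findings(self):
        cases = [pair(patient=f"P{i}") for i in range(10)]
        summary = summarize(cases)
        assert summary["pct_with_any_change"] == 0.0
        assert summary["gene_table"].empty

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_patient_counted_once_per_gene_per_type(self):
        p = pair(post_variants=[B2M_NONSENSE, EventKey("B2M", "SNV", "p.E36D")])
        summary = summarize([p])
        row = summary["gene_table"].query("gene == 'B2M' and finding_type == 'mutation'")
        assert int(row["n_patients"].iloc[0]) == 1


class TestStratify:
    def test_no_association_balanced(self):
        cases = []
        for i in range(10):
            time = 4.0 if i < 5 else 8.0
            post = [STK11_FS] if i % 5 < 2 else []
            cases.append(pair(patient=f"P{i}", post_variants=post, time_to_ar=time))
        out = stratify(cases, by="time_to_ar", time_cutoff_months=6.0)
        mut = out["tests"].query("level == 'category' and outcome == 'mutation'")
        assert float(mut["fisher_p"].iloc[0]) == pytest.approx(1.0)

    def test_separated_strata_exact_p(self):
        # 5/10 vs 0/10 events: p from hypergeometric enumeration = 0.0325
        cases = []
        for i in range(20):
            time = 8.0 if i < 10 else 4.0
            post = [STK11_FS] if (i < 5) else []
            cases.append(pair(patient=f"P{i}", post_variants=post, time_to_ar=time))
        out = stratify(cases, by="time_to_ar")
        mut = out["tests"].query("level == 'category' and outcome == 'mutation'")
        from .test_ihc import enumerate_fisher_p
        assert float(mut["fisher_p"].iloc[0]) == pytest.approx(
            enumerate_fisher_p(5, 5, 0, 10), abs=1e-10
        )

    def test_single_stratum_no_tests(self):
        cases = [pair(patient=f"P{i}", time_to_ar=8.0) for i in range(5)]
        out = stratify(cases, by="time_to_ar", time_cutoff_months=6.0)
        assert len(out["strata"]) == 1

    def test_missing_stratum_variable_excluded(self):
        cases = [pair(patient=f"P{i}") for i in range(4)]
        out = stratify(cases, by="pd_l1_tps_bin")
        assert out["n_excluded_missing"] == 4


class TestReportingArtifacts:
    def test_findings_frame_columns(self):
        p = pair(post_variants=[B2M_NONSENSE],
                 pre_acn=[acn("B2M", "neutral")],
                 post_acn=[acn("B2M", "heterozygous-deletion")])
        df = findings_frame([p])
        assert set(df["finding_type"]) == {"mutation", "heterozygous-loss"}
        assert df["biallelic"].all()

    def test_oncoprint_biallelic_coding(self):
        p = pair(post_variants=[B2M_NONSENSE],
                 pre_acn=[acn("B2M", "neutral")],
                 post_acn=[acn("B2M", "heterozygous-deletion")])
        mat = oncoprint_matrix([p])
        assert mat.loc["B2M", "P1"] == "biallelic"

    def test_time_to_ar_floor_enforced(self):
        with pytest.raises(ValueError):
            pair(time_to_ar=2.0)
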