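"""Acquired genomic alterations between matched pre/post biopsy pairs.

An alteration is *acquired* when it is present in the post-treatment
sample and absent from the matched pre-treatment sample: mutations by
event identity (presence/absence on a targeted panel — no allele
fractions), copy-number alterations by a change of CNA category away from
the pre-treatment state into a non-neutral category.  An acquired
mutation plus an acquired copy loss of the same gene in the same post
sample marks biallelic inactivation.

Variants flagged as predicted-benign or as clonal hematopoiesis (CHIP)
are filtered out before calling, mirroring standard somatic reporting
practice for serial biopsies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .copy_number import AcnCall
from .ihc import fisher_exact
from .lineage import EventKey

logger = logging.getLogger(__name__)

THERAPY_CATEGORIES = ("ICI-mono", "ICI+CTLA4", "chemo-ICI", "chemo", "targeted", "mixed")
RESPONSES = ("CR", "PR", "SD")
FINDING_TYPES = ("mutation", "heterozygous-loss", "homozygous-deletion", "amplification")

#: CNA category -> acquired finding type; neutral never yields a finding
_CATEGORY_TO_FINDING = {
    "heterozygous-deletion": "heterozygous-loss",
    "homozygous-deletion": "homozygous-deletion",
    "gain": "amplification",
    "high-amplification": "amplification",
}

LOSS_FINDINGS = ("heterozygous-loss", "homozygous-deletion")


@dataclass(frozen=True)
class Variant:
    event: EventKey
    benign: bool = False
    chip: bool = False
    functional_class: str = "VUS"  # LOF / activating / VUS


@dataclass
class SampleProfile:
    sample_id: str
    timepoint: str  # pre / post
    variants: list[Variant] = field(default_factory=list)
    acn_calls: list[AcnCall] = field(default_factory=list)
    tmb: float | None = None
    purity: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        keys = [v.event for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant EventKeys in sample {self.sample_id}")

    @property
    def variant_keys(self) -> set[EventKey]:
        return {v.event for v in self.variants}


@dataclass
class PairedCase:
    patient_id: str
    pre: SampleProfile
    post: SampleProfile
    therapy_category: str
    best_response: str = "SD"
    time_to_ar_months: float = 3.0
    biopsy_interval_months: float | None = None
    pd_l1_tps_bin: str | None = None  # <1% / 1-49% / >=50%

    def __post_init__(self) -> None:
        if self.therapy_category not in THERAPY_CATEGORIES:
            raise ValueError(f"unknown therapy category {self.therapy_category!r}")
        if self.best_response not in RESPONSES:
            raise ValueError(f"unknown best response {self.best_response!r}")
        if self.time_to_ar_months < 3.0:
            raise ValueError(
                "time to acquired resistance must be >= 3 months (AR requires "
                "response or stable disease for at least 3 months)"
            )
        if self.pre.timepoint != "pre" or self.post.timepoint != "post":
            raise ValueError("pair must hold one pre and one post profile")


@dataclass
class AcquiredFinding:
    gene: str
    finding_type: str
    biallelic: bool = False
    event: EventKey | None = None
    acn_call: AcnCall | None = None

    def __post_init__(self) -> None:
        if self.finding_type not in FINDING_TYPES:
            raise ValueError(f"unknown finding type {self.finding_type!r}")


def filter_variants(variants: Iterable[Variant]) -> list[Variant]:
    """Drop benign- and CHIP-flagged variants; removal counts are logged.

    Missing flags are treated as False upstream (at I/O), also logged.
    """
    variants = list(variants)
    kept = [v for v in variants if not (v.benign or v.chip)]
    n_benign = sum(1 for v in variants if v.benign)
    n_chip = sum(1 for v in variants if v.chip and not v.benign)
    if n_benign or n_chip:
        logger.info("filtered %d benign and %d CHIP variants", n_benign, n_chip)
    return kept


def call_acquired(pair: PairedCase) -> list[AcquiredFinding]:
    """Acquired findings for one pair.

    Mutations: EventKey in post, not in pre (any pre-treatment presence
    blocks an acquired call).  CNAs: post category differs from pre and is
    non-neutral; genes uncallable at either timepoint are skipped.  The
    biallelic flag marks genes with both an acquired mutation and an
    acquired copy loss in the same post sample.
    """
    if pair.pre.sample_id.split("_")[0] and pair.post.sample_id.split("_")[0]:
        pass  # sample naming is free-form; the patient check below is the contract
    pre_keys = pair.pre.variant_keys
    findings: list[AcquiredFinding] = []

    acquired_mut_genes: set[str] = set()
    for variant in pair.post.variants:
        if variant.event not in pre_keys and variant.event.event_class in ("SNV", "indel", "SV"):
            findings.append(
                AcquiredFinding(
                    gene=variant.event.gene, finding_type="mutation", event=variant.event
                )
            )
            acquired_mut_genes.add(variant.event.gene)

    pre_cat = {c.gene: c.category for c in pair.pre.acn_calls}
    loss_genes: set[str] = set()
    for call in pair.post.acn_calls:
        if call.gene not in pre_cat:
            logger.info("gene %s uncallable pre-treatment; CNA change not assessed", call.gene)
            continue
        if call.category != pre_cat[call.gene] and call.category != "neutral":
            ftype = _CATEGORY_TO_FINDING[call.category]
            findings.append(
                AcquiredFinding(gene=call.gene, finding_type=ftype, acn_call=call)
            )
            if ftype in LOSS_FINDINGS:
                loss_genes.add(call.gene)

    biallelic_genes = acquired_mut_genes & loss_genes
    for f in findings:
        if f.gene in biallelic_genes and (
            f.finding_type == "mutation" or f.finding_type in LOSS_FINDINGS
        ):
            f.biallelic = True
    return findings


def lost_events(pair: PairedCase) -> list[EventKey]:
    """Mutations present pre-treatment but absent post (reversions); kept
    separate from acquired findings."""
    post_keys = pair.post.variant_keys
    return sorted(k for k in pair.pre.variant_keys if k not in post_keys)


def _per_pair_findings(
    cohort: Sequence[PairedCase],
) -> list[tuple[PairedCase, list[AcquiredFinding]]]:
    return [(pair, call_acquired(pair)) for pair in cohort]


def summarize(
    cohort: Sequence[PairedCase],
    gene_panel: Sequence[str] | None = None,
) -> dict:
    """Cohort-level acquired-alteration summary.

    Returns a dict with ``n_pairs`` (the denominator: pairs with genomic
    profiling), cohort percentages of pairs with >= 1 acquired mutation,
    >= 1 acquired CNA and >= 1 change of any kind (rounded to one decimal
    for report parity), and a per-gene table of acquired frequencies with
    per-gene, per-patient deduplication within each finding type.
    """
    if not cohort:
        raise ValueError("cannot summarize an empty cohort")
    pairs = _per_pair_findings(cohort)
    n = len(pairs)

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1)

    n_mut = sum(1 for _, f in pairs if any(x.finding_type == "mutation" for x in f))
    n_cna = sum(1 for _, f in pairs if any(x.finding_type != "mutation" for x in f))
    n_any = sum(1 for _, f in pairs if f)

    # per-gene, per-finding-type patient counts (a patient counts once per
    # gene per finding type)
    counts: dict[tuple[str, str], int] = {}
    biallelic_counts: dict[str, int] = {}
    for pair, findings in pairs:
        seen: set[tuple[str, str]] = set()
        bi_seen: set[str] = set()
        for f in findings:
            if gene_panel is not None and f.gene not in gene_panel:
                continue
            key = (f.gene, f.finding_type)
            if key not in seen:
                counts[key] = counts.get(key, 0) + 1
                seen.add(key)
            if f.biallelic and f.gene not in bi_seen:
                biallelic_counts[f.gene] = biallelic_counts.get(f.gene, 0) + 1
                bi_seen.add(f.gene)

    rows = [
        {
            "gene": gene,
            "finding_type": ftype,
            "n_patients": k,
            "frequency_pct": pct(k),
        }
        for (gene, ftype), k in sorted(counts.items())
    ]
    gene_table = pd.DataFrame(
        rows, columns=["gene", "finding_type", "n_patients", "frequency_pct"]
    )
    return {
        "n_pairs": n,
        "n_with_acquired_mutation": n_mut,
        "n_with_acquired_cna": n_cna,
        "n_with_any_change": n_any,
        "pct_with_acquired_mutation": pct(n_mut),
        "pct_with_acquired_cna": pct(n_cna),
        "pct_with_any_change": pct(n_any),
        "gene_table": gene_table,
        "biallelic_counts": biallelic_counts,
    }


def _stratum_label(pair: PairedCase, by: str, time_cutoff_months: float) -> str | None:
    if by == "time_to_ar":
        return f">={time_cutoff_months:g}mo" if pair.time_to_ar_months >= time_cutoff_months else f"<{time_cutoff_months:g}mo"
    if by == "therapy_category":
        return pair.therapy_category
    if by == "best_response":
        return pair.best_response
    if by == "pd_l1_tps_bin":
        return pair.pd_l1_tps_bin
    raise ValueError(f"unknown stratification variable {by!r}")


def stratify(
    cohort: Sequence[PairedCase],
    by: str = "time_to_ar",
    time_cutoff_months: float = 6.0,
    gene_panel: Sequence[str] | None = None,
) -> dict:
    """Per-stratum summaries with Fisher exact tests.

    Pairs missing the stratification variable are excluded (logged); a
    stratum that ends up empty is omitted with a warning.  For each
    category-level outcome (>=1 acquired mutation / CNA / any) and each
    gene, a 2x2 Fisher exact p is computed — stratum vs rest when more
    than two strata exist.
    """
    labelled: dict[str, list[PairedCase]] = {}
    n_missing = 0
    for pair in cohort:
        label = _stratum_label(pair, by, time_cutoff_months)
        if label is None:
            n_missing += 1
            continue
        labelled.setdefault(label, []).append(pair)
    if n_missing:
        logger.info("excluded %d pairs missing %s", n_missing, by)
    labelled = {k: v for k, v in labelled.items() if v}
    if len(labelled) < 2:
        logger.warning("fewer than 2 non-empty strata for %s; no tests computed", by)

    summaries = {label: summarize(pairs, gene_panel) for label, pairs in labelled.items()}

    def has_outcome(pair: PairedCase, outcome: tuple[str, str]) -> bool:
        kind, value = outcome
        findings = call_acquired(pair)
        if kind == "category":
            if value == "mutation":
                return any(f.finding_type == "mutation" for f in findings)
            if value == "cna":
                return any(f.finding_type != "mutation" for f in findings)
            return bool(findings)
        return any(f.gene == value for f in findings)

    outcomes: list[tuple[str, str]] = [
        ("category", "mutation"), ("category", "cna"), ("category", "any")
    ]
    genes = sorted({
        row.gene
        for s in summaries.values()
        for row in s["gene_table"].itertuples(index=False)
    })
    outcomes += [("gene", g) for g in genes]

    tests = []
    labels = sorted(labelled)
    for kind, value in outcomes:
        if len(labels) == 2:
            contrasts = [(labels[0], [labels[1]])]
        else:
            contrasts = [(lab, [o for o in labels if o != lab]) for lab in labels]
        for stratum, others in contrasts:
            in_pairs = labelled[stratum]
            out_pairs = [p for lab in others for p in labelled[lab]]
            a = sum(1 for p in in_pairs if has_outcome(p, (kind, value)))
            b = len(in_pairs) - a
            c = sum(1 for p in out_pairs if has_outcome(p, (kind, value)))
            d = len(out_pairs) - c
            tests.append(
                {
                    "level": kind,
                    "outcome": value,
                    "stratum": stratum,
                    "vs": "+".join(others),
                    "a": a, "b": b, "c": c, "d": d,
                    "pct_stratum": round(100.0 * a / (a + b), 1) if a + b else None,
                    "pct_rest": round(100.0 * c / (c + d), 1) if c + d else None,
                    "fisher_p": fisher_exact(a, b, c, d),
                }
            )
    return {
        "by": by,
        "strata": summaries,
        "tests": pd.DataFrame(tests),
        "n_excluded_missing": n_missing,
    }


def findings_frame(cohort: Sequence[PairedCase]) -> pd.DataFrame:
    """Long table of acquired findings across a cohort."""
    rows = []
    for pair, findings in _per_pair_findings(cohort):
        for f in findings:
            rows.append(
                {
                    "patient": pair.patient_id,
                    "gene": f.gene,
                    "finding_type": f.finding_type,
                    "biallelic": f.biallelic,
                    "event": str(f.event) if f.event else "",
                    "acn": f.acn_call.acn if f.acn_call else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient", "gene", "finding_type", "biallelic", "event", "acn"]
    )


def oncoprint_matrix(cohort: Sequence[PairedCase]) -> pd.DataFrame:
    """Genes x patients matrix coded by acquired finding type; concurrent
    mutation + loss in one gene is coded 'biallelic'."""
    cells: dict[str, dict[str, str]] = {}
    for pair, findings in _per_pair_findings(cohort):
        for f in findings:
            code = "biallelic" if f.biallelic else f.finding_type
            prev = cells.setdefault(f.gene, {}).get(pair.patient_id)
            if prev == "biallelic":
                continue
            if prev == "mutation" and f.finding_type in LOSS_FINDINGS:
                code = "biallelic" if f.biallelic else f"mutation+{f.finding_type}"
            cells[f.gene][pair.patient_id] = code
    patients = [p.patient_id for p in cohort]
    mat = pd.DataFrame(index=sorted(cells), columns=patients, dtype=object)
    for gene, row in cells.items():
        for patient, code in row.items():
            mat.loc[gene, patient] = code
    return mat.fillna("")
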