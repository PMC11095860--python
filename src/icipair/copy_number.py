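"""Gene-level absolute copy number from purity and segmented log2 ratios.

The tumor compartment of a biopsy with purity ``p`` carrying ``ACN``
copies of a locus, mixed with diploid normal cells, yields a segmented
log2 ratio ``l = log2((p*ACN + 2*(1-p)) / 2)``.  Inverting:

    ACN = (2**(l + 1) - 2*(1 - p)) / p

At ``l = 0`` purity cancels and ACN = 2 for any ``p``, which is the
property that pins down the grouping of the formula.  Gene-level ``l`` is
the overlap-length-weighted mean of segment log2 ratios across the gene.

Also provided: CNA categorization of the (clamped) ACN, and a simplified
arm-level aneuploidy score: an arm is called gained or lost when enough of
its segment-covered length exceeds an amplitude threshold, in the spirit
of arm-level callers for targeted panels (coverage-weighted, no
allele-specific modeling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CNA_CATEGORIES = (
    "homozygous-deletion",
    "heterozygous-deletion",
    "neutral",
    "gain",
    "high-amplification",
)

#: ACN cut points between consecutive categories; boundaries go to the
#: lower-severity (more neutral) side.
DEFAULT_ACN_THRESHOLDS = (0.5, 1.5, 2.5, 6.0)


@dataclass(frozen=True)
class Segment:
    """One segment of piecewise-constant copy ratio, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AcnCall:
    gene: str
    l: float
    purity: float
    acn_raw: float
    acn: float
    category: str

    def __post_init__(self) -> None:
        if self.acn < 0:
            raise ValueError("clamped ACN must be nonnegative")


@dataclass
class ArmCall:
    arm: str
    covered_fraction: float
    call: str  # gain / loss / neutral / uncalled


def _overlap_bp(seg: Segment, chrom: str, start: int, end: int) -> int:
    """Overlap in bp between a segment and a 1-based inclusive interval."""
    if seg.chrom != chrom:
        return 0
    return max(0, min(seg.end, end) - max(seg.start, start) + 1)


def weighted_gene_log2(
    segments: Iterable[Segment],
    gene_interval: tuple[str, int, int],
) -> float | None:
    """Overlap-length-weighted mean log2 ratio across a gene interval.

    Returns None (gene uncallable) when no segment overlaps the gene.
    """
    chrom, start, end = gene_interval
    if start > end:
        raise ValueError(f"invalid gene interval {chrom}:{start}-{end}")
    num = 0.0
    den = 0
    for seg in segments:
        bp = _overlap_bp(seg, chrom, start, end)
        if bp > 0:
            num += bp * seg.log2_ratio
            den += bp
    if den == 0:
        logger.info("no segment overlaps %s:%d-%d; gene uncallable", chrom, start, end)
        return None
    return num / den


def absolute_copy_number(l: float, purity: float) -> float:
    """ACN = (2**(l+1) - 2*(1-p)) / p.  The raw value may be negative when
    the observed ratio is deeper than a pure homozygous deletion allows
    (a diagnostic of purity overestimation); callers clamp at 0."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    return (2.0 ** (l + 1.0) - 2.0 * (1.0 - purity)) / purity


def classify_acn(
    acn: float,
    thresholds: Sequence[float] = DEFAULT_ACN_THRESHOLDS,
) -> str:
    """Map a clamped ACN to a CNA category.

    Default cut points 0.5 / 1.5 / 2.5 / 6.0 delimit homozygous deletion,
    heterozygous deletion, neutral, gain, and high amplification; each
    boundary value is assigned to the class nearer neutral.
    """
    if acn < 0:
        raise ValueError(f"ACN must be nonnegative, got {acn}")
    t = tuple(thresholds)
    if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
        raise ValueError(f"thresholds must be 4 strictly increasing values, got {t}")
    hom, het, neu_hi, gain_hi = t
    if acn < hom:
        return "homozygous-deletion"
    if acn < het:
        return "heterozygous-deletion"
    if acn <= neu_hi:
        return "neutral"
    if acn <= gain_hi:
        return "gain"
    return "high-amplification"


def call_gene_acn(
    segments: Iterable[Segment],
    gene: str,
    gene_interval: tuple[str, int, int],
    purity: float,
    thresholds: Sequence[float] = DEFAULT_ACN_THRESHOLDS,
) -> AcnCall | None:
    """Convenience: weighted l -> ACN -> category for one gene.

    Returns None when the gene has no segment coverage.
    """
    segments = list(segments)
    l = weighted_gene_log2(segments, gene_interval)
    if l is None:
        return None
    raw = absolute_copy_number(l, purity)
    acn = max(raw, 0.0)
    return AcnCall(
        gene=gene,
        l=l,
        purity=purity,
        acn_raw=raw,
        acn=acn,
        category=classify_acn(acn, thresholds),
    )


def call_sample_acn(
    segments: Iterable[Segment],
    gene_intervals: pd.DataFrame,
    purity: float,
    thresholds: Sequence[float] = DEFAULT_ACN_THRESHOLDS,
) -> list[AcnCall]:
    """ACN calls for every gene in an interval table (columns gene, chrom,
    start, end); uncallable genes are skipped with a log line."""
    segments = list(segments)
    calls = []
    for row in gene_intervals.itertuples(index=False):
        call = call_gene_acn(
            segments, row.gene, (str(row.chrom), int(row.start), int(row.end)),
            purity, thresholds,
        )
        if call is not None:
            calls.append(call)
    return calls


def aneuploidy_score(
    segments: Iterable[Segment],
    arm_intervals: pd.DataFrame,
    amplitude_threshold: float = 0.2,
    coverage_threshold: float = 0.7,
) -> tuple[list[ArmCall], int]:
    """Arm-level gain/loss calls and their count (the aneuploidy score).

    ``arm_intervals`` has columns arm, chrom, start, end (1-based
    inclusive).  An arm is uncalled when segments cover less than
    ``coverage_threshold`` of its length; otherwise it is called gain
    (loss) when at least ``coverage_threshold`` of the covered length has
    log2 ratio >= +threshold (<= -threshold), else neutral.  The score
    counts gained plus lost arms.
    """
    segments = list(segments)
    if not segments:
        logger.warning("empty segment set: all arms uncalled, score 0")
        calls = [
            ArmCall(arm=row.arm, covered_fraction=0.0, call="uncalled")
            for row in arm_intervals.itertuples(index=False)
        ]
        return calls, 0

    calls = []
    score = 0
    for row in arm_intervals.itertuples(index=False):
        arm_len = int(row.end) - int(row.start) + 1
        covered = 0
        gained = 0
        lost = 0
        for seg in segments:
            bp = _overlap_bp(seg, str(row.chrom), int(row.start), int(row.end))
            if bp == 0:
                continue
            covered += bp
            if seg.log2_ratio >= amplitude_threshold:
                gained += bp
            elif seg.log2_ratio <= -amplitude_threshold:
                lost += bp
        frac = covered / arm_len
        if frac < coverage_threshold:
            call = "uncalled"
        elif gained / covered >= coverage_threshold:
            call = "gain"
        elif lost / covered >= coverage_threshold:
            call = "loss"
        else:
            call = "neutral"
        if call in ("gain", "loss"):
            score += 1
        calls.append(ArmCall(arm=row.arm, covered_fraction=frac, call=call))
    return calls, score


def acn_calls_frame(calls: Iterable[AcnCall], sample_id: str | None = None) -> pd.DataFrame:
    """Tabulate AcnCalls, keeping the raw (possibly negative) ACN next to
    the clamped value."""
    rows = [
        {
            "gene": c.gene,
            "l": c.l,
            "purity": c.purity,
            "acn_raw": c.acn_raw,
            "acn": c.acn,
            "category": c.category,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["gene", "l", "purity", "acn_raw", "acn", "category"])
    if sample_id is not None:
        df.insert(0, "sample", sample_id)
    return df
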