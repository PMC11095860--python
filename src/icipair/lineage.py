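"""Tumor-pair shared-lineage similarity scoring.

A matched biopsy pair is scored against a cohort event-frequency catalog:
for each genomic event in the union of the two samples' event sets, a
shared event contributes the surprisal of observing it independently twice
(probability ``alpha * f**2`` for cohort frequency ``f``), while an
unshared event contributes the probability of *not* co-occurring
(``1 - f**2``).  The score is the negative natural log of the product, so
rare shared events dominate: two tumors sharing several private variants
are very unlikely to be independent primaries.

Because no analytic null is available, a permutation null is built from
cross-patient sample pairs, and a pair is called shared-lineage when its
score exceeds a configurable percentile of that null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("SNV", "indel", "CNA", "SV")

_CLASS_ALIASES = {
    "snv": "SNV",
    "snp": "SNV",
    "missense": "SNV",
    "nonsense": "SNV",
    "splice_site": "SNV",
    "indel": "indel",
    "small-indel": "indel",
    "ins": "indel",
    "del": "indel",
    "frameshift": "indel",
    "in_frame_del": "indel",
    "cna": "CNA",
    "gene-cna": "CNA",
    "copy_number": "CNA",
    "sv": "SV",
    "structural-variant": "SV",
    "rearrangement": "SV",
}


@dataclass(frozen=True, order=True)
class EventKey:
    """Canonical identity of one genomic event.

    ``detail`` holds the protein change for SNV/indel, the direction
    (``loss``, ``deletion``, ``amplification``) for gene-level CNAs, and a
    partner/breakpoint label for structural variants.  Fields are
    case-normalized on construction so that two textual spellings of the
    same event compare equal.
    """

    gene: str
    event_class: str
    detail: str

    def __post_init__(self) -> None:
        gene = self.gene.strip().upper()
        raw_class = self.event_class.strip()
        event_class = _CLASS_ALIASES.get(raw_class.lower(), raw_class)
        if event_class not in EVENT_CLASSES:
            raise ValueError(
                f"unknown event class {self.event_class!r}; "
                f"expected one of {EVENT_CLASSES}"
            )
        detail = " ".join(self.detail.split()).casefold()
        if not gene:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "event_class", event_class)
        object.__setattr__(self, "detail", detail)

    def __str__(self) -> str:  # canonical string form, unique per key
        return f"{self.gene}:{self.event_class}:{self.detail}"

    @classmethod
    def parse(cls, text: str) -> "EventKey":
        gene, event_class, detail = text.split(":", 2)
        return cls(gene, event_class, detail)


@dataclass
class EventCatalog:
    """Cohort event frequencies ``f`` in (0, 1]; ``p_event = f**2`` is
    recomputed on demand, never stored."""

    cohort_size: int
    freq: dict[EventKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        for key, f in self.freq.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"frequency for {key} must be in (0,1], got {f}")

    def frequency(self, event: EventKey) -> float:
        """Catalog frequency; events never seen in the cohort are imputed
        at 1/(N+1) (pseudo-count for scoring external pairs)."""
        try:
            return self.freq[event]
        except KeyError:
            imputed = 1.0 / (self.cohort_size + 1)
            logger.info("event %s absent from catalog; imputing f=%.4g", event, imputed)
            return imputed


@dataclass
class SimilarityResult:
    score: float
    shared_events: list[EventKey]
    per_event_contribution: dict[EventKey, float]
    null_percentile: float | None = None
    shared_lineage_call: bool | None = None
    has_infinite_contribution: bool = False

    def __post_init__(self) -> None:
        total = sum(self.per_event_contribution.values())
        if math.isfinite(self.score) and abs(total - self.score) > 1e-9:
            raise ValueError("score does not equal the sum of contributions")


def build_catalog(
    per_sample_events: Mapping[str, Iterable[EventKey]],
    one_sample_per_patient: bool = True,
    patient_of: Mapping[str, str] | None = None,
    sample_selection: Mapping[str, str] | None = None,
) -> EventCatalog:
    """Count cohort frequencies f_i = (samples containing event i) / N.

    With ``one_sample_per_patient`` (the default, matching the convention
    of counting each patient once, from the pre-treatment sample),
    ``patient_of`` maps sample id -> patient id and ``sample_selection``
    maps patient id -> the one sample to count; if no selection is given
    the lexicographically first sample of each patient is used.
    """
    if not per_sample_events:
        raise ValueError("cannot build a catalog from an empty cohort")

    if one_sample_per_patient and patient_of is not None:
        if sample_selection is None:
            sample_selection = {}
            for sample in sorted(per_sample_events):
                patient = patient_of[sample]
                sample_selection.setdefault(patient, sample)
        counted = [s for s in per_sample_events if s in set(sample_selection.values())]
    else:
        counted = list(per_sample_events)

    if not counted:
        raise ValueError("no samples left to count after patient selection")

    n = len(counted)
    counts: dict[EventKey, int] = {}
    for sample in counted:
        for event in set(per_sample_events[sample]):
            counts[event] = counts.get(event, 0) + 1
    freq = {event: c / n for event, c in counts.items()}
    return EventCatalog(cohort_size=n, freq=freq)


def similarity_score(
    events_a: Iterable[EventKey],
    events_b: Iterable[EventKey],
    catalog: EventCatalog,
    alpha: float = 1.0,
    universe: str = "union",
) -> SimilarityResult:
    """Score = -ln prod_i [ alpha*f_i^2 if i shared else (1 - f_i^2) ].

    The product runs over the union of the two samples' events (the
    per-pair event universe); ``universe='catalog'`` extends it to every
    catalog event, in which case events absent from both samples also take
    the unshared factor.  Symmetric in (a, b) by construction.

    A frequency-1 event present in only one sample gives a factor of 0 and
    hence an infinite score; the result is flagged, not raised.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if universe not in ("union", "catalog"):
        raise ValueError("universe must be 'union' or 'catalog'")

    set_a, set_b = set(events_a), set(events_b)
    if universe == "union":
        domain = set_a | set_b
    else:
        domain = set_a | set_b | set(catalog.freq)

    contributions: dict[EventKey, float] = {}
    shared: list[EventKey] = []
    infinite = False
    for event in sorted(domain):
        f = catalog.frequency(event)
        if event in set_a and event in set_b:
            shared.append(event)
            contributions[event] = -math.log(alpha * f * f)
        else:
            q = 1.0 - f * f
            if q <= 0.0:
                logger.warning(
                    "event %s has f=1 but is unshared: infinite contribution", event
                )
                contributions[event] = math.inf
                infinite = True
            else:
                contributions[event] = -math.log(q)

    score = sum(contributions.values())
    return SimilarityResult(
        score=score,
        shared_events=shared,
        per_event_contribution=contributions,
        has_infinite_contribution=infinite,
    )


def calibrate_null(
    catalog: EventCatalog,
    per_sample_events: Mapping[str, Iterable[EventKey]],
    patient_of: Mapping[str, str],
    n_permutations: int = 1000,
    alpha: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Empirical null score distribution from random cross-patient pairs.

    Cross-patient pairs cannot share lineage, so their scores estimate the
    distribution expected under independent tumors with this cohort's
    event frequencies.  Deterministic under a fixed seed.
    """
    patients: dict[str, list[str]] = {}
    for sample in sorted(per_sample_events):
        patients.setdefault(patient_of[sample], []).append(sample)
    if len(patients) < 2:
        raise ValueError("need samples from at least 2 distinct patients")
    if n_permutations < 100:
        logger.warning(
            "n_permutations=%d is small; null quantiles will be noisy", n_permutations
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patient_ids = sorted(patients)
    scores = np.empty(n_permutations)
    for i in range(n_permutations):
        pa, pb = rng.choice(len(patient_ids), size=2, replace=False)
        sa = patients[patient_ids[pa]][rng.integers(len(patients[patient_ids[pa]]))]
        sb = patients[patient_ids[pb]][rng.integers(len(patients[patient_ids[pb]]))]
        res = similarity_score(
            per_sample_events[sa], per_sample_events[sb], catalog, alpha=alpha
        )
        scores[i] = res.score
    return scores


def call_shared_lineage(
    result: SimilarityResult,
    null_scores: Sequence[float],
    percentile: float = 95.0,
) -> SimilarityResult:
    """Attach the null percentile of the observed score and the
    shared-lineage call (score strictly above the chosen null percentile)."""
    null_arr = np.asarray(null_scores, dtype=float)
    threshold = float(np.percentile(null_arr, percentile))
    pct = float(100.0 * np.mean(null_arr < result.score))
    result.null_percentile = pct
    result.shared_lineage_call = bool(result.score > threshold)
    return result
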