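"""Seeded synthetic paired-biopsy cohorts with known ground truth.

The generator emulates the statistical structure of an acquired-resistance
cohort: matched pre/post tumor samples per patient, baseline driver and
private clonal variants shared by both samples, acquired events planted in
the post sample only at configured per-patient probabilities, segmented
copy-number profiles that invert the purity-corrected absolute-copy-number
formula exactly at zero noise, spatial point patterns with a constructed
PD-1/PD-L1 engagement fraction, and paired H-score shifts.

Default event frequencies, therapy mix, response distribution and paired
H-score shift follow the published cohort-level rates of acquired
resistance to PD-(L)1 blockade in NSCLC; where no value is reported
(segment noise, purity range, spatial densities) defaults are chosen to be
realistic for targeted-panel and mIF data and are documented in the
methods note.  All coordinates and gene intervals are synthetic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquired import PairedCase, SampleProfile, Variant
from .copy_number import (
    DEFAULT_ACN_THRESHOLDS,
    Segment,
    call_sample_acn,
)
from .lineage import EventKey
from .spatial import CellFrame

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# synthetic gene panel and chromosome-arm intervals

CHROM_LENGTH_BP = 100_000_000
CENTROMERE_BP = 40_000_000
GENE_LENGTH_BP = 100_000

PANEL_GENES = (
    "STK11", "B2M", "SMARCA4", "NF1", "NF2", "APC", "CDKN2A", "MAP3K1",
    "MAP2K4", "KEAP1", "MTOR", "JAK1", "JAK2", "PIK3CA", "SOS1", "PDGFRA",
    "ERBB2", "BRAF", "KRAS", "TP53", "EGFR", "PTEN", "CD274", "FBXW7",
    "MDM2", "MYC", "AKT1",
)


def default_gene_panel() -> pd.DataFrame:
    """Synthetic gene interval table (gene, chrom, start, end; 1-based
    inclusive).  Coordinates are invented on 22 uniform 100 Mb autosomes —
    they carry no genomic meaning beyond giving every gene a unique,
    arm-assignable locus."""
    rows = []
    for i, gene in enumerate(PANEL_GENES):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000_000 + (i // 22) * 35_000_000 + 1
        rows.append(
            {"gene": gene, "chrom": chrom, "start": start, "end": start + GENE_LENGTH_BP - 1}
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def default_arm_intervals() -> pd.DataFrame:
    """Synthetic p/q arm intervals matching the synthetic chromosomes."""
    rows = []
    for i in range(1, 23):
        chrom = f"chr{i}"
        rows.append({"arm": f"{i}p", "chrom": chrom, "start": 1, "end": CENTROMERE_BP})
        rows.append(
            {"arm": f"{i}q", "chrom": chrom, "start": CENTROMERE_BP + 1, "end": CHROM_LENGTH_BP}
        )
    return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# default study conditions

def _snv(gene: str, pchange: str) -> EventKey:
    return EventKey(gene, "SNV", pchange)


def _indel(gene: str, pchange: str) -> EventKey:
    return EventKey(gene, "indel", pchange)


def _cna(gene: str, direction: str) -> EventKey:
    return EventKey(gene, "CNA", direction)


#: acquired mutation probabilities per patient (cohort rates of acquired
#: loss-of-function / activating mutations at resistance)
DEFAULT_ACQUIRED_MUTATION_FREQS: dict[EventKey, float] = {
    _indel("STK11", "p.K78fs"): 0.089,
    _snv("B2M", "p.E94*"): 0.063,
    _snv("SMARCA4", "p.R1192*"): 0.063,
    _snv("NF1", "p.R461*"): 0.051,
    _snv("APC", "p.R1450*"): 0.038,
    _snv("CDKN2A", "p.R80*"): 0.038,
    _snv("PIK3CA", "p.E545K"): 0.038,
    _snv("MAP3K1", "p.S939*"): 0.025,
    _snv("MAP2K4", "p.R154*"): 0.025,
    _snv("KEAP1", "p.R320Q"): 0.025,
    _snv("MTOR", "p.S2215F"): 0.013,
    _snv("JAK1", "p.K860fs"): 0.013,
    _snv("JAK2", "p.R683*"): 0.013,
    _snv("SOS1", "p.N233Y"): 0.013,
    _snv("PDGFRA", "p.D842V"): 0.013,
    _snv("ERBB2", "p.V777L"): 0.013,
    _snv("BRAF", "p.G469A"): 0.013,
}

#: acquired gene-level CNA probabilities per patient
DEFAULT_ACQUIRED_CNA_FREQS: dict[EventKey, float] = {
    _cna("B2M", "loss"): 0.228,
    _cna("STK11", "loss"): 0.177,
    _cna("SMARCA4", "loss"): 0.177,
    _cna("KEAP1", "loss"): 0.165,
    _cna("PTEN", "loss"): 0.101,
    _cna("CDKN2A", "loss"): 0.101,
    _cna("CD274", "loss"): 0.089,
    _cna("JAK2", "loss"): 0.076,
    _cna("FBXW7", "loss"): 0.076,
    _cna("JAK1", "loss"): 0.063,
    _cna("CDKN2A", "deletion"): 0.089,
    _cna("NF1", "deletion"): 0.025,
    _cna("CD274", "deletion"): 0.013,
    _cna("JAK2", "deletion"): 0.013,
    _cna("MDM2", "amplification"): 0.051,
    _cna("KRAS", "amplification"): 0.038,
    _cna("MYC", "amplification"): 0.025,
    _cna("AKT1", "amplification"): 0.013,
    _cna("EGFR", "amplification"): 0.013,
}

#: probability of a concurrent acquired mutation + heterozygous loss
#: (biallelic inactivation) planted jointly
DEFAULT_BIALLELIC_FREQS: dict[str, float] = {
    "STK11": 0.051,
    "SMARCA4": 0.025,
    "KEAP1": 0.013,
    "B2M": 0.013,
    "JAK1": 0.013,
}

#: baseline (pre-treatment, clonal) event probabilities — present in both
#: samples of a pair
DEFAULT_BASELINE_FREQS: dict[EventKey, float] = {
    _snv("KRAS", "p.G12C"): 0.341,
    _snv("TP53", "p.R273H"): 0.300,
    _snv("TP53", "p.R175H"): 0.150,
    _snv("EGFR", "p.L858R"): 0.120,
    _snv("STK11", "p.F354L"): 0.080,
}

DEFAULT_THERAPY_MIX: dict[str, float] = {
    "ICI-mono": 0.561,
    "ICI+CTLA4": 0.061,
    "chemo-ICI": 0.378,
}

RESPONSE_PROBS = {"CR": 0.024, "PR": 0.415, "SD": 0.561}

#: true copy number planted for each CNA direction
ACN_FOR_DIRECTION = {"loss": 1.0, "deletion": 0.25, "amplification": 8.0}

#: marker bundles for the synthetic cell classes
CLASS_MARKERS: dict[str, tuple[str, ...]] = {
    "tumor": ("CK",),
    "tumor_pdl1": ("CK", "PDL1"),
    "lymphocyte": ("CD3e", "CD45"),
    "cd8_t": ("CD3e", "CD8a", "CD45"),
    "cd8_pd1_t": ("CD3e", "CD8a", "PD1", "CD45"),
    "cd4_t": ("CD3e", "CD4", "CD45"),
    "macrophage": ("CD68", "CD45"),
}

CLASS_LABEL = {
    "tumor": "epithelial",
    "tumor_pdl1": "epithelial",
    "lymphocyte": "lymphocyte",
    "cd8_t": "lymphocyte",
    "cd8_pd1_t": "lymphocyte",
    "cd4_t": "lymphocyte",
    "macrophage": "macrophage",
}

ALL_MARKERS = ("CK", "PDL1", "PD1", "CD3e", "CD8a", "CD4", "CD45", "CD68")


@dataclass
class SpatialConfig:
    """Point-pattern conditions for one simulated mIF sample.

    ``density`` is cells/mm^2 per cell class.  ``target_engagement`` is
    the fraction of PD-L1+ cells to be given a PD-1+ neighbor within the
    20 um interaction radius; the construction guarantees the realized
    fraction equals round(target * n_pdl1) / n_pdl1 exactly.
    """

    area_mm2: float = 1.0
    density: dict[str, float] = field(
        default_factory=lambda: {
            "tumor": 1500.0,
            "tumor_pdl1": 40.0,
            "lymphocyte": 30.0,
            "cd8_t": 20.0,
            "cd8_pd1_t": 18.0,
            "cd4_t": 20.0,
            "macrophage": 80.0,
        }
    )
    target_engagement: float = 0.30
    process: str = "poisson"  # or "thomas" for clustered placement
    cluster_parent_density: float = 5.0  # parents/mm^2 for the Thomas option
    cluster_sd_um: float = 50.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("tissue area must be positive")
        if any(d < 0 for d in self.density.values()):
            raise ValueError("densities must be nonnegative")
        if not (0.0 <= self.target_engagement <= 1.0):
            raise ValueError(
                f"target_engagement must be in [0,1], got {self.target_engagement}"
            )
        if self.process not in ("poisson", "thomas"):
            raise ValueError("process must be 'poisson' or 'thomas'")


@dataclass
class SimConfig:
    """Conditions of one synthetic cohort run."""

    n_patients: int = 82
    therapy_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THERAPY_MIX))
    acquired_event_freqs: dict[EventKey, float] = field(
        default_factory=lambda: {
            **DEFAULT_ACQUIRED_MUTATION_FREQS,
            **DEFAULT_ACQUIRED_CNA_FREQS,
        }
    )
    baseline_event_freqs: dict[EventKey, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_FREQS)
    )
    biallelic_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIALLELIC_FREQS)
    )
    private_event_rate: float = 4.0  # mean patient-private clonal variants
    purity_range: tuple[float, float] = (0.3, 0.9)
    segment_noise_sd: float = 0.05  # log2 units
    spatial: SpatialConfig | None = field(default_factory=SpatialConfig)
    spatial_engagement_post: float = 0.10
    #: immune-class density drop at resistance (TIL medians 88 -> 36 /mm^2)
    spatial_density_post_scale: float = 36.0 / 88.0
    spatial_n_patients: int = 6
    hscore_shift: float = -70.0
    hscore_noise_sd: float = 25.0
    hscore_n_patients: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.therapy_mix:
            raise ValueError("therapy_mix must not be empty")
        total = sum(self.therapy_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"therapy_mix proportions must sum to 1, got {total}")
        for table in (self.acquired_event_freqs, self.baseline_event_freqs):
            for key, p in table.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability for {key} outside [0,1]: {p}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must lie within (0,1]: {self.purity_range}")
        if self.segment_noise_sd < 0:
            raise ValueError("segment_noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Planted truths, serialized alongside the simulated outputs.

    ``cell_frames`` holds the emitted spatial tables (data, not truth);
    they are written as CSV and excluded from the truth JSON.
    """

    planted_acquired: dict[str, list[str]] = field(default_factory=dict)
    planted_baseline: dict[str, list[str]] = field(default_factory=dict)
    true_acn: dict[str, dict[str, float]] = field(default_factory=dict)
    true_engagement: dict[str, float | None] = field(default_factory=dict)
    true_density: dict[str, dict[str, float]] = field(default_factory=dict)
    hscores: dict[str, tuple[float, float]] = field(default_factory=dict)
    cell_frames: dict[str, CellFrame] = field(default_factory=dict)
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_acquired": self.planted_acquired,
            "planted_baseline": self.planted_baseline,
            "true_acn": self.true_acn,
            "true_engagement": self.true_engagement,
            "true_density": self.true_density,
            "hscores": self.hscores,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# segments

def noise_free_log2(acn: float, purity: float) -> float:
    """The segment log2 ratio implied by a true ACN at a given purity:
    l = log2(p*ACN + 2*(1-p)) - 1, the exact inverse of the forward
    ACN formula."""
    mix = purity * acn + 2.0 * (1.0 - purity)
    if mix <= 0.0:
        raise ValueError(
            f"infeasible configuration: p*ACN + 2(1-p) = {mix} <= 0 "
            f"(ACN={acn}, purity={purity})"
        )
    return math.log2(mix) - 1.0


def simulate_segments(
    true_acn_by_gene: Mapping[str, float],
    purity: float,
    noise_sd: float,
    gene_intervals: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    chrom_length: int = CHROM_LENGTH_BP,
) -> list[Segment]:
    """Segment profile consistent with planted per-gene absolute copy
    numbers.

    Each gene gets a segment exactly spanning its interval at the
    noise-free log2 ratio implied by its true ACN (plus Gaussian noise of
    ``noise_sd`` log2 units); the remainder of every chromosome is covered
    by copy-neutral background segments, so the forward gene-level
    ACN computation round-trips exactly at ``noise_sd = 0``.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if any(acn < 0 for acn in true_acn_by_gene.values()):
        raise ValueError("true ACN values must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    segments: list[Segment] = []
    panel = gene_intervals.sort_values(["chrom", "start"])
    for chrom, group in panel.groupby("chrom", sort=True):
        cursor = 1
        for row in group.itertuples(index=False):
            acn = float(true_acn_by_gene.get(row.gene, 2.0))
            l = noise_free_log2(acn, purity)
            if noise_sd > 0:
                l += rng.normal(0.0, noise_sd)
            if row.start > cursor:
                bg = noise_free_log2(2.0, purity)  # == 0 exactly
                if noise_sd > 0:
                    bg += rng.normal(0.0, noise_sd)
                segments.append(Segment(chrom, cursor, row.start - 1, bg, n_markers=50))
            segments.append(Segment(chrom, int(row.start), int(row.end), l, n_markers=20))
            cursor = int(row.end) + 1
        if cursor <= chrom_length:
            bg = 0.0 if noise_sd == 0 else rng.normal(0.0, noise_sd)
            segments.append(Segment(chrom, cursor, chrom_length, bg, n_markers=50))
    return segments


# ---------------------------------------------------------------------------
# cells

def _poisson_points(rng: np.random.Generator, density: float, area_mm2: float,
                    side_um: float) -> np.ndarray:
    n = rng.poisson(density * area_mm2)
    return rng.uniform(0.0, side_um, size=(n, 2))


def _thomas_points(rng: np.random.Generator, density: float, area_mm2: float,
                   side_um: float, parent_density: float, sd_um: float) -> np.ndarray:
    """Clustered (Thomas process) placement: Poisson parents with Gaussian
    offspring, points falling outside the frame redrawn uniformly."""
    n_total = rng.poisson(density * area_mm2)
    n_parents = max(1, rng.poisson(parent_density * area_mm2))
    parents = rng.uniform(0.0, side_um, size=(n_parents, 2))
    assignment = rng.integers(0, n_parents, size=n_total)
    pts = parents[assignment] + rng.normal(0.0, sd_um, size=(n_total, 2))
    outside = (pts < 0).any(axis=1) | (pts > side_um).any(axis=1)
    pts[outside] = rng.uniform(0.0, side_um, size=(int(outside.sum()), 2))
    return pts


def simulate_cells(
    config: SpatialConfig,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
    timepoint: str = "",
    target_engagement: float | None = None,
    density_scale: float = 1.0,
) -> tuple[CellFrame, dict]:
    """One synthetic mIF cell table plus its ground-truth dict.

    Non-PD-1 classes are placed by a homogeneous Poisson process (or the
    clustered Thomas option).  PD-1+ cells are placed constructively: a
    round(target * n_pdl1) subset of PD-L1+ cells each receives a PD-1+
    companion within the 20 um radius, and every other PD-1+ cell is kept
    farther than 20 um from all non-interactor PD-L1+ cells, so the
    realized engagement fraction is exact by construction.  Coordinates
    are rounded to two decimal microns for cross-platform file stability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = config.target_engagement if target_engagement is None else target_engagement
    if not (0.0 <= target <= 1.0):
        raise ValueError(f"target_engagement must be in [0,1], got {target}")

    side_um = math.sqrt(config.area_mm2) * 1000.0
    radius, margin = 20.0, 21.0  # margin absorbs the 0.01 um rounding

    placements: dict[str, np.ndarray] = {}
    for cls in sorted(config.density):
        dens = config.density[cls] * density_scale if CLASS_LABEL.get(cls) != "epithelial" \
            else config.density[cls]
        if "PD1" in CLASS_MARKERS.get(cls, ()):
            continue  # PD-1+ classes are placed constructively below
        if config.process == "thomas":
            placements[cls] = _thomas_points(
                rng, dens, config.area_mm2, side_um,
                config.cluster_parent_density, config.cluster_sd_um,
            )
        else:
            placements[cls] = _poisson_points(rng, dens, config.area_mm2, side_um)

    pdl1 = placements.get("tumor_pdl1", np.empty((0, 2)))
    n_pdl1 = len(pdl1)
    k = int(round(target * n_pdl1))
    interactor_idx = rng.choice(n_pdl1, size=k, replace=False) if k else np.array([], dtype=int)
    non_interactors = np.delete(pdl1, interactor_idx, axis=0) if n_pdl1 else pdl1

    def clear_of_non_interactors(pt: np.ndarray) -> bool:
        if len(non_interactors) == 0:
            return True
        return bool(np.min(np.hypot(*(non_interactors - pt).T)) > margin)

    pd1_points: list[np.ndarray] = []
    for idx in interactor_idx:
        anchor = pdl1[idx]
        placed = False
        for _ in range(500):
            r = rng.uniform(3.0, 12.0)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pt = anchor + np.array([r * math.cos(theta), r * math.sin(theta)])
            if (pt < 0).any() or (pt > side_um).any():
                continue
            if clear_of_non_interactors(pt):
                pd1_points.append(pt)
                placed = True
                break
        if not placed:
            # the anchor is hemmed in by non-interactors: move it to open
            # ground and try again
            for _ in range(5000):
                new_anchor = rng.uniform(0.0, side_um, size=2)
                others = np.delete(pdl1, idx, axis=0)
                if len(others) == 0 or np.min(np.hypot(*(others - new_anchor).T)) > 2 * margin:
                    pdl1[idx] = new_anchor
                    pt = new_anchor + np.array([5.0, 0.0])
                    pd1_points.append(np.clip(pt, 0.0, side_um))
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place an interacting PD-1+ cell")
    placements["tumor_pdl1"] = pdl1
    non_interactors = np.delete(pdl1, interactor_idx, axis=0) if n_pdl1 else pdl1

    pd1_classes = [c for c in sorted(config.density) if "PD1" in CLASS_MARKERS.get(c, ())]
    for cls in pd1_classes:
        dens = config.density[cls] * density_scale
        n_cls = rng.poisson(dens * config.area_mm2)
        take_companions = min(len(pd1_points), n_cls)
        pts = [pd1_points.pop() for _ in range(take_companions)]
        for _ in range(n_cls - take_companions):
            for _ in range(500):
                pt = rng.uniform(0.0, side_um, size=2)
                if clear_of_non_interactors(pt):
                    pts.append(pt)
                    break
        placements[cls] = np.array(pts) if pts else np.empty((0, 2))
    if pd1_points:
        # companions beyond the PD-1 class budget still must exist to make
        # the construction exact; append them to the first PD-1+ class
        cls = pd1_classes[0] if pd1_classes else "cd8_pd1_t"
        extra = np.array(pd1_points)
        placements[cls] = (
            np.vstack([placements.get(cls, np.empty((0, 2))), extra])
            if len(extra) else placements.get(cls, np.empty((0, 2)))
        )

    rows = []
    cell_no = 0
    for cls in sorted(placements):
        markers = set(CLASS_MARKERS.get(cls, ()))
        for x, y in placements[cls]:
            row = {
                "cell_id": f"{sample_id or 'c'}_{cell_no:05d}",
                "x": round(float(x), 2),
                "y": round(float(y), 2),
                "cell_class": CLASS_LABEL.get(cls, cls),
            }
            for m in ALL_MARKERS:
                row[m] = m in markers
            rows.append(row)
            cell_no += 1
    cells = pd.DataFrame(rows, columns=["cell_id", "x", "y", "cell_class", *ALL_MARKERS])
    frame = CellFrame(
        cells=cells, tissue_area_mm2=config.area_mm2,
        sample_id=sample_id, timepoint=timepoint,
    )
    truth = {
        "engagement": (k / n_pdl1) if n_pdl1 else None,
        "density": {
            cls: len(pts) / config.area_mm2 for cls, pts in placements.items()
        },
    }
    return frame, truth


# ---------------------------------------------------------------------------
# cohort

def _sample_events(rng: np.random.Generator, freqs: Mapping[EventKey, float]) -> list[EventKey]:
    return [e for e in sorted(freqs) if rng.random() < freqs[e]]


def _private_variants(rng: np.random.Generator, patient_id: str, mean_count: float) -> list[Variant]:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    n = rng.poisson(mean_count)
    out = []
    for j in range(n):
        gene = PANEL_GENES[rng.integers(len(PANEL_GENES))]
        pos = int(rng.integers(30, 900))
        change = f"p.{aa[rng.integers(20)]}{pos}{aa[rng.integers(20)]}.{patient_id}.{j}"
        out.append(Variant(_snv(gene, change)))
    return out


def simulate_cohort(config: SimConfig) -> tuple[list[PairedCase], GroundTruth]:
    """Generate a full synthetic paired cohort.

    Baseline events appear in both samples of a pair; acquired events only
    in the post sample.  Copy-number truths are realized through segment
    profiles and re-called with the production ACN caller, so category
    noise behaves as it would on real segmented data.  The same seed
    reproduces byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    panel = default_gene_panel()
    cases: list[PairedCase] = []
    truth = GroundTruth()

    therapy_names = sorted(config.therapy_mix)
    therapy_probs = np.array([config.therapy_mix[t] for t in therapy_names])
    response_names = sorted(RESPONSE_PROBS)
    response_probs = np.array([RESPONSE_PROBS[r] for r in response_names])

    mut_events = {
        e: f for e, f in config.acquired_event_freqs.items() if e.event_class != "CNA"
    }
    cna_events = {
        e: f for e, f in config.acquired_event_freqs.items() if e.event_class == "CNA"
    }

    for i in range(config.n_patients):
        patient_id = f"P{i:03d}"
        pre_id, post_id = f"{patient_id}_pre", f"{patient_id}_post"
        therapy = therapy_names[rng.choice(len(therapy_names), p=therapy_probs)]
        response = response_names[rng.choice(len(response_names), p=response_probs)]
        time_to_ar = 3.0 + float(rng.gamma(2.0, 3.0))
        interval = time_to_ar + float(rng.gamma(2.0, 5.0))
        purity = float(rng.uniform(*config.purity_range))

        baseline = _sample_events(rng, config.baseline_event_freqs)
        private = _private_variants(rng, patient_id, config.private_event_rate)
        base_variants = [Variant(e) for e in baseline] + private

        acquired_mut = set(_sample_events(rng, mut_events))
        acquired_cna = set(_sample_events(rng, cna_events))
        for gene, pbi in sorted(config.biallelic_freqs.items()):
            if rng.random() < pbi:
                gene_muts = [e for e in mut_events if e.gene == gene]
                if gene_muts:
                    acquired_mut.add(gene_muts[0])
                acquired_cna.add(_cna(gene, "loss"))

        acn_pre = {g: 2.0 for g in panel["gene"]}
        acn_post = dict(acn_pre)
        for e in sorted(acquired_cna):
            planted = ACN_FOR_DIRECTION[e.detail]
            current = acn_post.get(e.gene, 2.0)
            # a homozygous deletion supersedes a heterozygous loss of the
            # same gene
            if e.detail == "loss" and current < 2.0:
                continue
            acn_post[e.gene] = planted

        seg_pre = simulate_segments(acn_pre, purity, config.segment_noise_sd, panel, rng)
        seg_post = simulate_segments(acn_post, purity, config.segment_noise_sd, panel, rng)
        calls_pre = call_sample_acn(seg_pre, panel, purity)
        calls_post = call_sample_acn(seg_post, panel, purity)

        pre = SampleProfile(
            sample_id=pre_id, timepoint="pre",
            variants=list(base_variants), acn_calls=calls_pre,
            tmb=float(rng.gamma(3.0, 3.0)), purity=purity,
        )
        post_variants = list(base_variants) + [Variant(e) for e in sorted(acquired_mut)]
        post = SampleProfile(
            sample_id=post_id, timepoint="post",
            variants=post_variants, acn_calls=calls_post,
            tmb=float(rng.gamma(3.0, 3.0)), purity=purity,
        )
        cases.append(
            PairedCase(
                patient_id=patient_id, pre=pre, post=post,
                therapy_category=therapy, best_response=response,
                time_to_ar_months=time_to_ar, biopsy_interval_months=interval,
            )
        )
        truth.planted_acquired[patient_id] = [
            str(e) for e in sorted(acquired_mut | acquired_cna)
        ]
        truth.planted_baseline[patient_id] = [str(v.event) for v in base_variants]
        truth.true_acn[pre_id] = dict(acn_pre)
        truth.true_acn[post_id] = dict(acn_post)
        truth.segments[pre_id] = seg_pre
        truth.segments[post_id] = seg_post

    if config.spatial is not None:
        for case in cases[: config.spatial_n_patients]:
            for profile, target, scale in (
                (case.pre, config.spatial.target_engagement, 1.0),
                (case.post, config.spatial_engagement_post, config.spatial_density_post_scale),
            ):
                frame, cell_truth = simulate_cells(
                    config.spatial, rng, sample_id=profile.sample_id,
                    timepoint=profile.timepoint,
                    target_engagement=target, density_scale=scale,
                )
                truth.cell_frames[profile.sample_id] = frame
                truth.true_engagement[profile.sample_id] = cell_truth["engagement"]
                truth.true_density[profile.sample_id] = cell_truth["density"]

    for case in cases[: config.hscore_n_patients]:
        pre_h = float(np.clip(rng.normal(285.0, 20.0), 0.0, 300.0))
        post_h = float(np.clip(
            pre_h + config.hscore_shift + rng.normal(0.0, config.hscore_noise_sd),
            0.0, 300.0,
        ))
        truth.hscores[case.patient_id] = (round(pre_h, 1), round(post_h, 1))

    return cases, truth
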