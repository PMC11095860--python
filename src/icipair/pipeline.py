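"""Top-level pipeline: simulate (or load) a paired cohort, then chain
lineage scoring, copy-number calling, acquired-event calling, spatial
metrics and paired statistics into one reproducible report bundle.

All randomness flows from a single top-level seed through per-stage
derived streams (SeedSequence spawning), so each stage is independently
reproducible and re-running with the same config is byte-identical except
for timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import acquired as acq
from . import ihc, io, lineage, spatial
from .simulate import GroundTruth, SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either a simulator config or input paths."""

    out_dir: str | Path = "icipair_run"
    seed: int = 0
    sim: SimConfig | None = None
    input_dir: str | Path | None = None
    alpha: float = 1.0
    n_permutations: int = 500
    lineage_percentile: float = 95.0
    radius_um: float = spatial.DEFAULT_RADIUS_UM

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of sim config or input_dir must be given")


def _derived_seed(seed: int, index: int) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return np.random.default_rng(child)


def _write_inputs(out: Path, cases, truth: GroundTruth) -> None:
    io.write_manifest(cases, out / "manifest.csv")
    io.write_variants(
        {s.sample_id: s.variants for c in cases for s in (c.pre, c.post)},
        out / "variants.tsv",
    )
    io.write_purity(
        {s.sample_id: s.purity for c in cases for s in (c.pre, c.post) if s.purity},
        out / "purity.tsv",
    )
    if truth.segments:
        io.write_seg(truth.segments, out / "segments.seg")
    for sample_id, frame in truth.cell_frames.items():
        io.write_cells(frame, out / f"cells_{sample_id}.csv")
    if truth.cell_frames:
        pd.DataFrame(
            [
                {"sample": s, "tissue_area_mm2": f.tissue_area_mm2}
                for s, f in truth.cell_frames.items()
            ]
        ).to_csv(out / "tissue_area.tsv", sep="\t", index=False)
    if truth.hscores:
        io.write_hscores(truth.hscores, out / "hscores.tsv")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")


def load_cohort(input_dir: str | Path) -> tuple[list, pd.DataFrame, dict]:
    """Assemble PairedCases from a cohort directory (manifest.csv,
    variants.tsv, purity.tsv, optional segments.seg / hscores.tsv /
    cells_<sample>.csv).

    Copy-number calls are re-derived from the SEG file with the bundled
    synthetic gene panel; supply a custom panel through the library for
    real interval tables.
    """
    from . import copy_number as cn
    from .acquired import PairedCase, SampleProfile
    from .simulate import default_gene_panel

    input_dir = Path(input_dir)
    manifest = io.read_manifest(input_dir / "manifest.csv")
    variants = io.read_variants(input_dir / "variants.tsv")
    purity = (
        io.read_purity(input_dir / "purity.tsv")
        if (input_dir / "purity.tsv").exists() else {}
    )
    seg_path = input_dir / "segments.seg"
    segments = io.read_seg(seg_path) if seg_path.exists() else {}
    if segments and not purity:
        raise ValueError(
            "segments.seg supplied without purity.tsv: copy-number calling "
            "requires a tumor-purity estimate per sample"
        )
    panel = default_gene_panel()

    def profile(sample_id: str, timepoint: str) -> SampleProfile:
        calls = []
        if sample_id in segments:
            calls = cn.call_sample_acn(segments[sample_id], panel, purity[sample_id])
        return SampleProfile(
            sample_id=sample_id, timepoint=timepoint,
            variants=variants.get(sample_id, []), acn_calls=calls,
            purity=purity.get(sample_id),
        )

    cases = []
    for row in manifest.itertuples(index=False):
        cases.append(
            PairedCase(
                patient_id=str(row.patient),
                pre=profile(str(row.pre_sample), "pre"),
                post=profile(str(row.post_sample), "post"),
                therapy_category=str(row.therapy_category),
                best_response=str(getattr(row, "best_response", "SD")),
                time_to_ar_months=float(getattr(row, "time_to_ar_months", 3.0)),
            )
        )
    hs_path = input_dir / "hscores.tsv"
    hscores = io.read_hscores(hs_path) if hs_path.exists() else pd.DataFrame(
        columns=["patient", "pre", "post"]
    )
    areas = {}
    area_path = input_dir / "tissue_area.tsv"
    if area_path.exists():
        area_df = pd.read_csv(area_path, sep="\t")
        areas = dict(zip(area_df["sample"], area_df["tissue_area_mm2"]))
    cell_frames = {}
    for path in sorted(input_dir.glob("cells_*.csv")):
        sample_id = path.stem.removeprefix("cells_")
        timepoint = "post" if sample_id.endswith("_post") else "pre"
        cell_frames[sample_id] = io.read_cells(
            path, tissue_area_mm2=float(areas.get(sample_id, 1.0)),
            sample_id=sample_id, timepoint=timepoint,
        )
    return cases, hscores, cell_frames


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write the report bundle.

    Returns the summary dict that is also written as ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim_config = dataclasses.replace(config.sim, seed=config.seed)
        cases, truth = simulate_cohort(sim_config)
        _write_inputs(out, cases, truth)
        hscores = pd.DataFrame(
            [{"patient": k, "pre": v[0], "post": v[1]} for k, v in truth.hscores.items()]
        )
        cell_frames = truth.cell_frames
    else:
        cases, hscores, cell_frames = load_cohort(config.input_dir)

    summary: dict = {
        "seed": config.seed,
        "version": __version__,
        "n_patients": len(cases),
        "parameters": {
            "alpha": config.alpha,
            "n_permutations": config.n_permutations,
            "lineage_percentile": config.lineage_percentile,
            "radius_um": config.radius_um,
        },
    }

    # --- lineage: catalog from pre-treatment samples, one per patient
    per_sample_events = {}
    patient_of = {}
    for case in cases:
        for profile in (case.pre, case.post):
            events = {v.event for v in acq.filter_variants(profile.variants)}
            events |= {
                lineage.EventKey(c.gene, "CNA", _cna_direction(c.category))
                for c in profile.acn_calls if c.category != "neutral"
            }
            per_sample_events[profile.sample_id] = events
            patient_of[profile.sample_id] = case.patient_id
    catalog = lineage.build_catalog(
        per_sample_events, one_sample_per_patient=True, patient_of=patient_of,
        sample_selection={c.patient_id: c.pre.sample_id for c in cases},
    )
    null = lineage.calibrate_null(
        catalog, per_sample_events, patient_of,
        n_permutations=config.n_permutations, alpha=config.alpha,
        seed=_derived_seed(config.seed, 1),
    )
    lineage_rows = []
    for case in cases:
        res = lineage.similarity_score(
            per_sample_events[case.pre.sample_id],
            per_sample_events[case.post.sample_id],
            catalog, alpha=config.alpha,
        )
        lineage.call_shared_lineage(res, null, config.lineage_percentile)
        lineage_rows.append(
            {
                "patient": case.patient_id,
                "score": res.score,
                "n_shared": len(res.shared_events),
                "null_percentile": res.null_percentile,
                "shared_lineage": res.shared_lineage_call,
            }
        )
    lineage_df = pd.DataFrame(lineage_rows)
    lineage_df.to_csv(out / "lineage_scores.tsv", sep="\t", index=False)
    summary["lineage"] = {
        "n_shared_lineage": int(lineage_df["shared_lineage"].sum()),
        "null_p95": float(np.percentile(null, 95)),
        "median_pair_score": float(lineage_df["score"].median()),
    }

    # --- acquired events
    findings = acq.findings_frame(cases)
    findings.to_csv(out / "acquired_findings.tsv", sep="\t", index=False)
    cohort_summary = acq.summarize(cases)
    cohort_summary["gene_table"].to_csv(out / "acquired_gene_table.tsv", sep="\t", index=False)
    acq.oncoprint_matrix(cases).to_csv(out / "oncoprint_matrix.tsv", sep="\t")
    summary["acquired"] = {
        k: v for k, v in cohort_summary.items()
        if k not in ("gene_table", "biallelic_counts")
    }
    summary["acquired"]["biallelic_counts"] = cohort_summary["biallelic_counts"]

    # --- paired TMB (consumed values; aneuploidy analogous)
    with_tmb = [c for c in cases if c.pre.tmb is not None and c.post.tmb is not None]
    if with_tmb:
        tmb = ihc.PairedSeries(
            pre=[c.pre.tmb for c in with_tmb], post=[c.post.tmb for c in with_tmb]
        )
        summary["tmb"] = {
            "median_pre": float(np.median(tmb.pre)),
            "median_post": float(np.median(tmb.post)),
            "wilcoxon_p": ihc.paired_wilcoxon(tmb),
        }

    # --- spatial metrics per sample, deltas per pair
    if cell_frames:
        metric_rows = [
            spatial.sample_metrics(frame, radius_um=config.radius_um)
            for _, frame in sorted(cell_frames.items())
        ]
        metrics_df = pd.DataFrame(metric_rows)
        metrics_df.to_csv(out / "spatial_metrics.tsv", sep="\t", index=False)
        deltas = _pair_deltas(metrics_df)
        deltas.to_csv(out / "spatial_deltas.tsv", sep="\t", index=False)
        eng = deltas.dropna(subset=["engagement_fraction_pre", "engagement_fraction_post"])
        if len(eng) >= 1:
            series = ihc.PairedSeries(
                pre=list(eng["engagement_fraction_pre"]),
                post=list(eng["engagement_fraction_post"]),
            )
            summary["spatial"] = {
                "n_pairs": len(eng),
                "median_engagement_pre": float(np.median(series.pre)),
                "median_engagement_post": float(np.median(series.post)),
                "engagement_wilcoxon_p": ihc.paired_wilcoxon(series),
            }

    # --- H-scores
    if len(hscores):
        series = ihc.PairedSeries(pre=list(hscores["pre"]), post=list(hscores["post"]))
        deltas_h = [ihc.delta_h(a, b) for a, b in zip(series.pre, series.post)]
        summary["hscore"] = {
            "n_pairs": len(hscores),
            "median_pre": float(np.median(series.pre)),
            "median_post": float(np.median(series.post)),
            "median_absolute_change": float(np.median([d[0] for d in deltas_h])),
            "wilcoxon_p": ihc.paired_wilcoxon(series),
        }

    io.write_json(summary, out / "summary.json")
    (out / "run.log").write_text(_run_log(config, summary))
    return summary


def _cna_direction(category: str) -> str:
    if category == "heterozygous-deletion":
        return "loss"
    if category == "homozygous-deletion":
        return "deletion"
    return "amplification"


def _pair_deltas(metrics: pd.DataFrame) -> pd.DataFrame:
    """Wide pre/post table per patient with post-minus-pre deltas."""
    m = metrics.copy()
    m["patient"] = m["sample"].str.replace(r"_(pre|post)$", "", regex=True)
    pre = m[m["timepoint"] == "pre"].set_index("patient")
    post = m[m["timepoint"] == "post"].set_index("patient")
    numeric = [
        c for c in metrics.columns
        if c not in ("sample", "timepoint") and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    rows = []
    for patient in pre.index.intersection(post.index):
        row: dict = {"patient": patient}
        for col in numeric:
            a, b = pre.loc[patient, col], post.loc[patient, col]
            row[f"{col}_pre"] = a
            row[f"{col}_post"] = b
            row[f"{col}_delta"] = (b - a) if pd.notna(a) and pd.notna(b) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _run_log(config: RunConfig, summary: dict) -> str:
    import datetime

    lines = [
        f"icipair {__version__}",
        f"python {platform.python_version()}",
        f"timestamp {datetime.datetime.now().isoformat()}",
        f"seed {config.seed}",
        "parameters " + json.dumps(summary["parameters"], sort_keys=True),
    ]
    return "\n".join(lines) + "\n"
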