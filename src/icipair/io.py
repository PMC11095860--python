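"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV/CSV/JSON with explicit headers; SEG files keep their
conventional 1-based inclusive coordinates (internal arithmetic also uses
1-based inclusive intervals, so no conversion is applied).  Malformed rows
are rejected with their line numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .acquired import PairedCase, SampleProfile, Variant
from .copy_number import AcnCall, Segment
from .lineage import EventKey
from .spatial import CellFrame

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
VARIANT_COLUMNS = [
    "sample", "gene", "genomic_change", "protein_change", "variant_class",
    "benign", "chip", "functional_class",
]


class ParseError(ValueError):
    pass


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("1", "true", "t", "yes", "y"):
        return True
    if text in ("0", "false", "f", "no", "n", "", "nan"):
        return False
    raise ParseError(f"cannot interpret {value!r} as a boolean flag")


# ---------------------------------------------------------------------------
# SEG

def read_seg(path: str | Path) -> dict[str, list[Segment]]:
    """Parse a SEG file into segments keyed by sample id.

    Coordinates stay 1-based inclusive.  Rows with non-numeric means or
    inverted coordinates raise a ParseError naming the offending line
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file, expected a SEG header row")
        cols = header.split("\t")
        if cols[:4] != SEG_COLUMNS[:4]:
            raise ParseError(
                f"{path}: unexpected SEG header {cols!r}; expected {SEG_COLUMNS}"
            )
        out: dict[str, list[Segment]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise ParseError(f"{path}: line {lineno}: expected {len(cols)} fields")
            sample, chrom, start_s, end_s, nmark_s, mean_s = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            try:
                mean = float(mean_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric seg.mean {mean_s!r}"
                )
            if start > end:
                raise ParseError(f"{path}: line {lineno}: start {start} > end {end}")
            nmark = int(nmark_s) if nmark_s not in ("", "NA") else None
            out.setdefault(sample, []).append(Segment(chrom, start, end, mean, nmark))
    return out


def write_seg(segments_by_sample: Mapping[str, Iterable[Segment]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sample in segments_by_sample:
            for seg in segments_by_sample[sample]:
                nmark = "" if seg.n_markers is None else str(seg.n_markers)
                fh.write(
                    f"{sample}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{nmark}\t"
                    f"{seg.log2_ratio:.6g}\n"
                )


# ---------------------------------------------------------------------------
# variants (MAF-like TSV)

_CLASS_FOR_EVENT = {"SNV": "SNV", "indel": "indel", "SV": "SV", "CNA": "CNA"}


def read_variants(path: str | Path) -> dict[str, list[Variant]]:
    """MAF-like variant TSV -> variants keyed by sample id.

    Missing benign/CHIP flags are treated as False (logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sample", "gene", "protein_change", "variant_class"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: variant table missing columns {sorted(missing)}")
    for flag in ("benign", "chip"):
        if flag not in df.columns:
            logger.info("%s: no %r column; treating all as False", path, flag)
            df[flag] = "false"
    if "functional_class" not in df.columns:
        df["functional_class"] = "VUS"
    out: dict[str, list[Variant]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            event = EventKey(row.gene, row.variant_class, row.protein_change)
            variant = Variant(
                event=event,
                benign=_parse_bool(row.benign),
                chip=_parse_bool(row.chip),
                functional_class=row.functional_class or "VUS",
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        out.setdefault(row.sample, []).append(variant)
    return out


def write_variants(variants_by_sample: Mapping[str, Iterable[Variant]], path: str | Path) -> None:
    rows = []
    for sample in variants_by_sample:
        for v in variants_by_sample[sample]:
            rows.append(
                {
                    "sample": sample,
                    "gene": v.event.gene,
                    "genomic_change": "",
                    "protein_change": v.event.detail,
                    "variant_class": v.event.event_class,
                    "benign": str(v.benign).lower(),
                    "chip": str(v.chip).lower(),
                    "functional_class": v.functional_class,
                }
            )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cells

def read_cells(
    path: str | Path,
    tissue_area_mm2: float,
    sample_id: str = "",
    timepoint: str = "",
    scale_um_per_px: float | None = None,
) -> CellFrame:
    """Cell CSV -> CellFrame.  Marker columns are coerced to booleans;
    pixel coordinates are converted to microns when a scale is given;
    duplicate cell ids are rejected."""
    df = pd.read_csv(path)
    missing = {"cell_id", "x", "y"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: cell table missing columns {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dupes = sorted(set(df.loc[df["cell_id"].duplicated(), "cell_id"]))[:5]
        raise ParseError(f"{path}: duplicate cell ids {dupes}")
    if scale_um_per_px is not None:
        df["x"] = df["x"] * scale_um_per_px
        df["y"] = df["y"] * scale_um_per_px
    for col in df.columns:
        if col in ("cell_id", "x", "y", "cell_class"):
            continue
        df[col] = df[col].map(_parse_bool)
    return CellFrame(
        cells=df, tissue_area_mm2=tissue_area_mm2,
        sample_id=sample_id, timepoint=timepoint,
    )


def write_cells(frame: CellFrame, path: str | Path) -> None:
    frame.cells.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tables: purity, manifest, H-scores

def read_purity(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "purity"} <= set(df.columns):
        raise ParseError(f"{path}: purity table needs columns sample, purity")
    out = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        p = float(row.purity)
        if not (0.0 < p <= 1.0):
            raise ParseError(f"{path}: line {lineno}: purity {p} outside (0,1]")
        out[str(row.sample)] = p
    return out


def write_purity(purity_by_sample: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample": s, "purity": p} for s, p in purity_by_sample.items()]
    ).to_csv(path, sep="\t", index=False)


MANIFEST_COLUMNS = [
    "patient", "pre_sample", "post_sample", "therapy_category", "best_response",
    "time_to_ar_months", "biopsy_interval_months", "pd_l1_tps_bin",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(cases: Iterable[PairedCase], path: str | Path) -> None:
    rows = [
        {
            "patient": c.patient_id,
            "pre_sample": c.pre.sample_id,
            "post_sample": c.post.sample_id,
            "therapy_category": c.therapy_category,
            "best_response": c.best_response,
            "time_to_ar_months": round(c.time_to_ar_months, 2),
            "biopsy_interval_months": (
                round(c.biopsy_interval_months, 2)
                if c.biopsy_interval_months is not None else ""
            ),
            "pd_l1_tps_bin": c.pd_l1_tps_bin or "",
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_hscores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"patient", "pre", "post"} <= set(df.columns):
        raise ParseError(f"{path}: H-score table needs columns patient, pre, post")
    return df


def write_hscores(hscores: Mapping[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient": k, "pre": v[0], "post": v[1]} for k, v in hscores.items()]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config / JSON

def read_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def write_config(config: Mapping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
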