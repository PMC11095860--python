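"""Single-cell spatial metrics from multiplexed-immunofluorescence tables.

Cells are centroids in micron coordinates with boolean marker flags.
Three metrics are computed per sample:

* PD-1/PD-L1 engagement — the fraction of PD-L1+ cells with at least one
  PD-1+ cell within a 20 um radius (boundary inclusive), the per-cell
  normalization of "interaction pairs / total PD-L1+ cells";
* nearest-neighbor distance from one phenotype to another (default tumor
  cytokeratin+ cells to CD8a+PD-1+ T cells), summarized by the median;
* per-phenotype density in cells/mm^2.

Neighbor queries use a k-d tree and match a brute-force all-pairs scan
exactly; distances are center-to-center with no edge correction (the
fraction of query cells near the frame boundary is recorded instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 20.0

KNOWN_MARKERS = (
    "PD1", "PDL1", "CD3e", "CD8a", "CD4", "CK", "FOXP3", "CD68", "CD45", "CD163",
)


@dataclass
class CellFrame:
    """A sample's cell table: cell_id, x, y (microns), one boolean column
    per marker, and an optional cell_class label column."""

    cells: pd.DataFrame
    tissue_area_mm2: float
    sample_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.tissue_area_mm2 <= 0:
            raise ValueError(f"tissue area must be positive, got {self.tissue_area_mm2}")
        required = {"cell_id", "x", "y"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if self.cells["cell_id"].duplicated().any():
            dupes = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"]
            raise ValueError(f"duplicate cell ids: {sorted(set(dupes))[:5]}")
        coords = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("cell coordinates must be finite")

    def select(self, markers: str | Sequence[str] | None = None,
               cell_class: str | None = None) -> pd.DataFrame:
        """Rows matching all given marker flags (AND) and/or a class label."""
        mask = pd.Series(True, index=self.cells.index)
        if markers is not None:
            if isinstance(markers, str):
                markers = [markers]
            for m in markers:
                if m not in self.cells.columns:
                    mask &= False
                else:
                    mask &= self.cells[m].astype(bool)
        if cell_class is not None:
            if "cell_class" not in self.cells.columns:
                mask &= False
            else:
                mask &= self.cells["cell_class"] == cell_class
        return self.cells.loc[mask]


@dataclass
class EngagementResult:
    n_pdl1: int
    n_interactors: int
    fraction: float | None
    radius_um: float = DEFAULT_RADIUS_UM
    n_pairs: int = 0  # total PD-1/PD-L1 pairs within radius, pre-normalization

    def __post_init__(self) -> None:
        if self.n_interactors > self.n_pdl1:
            raise ValueError("interactors cannot exceed PD-L1+ cells")


@dataclass
class NearestDistanceResult:
    distances: pd.Series  # indexed by from-cell id; NaN when no to-cell exists
    median: float | None
    n_from: int
    n_missing: int
    boundary_fraction: float | None = None


def neighbors_within(
    frame: CellFrame,
    query_markers: str | Sequence[str],
    target_markers: str | Sequence[str],
    radius_um: float = DEFAULT_RADIUS_UM,
) -> dict:
    """Map each query cell id to its [(target cell id, distance), ...]
    within the radius (Euclidean, d <= radius), nearest first.

    A cell positive for both marker sets appears in both roles but is
    never its own neighbor.
    """
    if radius_um <= 0:
        raise ValueError(f"radius must be positive, got {radius_um}")
    query = frame.select(query_markers)
    target = frame.select(target_markers)
    result: dict = {qid: [] for qid in query["cell_id"]}
    if query.empty or target.empty:
        return result

    qxy = query[["x", "y"]].to_numpy(dtype=float)
    txy = target[["x", "y"]].to_numpy(dtype=float)
    tids = target["cell_id"].to_numpy()
    tree = cKDTree(txy)
    hits = tree.query_ball_point(qxy, r=radius_um)
    for (qid, qpos), idx in zip(zip(query["cell_id"], qxy), hits):
        pairs = []
        for j in idx:
            if tids[j] == qid:
                continue
            # np.hypot: same libm rounding scalar or vectorized, so the
            # all-pairs oracle reproduces these distances bit-exactly
            d = float(np.hypot(txy[j, 0] - qpos[0], txy[j, 1] - qpos[1]))
            pairs.append((tids[j], d))
        pairs.sort(key=lambda t: (t[1], str(t[0])))
        result[qid] = pairs
    return result


def engagement_fraction(
    frame: CellFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    pd1_marker: str = "PD1",
    pdl1_marker: str = "PDL1",
) -> EngagementResult:
    """Fraction of PD-L1+ cells with >= 1 PD-1+ neighbor within the radius.

    Undefined (fraction None) when the frame has no PD-L1+ cells — never
    reported as 0, which would conflate "no ligand-positive cells" with
    "no engagement".
    """
    neigh = neighbors_within(frame, pdl1_marker, pd1_marker, radius_um)
    n_pdl1 = len(frame.select(pdl1_marker))
    if n_pdl1 == 0:
        logger.warning("sample %s has no %s+ cells: engagement undefined",
                       frame.sample_id or "<unnamed>", pdl1_marker)
        return EngagementResult(0, 0, None, radius_um, 0)
    n_interactors = sum(1 for pairs in neigh.values() if pairs)
    n_pairs = sum(len(pairs) for pairs in neigh.values())
    return EngagementResult(
        n_pdl1=n_pdl1,
        n_interactors=n_interactors,
        fraction=n_interactors / n_pdl1,
        radius_um=radius_um,
        n_pairs=n_pairs,
    )


def nearest_distance(
    frame: CellFrame,
    from_markers: str | Sequence[str] = "CK",
    to_markers: str | Sequence[str] = ("CD8a", "PD1"),
    radius_for_boundary_note_um: float = DEFAULT_RADIUS_UM,
) -> NearestDistanceResult:
    """Each from-cell's distance to its nearest to-cell, and the median.

    From-cells that also satisfy the to-phenotype are matched to the
    nearest *other* cell.  With no to-cells in the frame every distance is
    missing (NaN) and a warning is logged.  ``boundary_fraction`` records
    the share of from-cells within the note radius of the bounding box —
    a diagnostic for uncorrected edge effects.
    """
    from_cells = frame.select(from_markers)
    if from_cells.empty:
        raise ValueError("no cells match the from-phenotype")
    to_cells = frame.select(to_markers)

    fxy = from_cells[["x", "y"]].to_numpy(dtype=float)
    idx = pd.Index(from_cells["cell_id"], name="cell_id")
    if to_cells.empty:
        logger.warning("no cells match the to-phenotype: all distances missing")
        dist = pd.Series(np.nan, index=idx)
        return NearestDistanceResult(dist, None, len(from_cells), len(from_cells))

    txy = to_cells[["x", "y"]].to_numpy(dtype=float)
    tids = to_cells["cell_id"].to_numpy()
    tree = cKDTree(txy)
    # k=2 so a cell that is its own nearest neighbor can fall back to the
    # second hit
    k = min(2, len(to_cells))
    dists, hits = tree.query(fxy, k=k)
    dists = np.atleast_2d(dists.reshape(len(fxy), k))
    hits = np.atleast_2d(hits.reshape(len(fxy), k))

    out = np.full(len(fxy), np.nan)
    for i, fid in enumerate(from_cells["cell_id"]):
        for col in range(k):
            if tids[hits[i, col]] != fid:
                out[i] = dists[i, col]
                break
    n_missing = int(np.isnan(out).sum())

    xmin, ymin = frame.cells[["x", "y"]].min()
    xmax, ymax = frame.cells[["x", "y"]].max()
    r = radius_for_boundary_note_um
    near_edge = (
        (fxy[:, 0] - xmin < r) | (xmax - fxy[:, 0] < r)
        | (fxy[:, 1] - ymin < r) | (ymax - fxy[:, 1] < r)
    )
    valid = out[~np.isnan(out)]
    return NearestDistanceResult(
        distances=pd.Series(out, index=idx),
        median=float(np.median(valid)) if valid.size else None,
        n_from=len(fxy),
        n_missing=n_missing,
        boundary_fraction=float(near_edge.mean()),
    )


def density(
    frame: CellFrame,
    markers: str | Sequence[str] | None = None,
    cell_class: str | None = None,
) -> float:
    """Count of matching cells per mm^2 of tissue."""
    n = len(frame.select(markers, cell_class))
    return n / frame.tissue_area_mm2


def sample_metrics(
    frame: CellFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    density_specs: dict | None = None,
) -> dict:
    """One row of per-sample spatial metrics (engagement, tumor-to-CD8+PD-1+
    median distance, densities)."""
    if density_specs is None:
        density_specs = {
            "lymphocyte_density": {"cell_class": "lymphocyte"},
            "cd8_t_density": {"markers": ["CD3e", "CD8a"]},
            "pd1_density": {"markers": "PD1"},
        }
    eng = engagement_fraction(frame, radius_um)
    row: dict = {
        "sample": frame.sample_id,
        "timepoint": frame.timepoint,
        "n_cells": len(frame.cells),
        "engagement_fraction": eng.fraction,
        "engagement_n_pdl1": eng.n_pdl1,
        "engagement_n_pairs": eng.n_pairs,
    }
    try:
        nd = nearest_distance(frame)
        row["tumor_to_cd8pd1_median_um"] = nd.median
    except ValueError:
        row["tumor_to_cd8pd1_median_um"] = None
    for name, spec in density_specs.items():
        row[name] = density(frame, **spec)
    return row
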