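"""Classical two-dimensional scaling (2DS) and per-group polygon areas.

Torgerson scaling: from the squared distance matrix D2, double-center
B = -1/2 * J @ D2 @ J (J the centering operator), take the eigenvectors of
B for the two largest positive eigenvalues and scale each by the square
root of its eigenvalue. Phi-based distances need not be Euclidean, so
negative eigenvalues may occur; they are dropped and the two-axis goodness
(share of the positive-eigenvalue mass retained) is reported alongside.

The dispersion of a group of samples in the 2DS plane is measured as the
area of the convex hull of their coordinates (shoelace area of the hull
polygon); fewer than three distinct non-collinear points give area 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .distance import DistanceMatrix
from .records import SampleMeta, TIME_ORDER, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Two-axis classical MDS embedding of a labelled distance matrix."""

    labels: list[str]
    coords: np.ndarray  # (n, 2)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    goodness: float  # retained positive eigenvalue share, in [0, 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.labels,
             "x": self.coords[:, 0], "y": self.coords[:, 1]})

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["goodness"] = self.goodness
        df.to_csv(path, index=False)


def classical_mds_2d(dist: DistanceMatrix) -> OrdinationResult:
    """Embed a distance matrix in two dimensions by Torgerson scaling.

    Axis signs are made deterministic: in each coordinate column the entry
    of largest magnitude is positive. Columns come out centered and ordered
    by decreasing variance because eigenvalues are sorted descending.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("classical MDS needs at least 3 samples")
    d = dist.values
    if not np.isfinite(d).all():
        raise ValidationError("non-finite distances")

    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    pos_mass = float(evals[evals > 0].sum())
    coords = np.zeros((n, 2))
    retained = 0.0
    for axis in range(2):
        if axis < len(evals) and evals[axis] > 0:
            coords[:, axis] = evecs[:, axis] * np.sqrt(evals[axis])
            retained += float(evals[axis])
    goodness = retained / pos_mass if pos_mass > 0 else 0.0

    for axis in range(2):
        col = coords[:, axis]
        if col.any():
            k = int(np.argmax(np.abs(col)))
            if col[k] < 0:
                coords[:, axis] = -col
    return OrdinationResult(list(dist.labels), coords, evals, goodness)


def polygon_area(points: Sequence[tuple[float, float]]) -> float:
    """Convex-hull area of a 2-d point set (0 if degenerate).

    Duplicates are allowed; fewer than 3 distinct non-collinear points
    yield 0 by convention."""
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        return 0.0
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (x, y) pairs")
    if not np.isfinite(pts).all():
        raise ValidationError("non-finite coordinates")
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint(pts.tolist()).convex_hull.area)


def group_areas(
    ordination: OrdinationResult,
    samples: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Convex-hull area per (family, time point) in a family's 2DS plane.

    Intended for a per-family ordination; columns ``family_id``,
    ``time_point``, ``n_points``, ``area``. Degenerate groups (under three
    distinct non-collinear points) get area 0 with a log note.
    """
    meta = {s.sample_id: s for s in samples}
    pos = {lab: i for i, lab in enumerate(ordination.labels)}
    present = [s for s in samples if s.sample_id in pos]
    families = sorted({s.family_id for s in present})
    if len(families) > 1:
        logger.warning(
            "group_areas called with %d families in one ordination", len(families))
    rows = []
    for fam in families:
        for tp in TIME_ORDER:
            ids = [s.sample_id for s in present
                   if s.family_id == fam and s.time_point is tp]
            pts = ordination.coords[[pos[i] for i in ids]] if ids else np.empty((0, 2))
            area = polygon_area(pts) if len(ids) else 0.0
            if len(ids) and area == 0.0:
                logger.info("degenerate polygon: family %s at %s (%d point(s))",
                            fam, tp.value, len(ids))
            rows.append({"family_id": fam, "time_point": tp.value,
                         "n_points": len(ids), "area": area})
    return pd.DataFrame(rows)
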