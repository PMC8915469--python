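"""Phi association coefficient on binary patterns and sample distances.

The phi coefficient of two 0/1 vectors equals their Pearson correlation and
is computed here from the 2x2 co-presence table: with a = both 1, b = only
x, c = only y, d = both 0,

    phi = (a*d - b*c) / sqrt((a+b)(c+d)(a+c)(b+d)).

Distances are the affine map d = (1 - phi)/2, bounding them in [0, 1]
(identical patterns -> 0, complementary -> 1). The map is order-preserving,
so every rank-based downstream statistic is unaffected by the choice
between (1-phi)/2 and the alternative 1-phi exposed as an option.

phi is undefined when a vector is constant (all-0 or all-1 pattern, e.g. a
sterile-looking sample). The ``constant_policy`` resolves such pairs:
``neutral`` treats phi as 0 (no association) unless the two rows are
identical, in which case the distance is 0; ``error`` aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import PresenceMatrix, ValidationError

logger = logging.getLogger(__name__)

TRANSFORMS = ("half_one_minus_phi", "one_minus_phi")
CONSTANT_POLICIES = ("neutral", "error")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labelled samples."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if not np.isfinite(self.values).all():
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if (self.values < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        # exact symmetry/zeros after validation
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.values[self.values < 0] = 0.0

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(list(df.index.astype(str)), df.to_numpy())

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square-matrix format (label, then full row)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValidationError(f"{name} is not a binary vector")
    return v.astype(np.int64)


def phi_coefficient(x, y) -> float:
    """Phi of two binary vectors; NaN when either vector is constant."""
    x = _check_binary(x, "x")
    y = _check_binary(y, "y")
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 2:
        raise ValidationError("vectors must have length >= 2")
    g = x.size
    a = int(np.sum(x & y))
    nx, ny = int(x.sum()), int(y.sum())
    b, c = nx - a, ny - a
    d = g - a - b - c
    denom2 = (a + b) * (c + d) * (a + c) * (b + d)
    if denom2 == 0:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(denom2))


def phi_matrix(m: PresenceMatrix) -> np.ndarray:
    """All-pairs phi among the rows of a presence matrix (NaN where undefined)."""
    x = m.values.astype(np.int64)
    g = x.shape[1]
    a = x @ x.T
    n1 = x.sum(axis=1)
    num = g * a - np.outer(n1, n1)  # = g*(ad-bc)/... numerator times g: g*a - n1_i*n1_j
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(
            np.outer(n1 * (g - n1), n1 * (g - n1)).astype(float)
        )
        phi = np.where(denom > 0, num / denom, np.nan)
    return phi


def phi_distance_matrix(
    m: PresenceMatrix,
    constant_policy: str = "neutral",
    transform: str = "half_one_minus_phi",
) -> DistanceMatrix:
    """Phi-based sample-by-sample distance matrix for a presence matrix.

    Computed on the full dataset-global genus universe: shared absences of
    genera never seen in the compared pair's family enter the 2x2 table,
    exactly as Pearson correlation on full patterns does.
    """
    if transform not in TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    if constant_policy not in CONSTANT_POLICIES:
        raise ValidationError(f"unknown constant_policy {constant_policy!r}")
    n, g = m.values.shape
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if g < 2:
        raise ValidationError("need at least 2 genus columns")

    phi = phi_matrix(m)
    undef = np.isnan(phi)
    np.fill_diagonal(undef, False)
    if undef.any():
        if constant_policy == "error":
            rows = sorted({m.sample_ids[i] for i in np.where(undef.any(axis=1))[0]})
            raise ValidationError(
                "constant pattern rows make phi undefined: " + ", ".join(rows))
        n_const = int((m.values.std(axis=1) == 0).sum())
        logger.warning(
            "%d constant pattern row(s); undefined phi treated as 0 "
            "(distance %s)", n_const,
            "0.5" if transform == "half_one_minus_phi" else "1.0")
        phi = np.where(undef, 0.0, phi)
        # identical constant rows are still identical patterns -> phi 1
        same = (m.values[:, None, :] == m.values[None, :, :]).all(axis=2)
        phi = np.where(undef & same, 1.0, phi)

    if transform == "half_one_minus_phi":
        d = (1.0 - phi) / 2.0
    else:
        d = 1.0 - phi
    np.fill_diagonal(d, 0.0)
    d[np.abs(d) < 1e-15] = 0.0
    return DistanceMatrix(list(m.sample_ids), d)
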