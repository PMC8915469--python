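"""Within-family heterogeneity trajectories and exact rank-sum tests.

*Heterogeneity* of a family at a time point is the arithmetic mean of the
pairwise distances among that family's samples collected then — a simple
group-dispersion measure. Convergence of the litter flora shows up as this
quantity shrinking from birth (T0) to day 60 (T60).

The comparison against birth is an unpaired two-sample Wilcoxon rank-sum
test, computed exactly: the null distribution of the rank-sum statistic is
obtained by full enumeration of all C(n_a+n_b, n_a) assignments of the
observed mid-ranks to group A, so the null is conditional on the observed
tie pattern. With 6 families per group the enumeration has C(12,6) = 924
terms and the smallest attainable two-sided p is 2/924 ~ 0.0022.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .records import (
    POST_BIRTH,
    MatrixType,
    SampleMeta,
    TimePoint,
    TIME_ORDER,
    ValidationError,
)
from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

#: Maximum number of enumerated group assignments before the normal
#: approximation (tie-corrected, continuity-corrected) takes over.
EXACT_ENUMERATION_LIMIT = 200_000

#: Matrix-type presets: the all-sample analysis and the rectal-only one
#: (meconium is the birth rectal swab of a puppy, so it belongs to both).
MATRIX_FILTERS: dict[str, set[MatrixType] | None] = {
    "all": None,
    "rectal_only": {MatrixType.RECTAL, MatrixType.MECONIUM},
}


def within_family_heterogeneity(
    dist: DistanceMatrix,
    samples: Sequence[SampleMeta],
    matrix_filter: Iterable[MatrixType] | str | None = None,
    include_dams: bool = True,
) -> pd.DataFrame:
    """Mean pairwise distance within each (family, time point) cell.

    Returns a DataFrame with columns ``family_id``, ``time_point``,
    ``n_samples`` and ``heterogeneity`` (NaN when fewer than two samples
    fall in the cell). ``matrix_filter`` is a preset name (``"all"``,
    ``"rectal_only"``) or an explicit set of matrix types; dams' samples are
    pooled with the litter's by default.
    """
    if isinstance(matrix_filter, str):
        if matrix_filter not in MATRIX_FILTERS:
            raise ValidationError(f"unknown matrix_filter preset {matrix_filter!r}")
        matrix_filter = MATRIX_FILTERS[matrix_filter]
    allowed = set(matrix_filter) if matrix_filter is not None else None

    pos = {lab: i for i, lab in enumerate(dist.labels)}
    selected = [
        s for s in samples
        if (allowed is None or s.matrix in allowed)
        and (include_dams or s.subject_role.value != "dam")
    ]
    missing = [s.sample_id for s in selected if s.sample_id not in pos]
    if missing:
        raise ValidationError(
            "distance matrix lacks sample(s): " + ", ".join(sorted(missing)))

    families = sorted({s.family_id for s in samples})
    rows = []
    for fam in families:
        fam_selected = [s for s in selected if s.family_id == fam]
        if not fam_selected:
            logger.warning("family %s has no samples after filtering", fam)
        for tp in TIME_ORDER:
            ids = [s.sample_id for s in fam_selected if s.time_point is tp]
            n = len(ids)
            if n >= 2:
                idx = [pos[i] for i in ids]
                sub = dist.values[np.ix_(idx, idx)]
                het = float(sub[np.triu_indices(n, k=1)].mean())
            else:
                het = float("nan")
            rows.append({"family_id": fam, "time_point": tp.value,
                         "n_samples": n, "heterogeneity": het})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample Wilcoxon rank-sum outcome.

    ``statistic_W`` is the rank-sum of group A under pooled mid-ranks;
    ``p_two_sided`` doubles the smaller exact tail, capped at 1.
    """

    statistic_W: float
    n_a: int
    n_b: int
    p_two_sided: float
    method: str  # "exact_enumeration" | "normal_approx"


def ranksum_exact(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Exact (enumeration) Wilcoxon rank-sum test of two independent samples.

    Falls back to a tie-corrected, continuity-corrected normal approximation
    only when the enumeration would exceed ``EXACT_ENUMERATION_LIMIT``
    assignments; the study-scale 6-vs-6 comparison is always exact.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite values in rank-sum input")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks for ties
    w_obs = float(ranks[:n_a].sum())

    if math.comb(n, n_a) <= EXACT_ENUMERATION_LIMIT:
        # enumerate every assignment of the observed mid-rank multiset
        total = math.comb(n, n_a)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(n), n_a):
            w = ranks[list(idx)].sum()
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return RankSumResult(w_obs, n_a, n_b, p, "exact_enumeration")

    # normal approximation with tie correction and continuity correction
    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return RankSumResult(w_obs, n_a, n_b, 1.0, "normal_approx")
    z_lo = (w_obs - mean + 0.5) / math.sqrt(var)
    z_hi = (w_obs - mean - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * min(norm.cdf(z_lo), norm.sf(z_hi)))
    return RankSumResult(w_obs, n_a, n_b, float(p), "normal_approx")


def holm_adjust(pvalues: Mapping[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a small family of p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adjusted[key] = running
    return adjusted


@dataclass(frozen=True)
class BirthComparison:
    """Rank-sum comparison of per-family heterogeneity at one time point
    against birth; ``testable`` is False when either group has fewer than
    two defined values."""

    time_point: str
    result: RankSumResult | None
    testable: bool
    n_t: int
    n_t0: int

    @property
    def p(self) -> float | None:
        return self.result.p_two_sided if self.result else None


def compare_to_birth(
    het: pd.DataFrame,
    holm: bool = False,
) -> dict[str, BirthComparison]:
    """Rank-sum tests of per-family heterogeneity at T2/T30/T60 versus T0.

    Unpaired comparisons of the family-level heterogeneity values; raw
    two-sided p by default, optional Holm adjustment across the three
    comparisons."""
    def values_at(tp: TimePoint) -> np.ndarray:
        sub = het[(het["time_point"] == tp.value) & het["heterogeneity"].notna()]
        return sub["heterogeneity"].to_numpy(dtype=float)

    t0 = values_at(TimePoint.T0)
    out: dict[str, BirthComparison] = {}
    for tp in POST_BIRTH:
        vals = values_at(tp)
        if len(t0) < 2 or len(vals) < 2:
            out[tp.value] = BirthComparison(tp.value, None, False,
                                            len(vals), len(t0))
            continue
        res = ranksum_exact(vals, t0)
        out[tp.value] = BirthComparison(tp.value, res, True, len(vals), len(t0))
    if holm:
        raw = {k: c.p for k, c in out.items() if c.testable}
        adj = holm_adjust(raw)
        for k, padj in adj.items():
            c = out[k]
            out[k] = BirthComparison(
                c.time_point,
                RankSumResult(c.result.statistic_W, c.result.n_a, c.result.n_b,
                              padj, c.result.method),
                True, c.n_t, c.n_t0)
    return out
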