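"""Optional rendering of dendrograms and 2DS scatter plots.

Thin layer over matplotlib; the tested artifacts are the tree structures
and coordinate tables, not these figures.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .cluster import LinkageTree
from .ordination import OrdinationResult
from .records import SampleMeta, SubjectRole, TimePoint, TIME_ORDER

_TP_STYLE = {  # time point -> (marker, polygon grey level)
    TimePoint.T0: ("o", "1.0"),
    TimePoint.T2: ("s", "0.8"),
    TimePoint.T30: ("D", "0.55"),
    TimePoint.T60: ("^", "0.25"),
}


def plot_dendrogram(tree: LinkageTree, path: str | Path,
                    title: str = "") -> None:
    """Render a family dendrogram; T0 leaves are suffixed '>' and T60 '>>'
    so the birth and day-60 samples can be told apart at a glance."""

    def label(leaf: str) -> str:
        if leaf.endswith("T0"):
            return leaf + " >"
        if leaf.endswith("T60"):
            return leaf + " >>"
        return leaf

    fig, ax = plt.subplots(figsize=(7, 0.3 * tree.n_leaves + 2))
    _scipy_dendrogram(tree.to_scipy_linkage(),
                      labels=[label(l) for l in tree.leaves],
                      orientation="left", ax=ax, color_threshold=0)
    ax.set_xlabel("complete-linkage height")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ordination(ordination: OrdinationResult,
                    samples: Sequence[SampleMeta],
                    path: str | Path, title: str = "") -> None:
    """2DS scatter of one family with a convex polygon per time point;
    dams in white markers, puppies in black."""
    from shapely.geometry import MultiPoint

    meta = {s.sample_id: s for s in samples}
    fig, ax = plt.subplots(figsize=(6, 6))
    for tp in TIME_ORDER:
        marker, grey = _TP_STYLE[tp]
        pts = [(x, y, meta[lab]) for lab, (x, y) in
               zip(ordination.labels, ordination.coords)
               if lab in meta and meta[lab].time_point is tp]
        if not pts:
            continue
        hull = MultiPoint([(x, y) for x, y, _ in pts]).convex_hull
        if hull.geom_type == "Polygon":
            xs, ys = hull.exterior.xy
            ax.fill(xs, ys, color=grey, alpha=0.4, zorder=1)
        for x, y, s in pts:
            face = "white" if s.subject_role is SubjectRole.DAM else "black"
            ax.scatter(x, y, marker=marker, facecolors=face,
                       edgecolors="black", s=60, zorder=2)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    if title:
        ax.set_title(f"{title} (2-axis share {ordination.goodness:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
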