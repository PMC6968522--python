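"""Plot data and selection queries for D-score displays.

The four display kinds mirror the app: a per-participant points plot, a
histogram, a kernel-density curve, and histogram + density combined.  Every
plot carries horizontal (points) or vertical (distribution) reference lines
at the effect-size cutoffs +-0.15, +-0.35 and +-0.65.  ``build_plot``
returns renderer-agnostic data and can additionally render a PDF (or PNG)
via matplotlib; ``lookup_point`` and ``lookup_area`` are the batch
equivalents of clicking a point or brushing an area in the app.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedScoreError, ValidationError
from .io import _algorithm_number

PLOT_KINDS = ("points", "histogram", "density", "histogram_density")
ORDERINGS = ("none", "increasing", "decreasing")

#: Reference lines at the effect-size band edges.
REFERENCE_LINES = (-0.65, -0.35, -0.15, 0.15, 0.35, 0.65)

_KIND_NAME = {
    "points": "Point",
    "histogram": "Histogram",
    "density": "Density",
    "histogram_density": "HistogramDensity",
}
_ORDER_NAME = {"none": "Default", "increasing": "Increasing", "decreasing": "Decreasing"}


@dataclass(frozen=True)
class PlotSpec:
    """Display options: kind, point ordering, histogram bin count."""

    kind: str = "points"
    ordering: str = "none"  # applies to the points kind only
    bins: int = 30

    def __post_init__(self) -> None:
        if self.kind not in PLOT_KINDS:
            raise ValidationError(f"kind must be one of {PLOT_KINDS}, got {self.kind!r}")
        if self.ordering not in ORDERINGS:
            raise ValidationError(
                f"ordering must be one of {ORDERINGS}, got {self.ordering!r}"
            )
        if self.bins < 1:
            raise ValidationError(f"bins must be a positive integer, got {self.bins}")


def default_plot_filename(spec: PlotSpec, algorithm) -> str:
    """E.g. ``PointDefaultDscore3.pdf`` for the default points plot of D3."""
    n = _algorithm_number(algorithm)
    return f"{_KIND_NAME[spec.kind]}{_ORDER_NAME[spec.ordering]}Dscore{n}.pdf"


def _plotted(results: pd.DataFrame) -> pd.DataFrame:
    """Non-excluded participants with a defined D-score, original order."""
    sub = results
    if "excluded" in sub.columns:
        sub = sub.loc[~sub["excluded"].astype(bool)]
    sub = sub.loc[sub["dscore"].notna(), ["participant", "dscore"]]
    if sub.empty:
        raise UndefinedScoreError("no defined D-scores to plot")
    return sub.reset_index(drop=True)


def build_plot(
    results: pd.DataFrame,
    spec: PlotSpec,
    path: Optional[Union[str, Path]] = None,
    algorithm=None,
) -> dict:
    """Assemble plot data for one display kind; optionally render to file.

    Returns a dict with the plotted participants and, depending on the
    kind: ``points`` — (index, participant, dscore) triples in display
    order; ``histogram`` — ``bin_edges`` and ``counts``; ``density`` —
    ``grid`` and ``density`` (Gaussian kernel, Scott's plug-in bandwidth,
    integrating to ~1).  ``reference_lines`` is always present.
    """
    sub = _plotted(results)
    if spec.ordering != "none" and spec.kind == "points":
        sub = sub.sort_values(
            "dscore", ascending=spec.ordering == "increasing", kind="stable"
        ).reset_index(drop=True)
    d = sub["dscore"].to_numpy(dtype=float)
    data: dict = {
        "kind": spec.kind,
        "participants": sub["participant"].tolist(),
        "dscores": d.tolist(),
        "reference_lines": list(REFERENCE_LINES),
    }
    if spec.kind == "points":
        data["points"] = [
            (i + 1, p, float(v))
            for i, (p, v) in enumerate(zip(sub["participant"], d))
        ]
    if spec.kind in ("histogram", "histogram_density"):
        counts, edges = np.histogram(d, bins=spec.bins)
        data["bin_edges"] = edges.tolist()
        data["counts"] = counts.tolist()
    if spec.kind in ("density", "histogram_density"):
        if d.size < 2 or np.std(d) == 0:
            raise UndefinedScoreError(
                "density estimate needs >= 2 distinct D-scores"
            )
        kde = sps.gaussian_kde(d)
        pad = 3.0 * kde.factor * d.std(ddof=1)
        grid = np.linspace(d.min() - pad, d.max() + pad, 512)
        data["grid"] = grid.tolist()
        data["density"] = kde(grid).tolist()
    if algorithm is not None:
        data["default_filename"] = default_plot_filename(spec, algorithm)
    if path is not None:
        _render(data, spec, path)
        data["file"] = str(path)
    return data


def _render(data: dict, spec: PlotSpec, path: Union[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    if spec.kind == "points":
        xs = [p[0] for p in data["points"]]
        ys = [p[2] for p in data["points"]]
        ax.scatter(xs, ys, s=18, color="#1f77b4", zorder=3)
        for y in data["reference_lines"]:
            ax.axhline(y, linestyle="--", linewidth=0.7, color="grey")
        ax.set_xlabel("participant")
        ax.set_ylabel("D-score")
    else:
        if "counts" in data:
            edges = np.asarray(data["bin_edges"])
            ax.hist(
                data["dscores"], bins=edges, density="density" in data,
                color="#1f77b4", alpha=0.6, edgecolor="white",
            )
        if "density" in data:
            ax.plot(data["grid"], data["density"], color="#d62728", linewidth=1.5)
        for x in data["reference_lines"]:
            ax.axvline(x, linestyle="--", linewidth=0.7, color="grey")
        ax.set_xlabel("D-score")
        ax.set_ylabel("density" if "density" in data else "count")
    ax.set_title(f"D-scores ({len(data['dscores'])} participants)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def lookup_point(
    results: pd.DataFrame, clicked_dscore: float, tolerance: float = 0.05
) -> Optional[tuple]:
    """Nearest plotted participant within ``tolerance`` of a clicked value.

    Ties are broken by participant ID order.  Returns ``(participant,
    dscore)`` or ``None`` when nothing lies within the tolerance.
    """
    sub = _plotted(results)
    dist = (sub["dscore"] - clicked_dscore).abs()
    mask = dist <= tolerance
    if not mask.any():
        return None
    within = sub.assign(dist=dist).loc[mask]
    best = within.sort_values(["dist", "participant"], kind="stable").iloc[0]
    return (best["participant"], float(best["dscore"]))


def lookup_area(
    results: pd.DataFrame,
    dscore_range: tuple,
    index_range: Optional[tuple] = None,
) -> list[tuple]:
    """All plotted participants inside a brushed area, sorted by D-score.

    ``dscore_range`` is a closed interval ``(low, high)``; ``index_range``
    optionally restricts the 1-based display positions as well.
    """
    sub = _plotted(results)
    lo, hi = dscore_range
    mask = (sub["dscore"] >= lo) & (sub["dscore"] <= hi)
    if index_range is not None:
        ilo, ihi = index_range
        idx = np.arange(1, len(sub) + 1)
        mask &= (idx >= ilo) & (idx <= ihi)
    hits = sub.loc[mask].sort_values("dscore", kind="stable")
    return [(p, float(v)) for p, v in zip(hits["participant"], hits["dscore"])]
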