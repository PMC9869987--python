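"""Grayscale determinant-selection plots.

The central graphic juxtaposes, per generic determinant, a wide bar
(the composite mean, read against the Likert scale on the left axis)
overlaid with narrow bars (the subdeterminant item means, with the gap
between item mean and composite mean shaded light gray), and a
meta-analysis-style diamond showing the confidence interval of the
determinant-target correlation, read against a [-1, 1] axis on the
right. No color, no raw data points: the graphic is deliberately lean.

Plot construction is split from rendering: ``build_*`` functions
return declarative, backend-free :class:`PlotModel` objects whose
element lists are directly testable (counts, coordinates, shades);
:func:`render` is the only matplotlib-dependent step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import DeterminantSummary, ExpertEstimateSet, LikertScale
from .estimators import ExpertAggregate, QComparison, aggregate_expert_estimates

__all__ = [
    "FigureStyle",
    "Bar",
    "ShadeSegment",
    "Diamond",
    "Dot",
    "Marker",
    "RefLine",
    "PlotModel",
    "PanelModel",
    "build_ciberlite_model",
    "build_panel",
    "build_q_panel",
    "build_expert_plot",
    "render",
]

SUPPORTED_FORMATS = ("png", "svg", "pdf")


@dataclass(frozen=True)
class FigureStyle:
    """Grayscale styling knobs (0 = black, 1 = white)."""

    wide_bar_gray: float = 0.45
    narrow_bar_gray: float = 0.25
    difference_gray: float = 0.85
    diamond_gray: float = 0.15
    narrow_to_wide_ratio: float = 0.25
    wide_bar_width: float = 0.8
    diamond_half_breadth: float = 0.18
    jitter_amplitude: float = 0.3
    jitter_seed: int = 0
    figsize: tuple[float, float] = (7.0, 4.5)

    def __post_init__(self) -> None:
        grays = {self.wide_bar_gray, self.narrow_bar_gray, self.difference_gray}
        if len(grays) != 3:
            raise ValueError("wide-bar, narrow-bar and difference grays must be distinct")
        if not (0 < self.narrow_to_wide_ratio < 1):
            raise ValueError("narrow bars must be narrower than wide bars")


@dataclass(frozen=True)
class Bar:
    x: float
    width: float
    bottom: float
    top: float
    gray: float
    role: str  # "generic" | "item"
    label: str


@dataclass(frozen=True)
class ShadeSegment:
    """Light-gray band marking |item mean - generic mean| on a narrow bar."""

    x: float
    width: float
    y0: float
    y1: float
    gray: float


@dataclass(frozen=True)
class Diamond:
    """Meta-analysis-style CI diamond along a named axis.

    ``lower``/``upper`` are the CI bounds and ``point`` the estimate,
    all in the units of ``axis``; the extreme vertices sit at the
    bounds and the widest point at the estimate.
    """

    x: float
    lower: float
    upper: float
    point: float
    axis: str  # "correlation" | "q" | "value"
    gray: float
    half_breadth: float

    def vertices(self) -> list[tuple[float, float]]:
        """(x, axis-value) polygon: bound - widest-point - bound - widest-point."""
        return [
            (self.x, self.lower),
            (self.x + self.half_breadth, self.point),
            (self.x, self.upper),
            (self.x - self.half_breadth, self.point),
        ]


@dataclass(frozen=True)
class Dot:
    x: float
    y: float


@dataclass(frozen=True)
class Marker:
    """Black observed-mean marker (diamond glyph plus a horizontal tick)."""

    x: float
    y: float
    half_width: float


@dataclass(frozen=True)
class RefLine:
    value: float
    axis: str


@dataclass
class PlotModel:
    """Declarative plot description, independent of any backend."""

    kind: str
    bars: list[Bar] = field(default_factory=list)
    shades: list[ShadeSegment] = field(default_factory=list)
    diamonds: list[Diamond] = field(default_factory=list)
    dots: list[Dot] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)
    ref_lines: list[RefLine] = field(default_factory=list)
    top_labels: list[tuple[float, str]] = field(default_factory=list)
    bottom_labels: list[tuple[float, str]] = field(default_factory=list)
    subtitle: str = ""
    mean_range: tuple[float, float] = (1.0, 5.0)
    corr_range: tuple[float, float] = (-1.0, 1.0)
    value_range: tuple[float, float] | None = None

    def corr_to_mean_axis(self, r: float) -> float:
        """Affine map from the correlation axis onto the bar (mean) axis."""
        c0, c1 = self.corr_range
        m0, m1 = self.mean_range
        return m0 + (r - c0) / (c1 - c0) * (m1 - m0)

    def mean_axis_to_corr(self, y: float) -> float:
        c0, c1 = self.corr_range
        m0, m1 = self.mean_range
        return c0 + (y - m0) / (m1 - m0) * (c1 - c0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PanelModel:
    """Grid of plot models with shared axes and per-cell subtitles."""

    models: list[PlotModel]
    nrows: int
    ncols: int

    def to_dict(self) -> dict:
        return {
            "nrows": self.nrows,
            "ncols": self.ncols,
            "models": [m.to_dict() for m in self.models],
        }


def _abbrev(label: str) -> str:
    words = [w for w in label.replace("_", " ").split() if w]
    if len(words) == 1 and len(words[0]) <= 4:
        return words[0].capitalize()
    if len(words) > 1:
        return "".join(w[0].upper() for w in words)
    return words[0][:3].capitalize()


def build_ciberlite_model(
    summary: DeterminantSummary, style: FigureStyle | None = None
) -> PlotModel:
    """One wide bar + narrow item bars + one correlation diamond per determinant."""
    style = style or FigureStyle()
    scale = summary.scale
    model = PlotModel(
        kind="ciberlite",
        subtitle=summary.behavior_label,
        mean_range=(float(scale.minimum), float(scale.maximum)),
        corr_range=(-1.0, 1.0),
    )
    model.ref_lines.append(RefLine(value=0.0, axis="correlation"))
    wide_w = style.wide_bar_width
    narrow_w = wide_w * style.narrow_to_wide_ratio
    for i, block in enumerate(summary.blocks):
        x = float(i)
        model.bars.append(
            Bar(
                x=x,
                width=wide_w,
                bottom=float(scale.minimum),
                top=block.generic_mean,
                gray=style.wide_bar_gray,
                role="generic",
                label=block.label,
            )
        )
        model.bottom_labels.append((x, _abbrev(block.label)))
        k = len(block.item_means)
        offsets = (np.arange(k) - (k - 1) / 2) * (wide_w / max(k, 1))
        for off, (sub_label, m) in zip(offsets, block.item_means):
            xi = x + float(off)
            model.bars.append(
                Bar(
                    x=xi,
                    width=narrow_w,
                    bottom=float(scale.minimum),
                    top=m,
                    gray=style.narrow_bar_gray,
                    role="item",
                    label=sub_label,
                )
            )
            model.top_labels.append((xi, _abbrev(sub_label)))
            lo, hi = sorted((m, block.generic_mean))
            if hi > lo:
                model.shades.append(
                    ShadeSegment(x=xi, width=narrow_w, y0=lo, y1=hi, gray=style.difference_gray)
                )
        ci = block.correlation.ci
        if not (-1.0 <= ci.lower <= ci.upper <= 1.0):
            raise ValueError(f"{block.label}: correlation CI outside [-1, 1]")
        model.diamonds.append(
            Diamond(
                x=x,
                lower=ci.lower,
                upper=ci.upper,
                point=block.correlation.r,
                axis="correlation",
                gray=style.diamond_gray,
                half_breadth=style.diamond_half_breadth,
            )
        )
    return model


def build_panel(
    summaries: Sequence[DeterminantSummary],
    style: FigureStyle | None = None,
    ncols: int | None = None,
) -> PanelModel:
    """Shared-axis grid of per-behavior plots, one subtitle each."""
    if not summaries:
        raise ValueError("need at least one summary")
    models = [build_ciberlite_model(s, style) for s in summaries]
    n = len(models)
    if ncols is None:
        ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    return PanelModel(models=models, nrows=nrows, ncols=ncols)


def build_q_panel(
    comparisons: Sequence[QComparison],
    labels: Sequence[str] | None = None,
    style: FigureStyle | None = None,
) -> PlotModel:
    """Diamonds for correlation differences on a q axis with a zero line.

    Diamonds, unlike whiskered error bars, do not draw the eye to the
    interval bounds; a comparison whose interval excludes zero shows as
    a diamond wholly on one side of the reference line.
    """
    style = style or FigureStyle()
    if labels is not None:
        if len(labels) != len(comparisons):
            raise ValueError(
                f"{len(labels)} labels for {len(comparisons)} comparisons"
            )
    else:
        labels = [
            "-".join(c.labels) if c.labels else f"pair{i + 1}"
            for i, c in enumerate(comparisons)
        ]
    model = PlotModel(kind="q_panel", value_range=None)
    model.ref_lines.append(RefLine(value=0.0, axis="q"))
    for i, (c, lab) in enumerate(zip(comparisons, labels)):
        model.diamonds.append(
            Diamond(
                x=float(i),
                lower=c.ci.lower,
                upper=c.ci.upper,
                point=c.q,
                axis="q",
                gray=style.diamond_gray,
                half_breadth=style.diamond_half_breadth,
            )
        )
        model.bottom_labels.append((float(i), lab))
    return model


def build_expert_plot(
    estimates: ExpertEstimateSet,
    observed: Sequence[DeterminantSummary],
    style: FigureStyle | None = None,
    aggregates: ExpertAggregate | None = None,
    level: float = 0.95,
) -> PlotModel:
    """Expert estimates against observed sample means, one column per parameter.

    Per (behavior, determinant) cell: one jittered dot per expert, a
    grey diamond spanning the CI of the experts' mean estimate, and a
    black marker at the observed sample mean.
    """
    style = style or FigureStyle()
    if aggregates is None:
        aggregates = aggregate_expert_estimates(estimates, level=level)

    observed_means: dict[tuple[str, str], float] = {}
    for summary in observed:
        for block in summary.blocks:
            observed_means[(summary.behavior_label, block.label)] = block.generic_mean
    missing = [c for c in estimates.cells if c not in observed_means]
    if missing:
        raise ValueError(f"no observed mean for cell(s): {missing[:5]}")

    scale = estimates.scale
    model = PlotModel(
        kind="expert",
        value_range=(float(scale.minimum), float(scale.maximum)),
        mean_range=(float(scale.minimum), float(scale.maximum)),
    )
    rng = np.random.default_rng(style.jitter_seed)
    for j, cell in enumerate(estimates.cells):
        x = float(j)
        jitter = rng.uniform(-style.jitter_amplitude, style.jitter_amplitude, size=estimates.n_experts)
        for e, dx in enumerate(jitter):
            model.dots.append(Dot(x=x + float(dx), y=float(estimates.values[e, j])))
        row = aggregates.table.iloc[j]
        model.diamonds.append(
            Diamond(
                x=x,
                lower=float(row["mean_lower"]),
                upper=float(row["mean_upper"]),
                point=float(row["mean"]),
                axis="value",
                gray=style.wide_bar_gray,
                half_breadth=style.diamond_half_breadth,
            )
        )
        model.markers.append(
            Marker(x=x, y=observed_means[cell], half_width=style.wide_bar_width / 2)
        )
        model.bottom_labels.append((x, f"{_abbrev(cell[0])}|{_abbrev(cell[1])}"))
    return model


# ---------------------------------------------------------------------------
# Rendering (the only backend-dependent step)


def _gray(g: float) -> str:
    return str(float(g))


def _render_model(ax, model: PlotModel) -> None:
    import matplotlib.patches as mpatches

    for bar in model.bars:
        ax.add_patch(
            mpatches.Rectangle(
                (bar.x - bar.width / 2, bar.bottom),
                bar.width,
                bar.top - bar.bottom,
                facecolor=_gray(bar.gray),
                edgecolor="none",
                zorder=2 if bar.role == "generic" else 3,
            )
        )
    for seg in model.shades:
        ax.add_patch(
            mpatches.Rectangle(
                (seg.x - seg.width / 2, seg.y0),
                seg.width,
                seg.y1 - seg.y0,
                facecolor=_gray(seg.gray),
                edgecolor="none",
                zorder=4,
            )
        )
    for line in model.ref_lines:
        y = model.corr_to_mean_axis(line.value) if line.axis == "correlation" else line.value
        ax.axhline(y, color="0.5", linewidth=0.6, linestyle=":", zorder=1)
    for d in model.diamonds:
        verts = d.vertices()
        if d.axis == "correlation":
            verts = [(x, model.corr_to_mean_axis(v)) for x, v in verts]
        ax.add_patch(
            mpatches.Polygon(verts, closed=True, facecolor=_gray(d.gray), edgecolor="none", zorder=5)
        )
    if model.dots:
        ax.plot(
            [p.x for p in model.dots],
            [p.y for p in model.dots],
            linestyle="none",
            marker=".",
            color="0.4",
            markersize=3,
            zorder=3,
        )
    for m in model.markers:
        ax.plot([m.x - m.half_width, m.x + m.half_width], [m.y, m.y], color="0", linewidth=1.0, zorder=6)
        ax.plot([m.x], [m.y], marker="D", color="0", markersize=4, zorder=6)

    if model.kind == "ciberlite":
        ax.set_ylim(*model.mean_range)
        right = ax.twinx()
        right.set_ylim(*model.corr_range)
        right.set_ylabel("r with target")
        ax.set_ylabel("mean")
    elif model.value_range is not None:
        ax.set_ylim(*model.value_range)
    if model.bottom_labels:
        xs, labs = zip(*model.bottom_labels)
        ax.set_xticks(xs, labs, fontsize=7, rotation=90 if model.kind == "expert" else 0)
    if model.top_labels:
        top = ax.secondary_xaxis("top")
        xs, labs = zip(*model.top_labels)
        top.set_xticks(xs, labs, fontsize=6)
    if model.subtitle:
        ax.set_title(model.subtitle, fontsize=8)


def render(model: PlotModel | PanelModel, path: str | Path, format: str | None = None) -> Path:
    """Write a plot model to PNG/SVG/PDF; deterministic given the model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    with matplotlib.rc_context({"svg.hashsalt": "ciberlite"}):
        if isinstance(model, PanelModel):
            fig, axes = plt.subplots(
                model.nrows,
                model.ncols,
                figsize=(3.2 * model.ncols, 2.6 * model.nrows),
                squeeze=False,
            )
            for ax in axes.ravel():
                ax.set_axis_off()
            for sub, ax in zip(model.models, axes.ravel()):
                ax.set_axis_on()
                _render_model(ax, sub)
            fig.tight_layout()
        else:
            fig, ax = plt.subplots(figsize=(7.0, 4.5))
            _render_model(ax, model)
            fig.tight_layout()
        try:
            fig.savefig(path, format=fmt, metadata={"Date": None} if fmt in ("svg", "pdf") else None)
        finally:
            plt.close(fig)
    return path
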