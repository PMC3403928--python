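"""Parallel-coordinates density rendering of parameter samples.

A q-dimensional parameter vector becomes a polyline across q equally
spaced vertical axes, each axis normalized to [0, 1] by its sample range.
Density is conveyed by translucent overplotting: with a small alpha
(default 0.03) high-density regions appear saturated and the overlap of
two classes appears dark.  For a quantitative response either a colormap
on the polylines or a split into percentile classes (with a mean-polyline
overlay) is available.

Rendering is static (matplotlib); figures are deterministic given the
spec, the sample, and the fixed draw-order seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib
import numpy as np
from matplotlib.collections import LineCollection

from .functionals import PropertySample

__all__ = [
    "RenderSpec",
    "PercentilePartition",
    "AxisInfo",
    "to_polylines",
    "render_classes",
    "partition_by_percentile",
    "render_continuous",
]

logger = logging.getLogger(__name__)

#: default class colors: positive class (e.g. surviving cells) blue,
#: negative class (cells that crossed the threshold / died) red
DEFAULT_CLASS_COLORS = {1: "tab:blue", -1: "tab:red"}


@dataclass(frozen=True)
class RenderSpec:
    """Axis order, normalization and blending style of a plot."""

    axis_order: tuple[str, ...] | None = None
    alpha: float = 0.03
    class_colors: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COLORS))
    blend_mode: str = "alpha"
    log_axes: bool = False
    draw_order_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.blend_mode not in ("alpha", "additive"):
            raise ValueError("blend_mode must be 'alpha' or 'additive'")


@dataclass(frozen=True)
class PercentilePartition:
    """Non-overlapping percentile intervals of the quantitative response."""

    intervals: tuple[tuple[float, float], ...] = ((0, 10), (45, 55), (90, 100))

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if not 0 <= lo < hi <= 100:
                raise ValueError(f"invalid percentile interval ({lo}, {hi})")
        spans = sorted(self.intervals)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi:
                raise ValueError("percentile intervals overlap")


@dataclass
class AxisInfo:
    """Per-axis normalization: stored min/max make polylines invertible."""

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    log: bool = False

    def denormalize(self, vertices: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        x = self.mins + vertices * np.where(span > 0, span, 1.0)
        return np.exp(x) if self.log else x


def _resolve_order(
    spec: RenderSpec, names: Sequence[str]
) -> list[int]:
    if spec.axis_order is None:
        return list(range(len(names)))
    if sorted(spec.axis_order) != sorted(names):
        raise ValueError("axis_order must be a permutation of the parameter names")
    return [list(names).index(n) for n in spec.axis_order]


def to_polylines(
    parameters: np.ndarray,
    parameter_names: Sequence[str],
    spec: RenderSpec = RenderSpec(),
) -> tuple[np.ndarray, AxisInfo]:
    """Normalize each axis to [0, 1]; rows become polyline vertex heights.

    Returns ``(vertices, axis_info)`` with ``vertices`` of shape ``(N, q)``.
    A constant column has no range; it is pinned to 0.5 with a warning.
    """
    parameters = np.asarray(parameters, dtype=float)
    if parameters.size == 0:
        raise ValueError("cannot build polylines from an empty sample")
    order = _resolve_order(spec, parameter_names)
    x = parameters[:, order]
    names = [parameter_names[j] for j in order]
    if spec.log_axes:
        if np.any(x <= 0):
            raise ValueError("log axes require strictly positive values")
        x = np.log(x)
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    span = maxs - mins
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"constant axes pinned to 0.5: {[names[j] for j in np.flatnonzero(constant)]}"
        )
    vertices = np.where(constant, 0.5, (x - mins) / np.where(constant, 1.0, span))
    return vertices, AxisInfo(names, mins, maxs, log=spec.log_axes)


def _new_axes(n_axes: int, names: Sequence[str]):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.8 * n_axes + 1, 4.5))
    for k in range(n_axes):
        ax.axvline(k, color="0.6", lw=0.8, zorder=0)
    ax.set_xticks(range(n_axes), names)
    ax.set_xlim(-0.3, n_axes - 0.7)
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("normalized value")
    return fig, ax


def _segments(vertices: np.ndarray) -> np.ndarray:
    n, q = vertices.shape
    xs = np.tile(np.arange(q, dtype=float), (n, 1))
    return np.stack([xs, vertices], axis=-1)


def render_classes(
    s_delta: PropertySample,
    spec: RenderSpec = RenderSpec(),
    out=None,
):
    """Class-colored density plot of a qualitative sample.

    Both classes are drawn with per-line opacity ``spec.alpha``; the draw
    order is shuffled with a fixed seed so neither class systematically
    overpaints the other.
    """
    if s_delta.kind != "delta":
        raise ValueError("render_classes expects a qualitative (delta) sample")
    unknown = set(np.unique(s_delta.labels)) - set(spec.class_colors)
    if unknown:
        raise ValueError(f"no color configured for labels {sorted(unknown)}")
    vertices, info = to_polylines(s_delta.parameters, s_delta.parameter_names, spec)
    fig, ax = _new_axes(vertices.shape[1], info.names)
    rng = np.random.default_rng(spec.draw_order_seed)
    order = rng.permutation(len(vertices))
    colors = np.empty(len(vertices), dtype=object)
    for label, color in spec.class_colors.items():
        colors[s_delta.labels == label] = color
    lines = LineCollection(
        _segments(vertices[order]),
        colors=[colors[i] for i in order],
        linewidths=0.7,
        alpha=spec.alpha,
    )
    ax.add_collection(lines)
    handles = [
        matplotlib.lines.Line2D([], [], color=c, label=f"class {label:+d}")
        for label, c in spec.class_colors.items()
        if np.any(s_delta.labels == label)
    ]
    ax.legend(handles=handles, loc="upper right")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def partition_by_percentile(
    s_phi: PropertySample,
    partition: PercentilePartition = PercentilePartition(),
) -> list[tuple[PropertySample, np.ndarray]]:
    """Split a quantitative sample into percentile classes of its response.

    Returns one ``(subset, mean_parameter_vector)`` pair per interval;
    subsets are disjoint (half-open intervals, the last closed above) and
    empty subsets trigger a warning.
    """
    if s_phi.kind != "phi":
        raise ValueError("expected a quantitative (phi) sample")
    if len(s_phi) == 0:
        raise ValueError("sample is empty")
    phi = s_phi.values
    out = []
    for lo, hi in partition.intervals:
        lo_v, hi_v = np.percentile(phi, [lo, hi])
        mask = (phi >= lo_v) & ((phi <= hi_v) if hi == 100 else (phi < hi_v))
        if not mask.any():
            warnings.warn(f"percentile interval ({lo}, {hi}) selected no rows")
        subset = s_phi.subset(np.flatnonzero(mask))
        mean = (
            subset.parameters.mean(axis=0)
            if len(subset)
            else np.full(s_phi.parameters.shape[1], np.nan)
        )
        out.append((subset, mean))
    return out


def render_percentile_classes(
    s_phi: PropertySample,
    partition: PercentilePartition = PercentilePartition(),
    spec: RenderSpec = RenderSpec(alpha=0.08),
    out=None,
):
    """One panel per percentile class: member polylines plus mean overlay.

    All panels share the normalization of the full sample so that offsets
    between classes are comparable across panels.
    """
    import matplotlib.pyplot as plt

    vertices, info = to_polylines(s_phi.parameters, s_phi.parameter_names, spec)
    parts = partition_by_percentile(s_phi, partition)
    q = vertices.shape[1]
    fig, axes = plt.subplots(
        1, len(parts), figsize=(1.3 * q * len(parts) + 1, 4.0), sharey=True
    )
    axes = np.atleast_1d(axes)
    phi = s_phi.values
    for ax, ((lo, hi), (subset, _)) in zip(axes, zip(partition.intervals, parts)):
        lo_v, hi_v = np.percentile(phi, [lo, hi])
        mask = (phi >= lo_v) & ((phi <= hi_v) if hi == 100 else (phi < hi_v))
        sub_vertices = vertices[mask]
        for k in range(q):
            ax.axvline(k, color="0.6", lw=0.8, zorder=0)
        if len(sub_vertices):
            ax.add_collection(
                LineCollection(
                    _segments(sub_vertices),
                    colors="black",
                    linewidths=0.5,
                    alpha=spec.alpha,
                )
            )
            ax.plot(range(q), sub_vertices.mean(axis=0), color="tab:orange", lw=2.5)
        ax.set_xticks(range(q), info.names)
        ax.set_xlim(-0.3, q - 0.7)
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"{lo:g}–{hi:g}th percentile")
    axes[0].set_ylabel("normalized value")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def render_continuous(
    s_phi: PropertySample,
    spec: RenderSpec = RenderSpec(alpha=0.1),
    colormap: str = "viridis",
    out=None,
):
    """Color every polyline by its quantitative response; adds a colorbar."""
    if s_phi.kind != "phi":
        raise ValueError("expected a quantitative (phi) sample")
    if not np.all(np.isfinite(s_phi.values)):
        raise ValueError("response values must be finite")
    vertices, info = to_polylines(s_phi.parameters, s_phi.parameter_names, spec)
    fig, ax = _new_axes(vertices.shape[1], info.names)
    phi = s_phi.values
    span = phi.max() - phi.min()
    norm = matplotlib.colors.Normalize(
        vmin=phi.min(), vmax=phi.max() if span > 0 else phi.min() + 1
    )
    cmap = matplotlib.colormaps[colormap]
    rng = np.random.default_rng(spec.draw_order_seed)
    order = rng.permutation(len(vertices))
    lines = LineCollection(
        _segments(vertices[order]),
        colors=cmap(norm(phi[order])),
        linewidths=0.7,
        alpha=spec.alpha,
    )
    ax.add_collection(lines)
    fig.colorbar(
        matplotlib.cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=ax,
        label="response",
    )
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
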