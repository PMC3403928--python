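"""Decision and timing functionals on simulated trajectories.

Two functionals condense a trajectory into the properties under study:

* the *decision* functional maps a trajectory to ``+1`` if a designated
  species reaches a threshold anywhere in the evaluation window and ``-1``
  otherwise (a qualitative, fate-like property);
* the *timing* functional returns the earliest threshold-crossing time,
  defined only for trajectories that cross (a quantitative property).

Both are evaluated on the solver output grid and refined by local cubic
interpolation with root polishing, so the reported event times are not
quantized to the grid spacing.

``build_samples`` applies the functionals to a whole ensemble and packages
the results as labelled samples: one row of parameters with a ``+1/-1``
label (all cells) and one with a positive event time (crossing cells only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .distributions import ParameterMatrix
from .ensemble import TrajectorySet

__all__ = [
    "ThresholdSpec",
    "PropertySample",
    "decision_functional",
    "crossing_time",
    "build_samples",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Which species, which level, and how long to watch.

    ``death_offset`` (minutes) is an optional constant added to crossing
    times, for processes where commitment is declared a fixed delay after
    the molecular threshold is reached.  It defaults to 0: a constant
    offset shifts every event time equally and cannot change which
    parameters predict the timing.
    """

    species: int | str
    threshold: float
    horizon: float
    death_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if not self.horizon > 0:
            raise ValueError("horizon must be > 0")

    def species_index(self, state_names: Sequence[str] | None = None) -> int:
        if isinstance(self.species, str):
            if state_names is None:
                raise ValueError("state names needed to resolve a species name")
            return list(state_names).index(self.species)
        return int(self.species)


def _first_crossing(times: np.ndarray, y: np.ndarray, threshold: float) -> float | None:
    """Earliest t with y(t) >= threshold, refined between grid points.

    Grid crossings are bracketed and polished with a local cubic spline;
    tangential events (local maxima that only touch the threshold between
    grid points) are caught by polishing interior maxima.  Equality counts
    as crossing.
    """
    above = y >= threshold
    idx = np.flatnonzero(above)
    if idx.size:
        i = int(idx[0])
        if i == 0:
            return float(times[0])
        lo = max(0, i - 2)
        hi = min(len(times), i + 2)
        spline = CubicSpline(times[lo:hi], y[lo:hi])
        f = lambda t: spline(t) - threshold  # noqa: E731
        a, b = times[i - 1], times[i]
        try:
            if f(a) < 0 <= f(b):
                return float(brentq(f, a, b, xtol=1e-12))
        except ValueError:
            pass
        # spline disagrees with the grid near a kink; fall back to linear
        frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
        return float(a + frac * (b - a))
    # no grid point reaches the threshold: polish interior local maxima
    interior = np.flatnonzero((y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:])) + 1
    order = interior[np.argsort(-y[interior])][:5]
    for i in order:
        lo = max(0, i - 2)
        hi = min(len(times), i + 3)
        spline = CubicSpline(times[lo:hi], y[lo:hi])
        tt = np.linspace(times[lo], times[hi - 1], 50 * (hi - lo))
        yy = spline(tt)
        if yy.max() >= threshold:
            j = int(np.argmax(yy >= threshold))
            return float(tt[j])
    return None


def crossing_time(
    times: np.ndarray,
    trajectory: np.ndarray,
    spec: ThresholdSpec,
    state_names: Sequence[str] | None = None,
) -> float | None:
    """Earliest time the species reaches the threshold, or None.

    ``trajectory`` is either the 1-D series of the species itself or the
    full ``(n_points, n_states)`` solution.  ``death_offset`` (minutes) is
    added to the returned time (hours).  Crossings after the horizon are
    unobserved and yield None.
    """
    trajectory = np.asarray(trajectory)
    if trajectory.ndim == 2:
        j = spec.species_index(state_names)
        if not 0 <= j < trajectory.shape[1]:
            raise ValueError(f"species index {j} out of range")
        y = trajectory[:, j]
    else:
        y = trajectory
    mask = times <= spec.horizon + 1e-12
    t = _first_crossing(times[mask], y[mask], spec.threshold)
    if t is None:
        return None
    return t + spec.death_offset / 60.0


def decision_functional(
    times: np.ndarray,
    trajectory: np.ndarray,
    spec: ThresholdSpec,
    state_names: Sequence[str] | None = None,
) -> int:
    """``+1`` if the species' maximum over the window reaches the threshold."""
    return 1 if crossing_time(times, trajectory, spec, state_names) is not None else -1


@dataclass
class PropertySample:
    """Parameter rows paired with a qualitative label or quantitative value.

    ``kind="delta"`` carries labels in {-1, +1}; ``kind="phi"`` carries
    positive event times (hours) and, by construction, contains only rows
    whose trajectory crossed the threshold.
    """

    parameters: np.ndarray
    parameter_names: list[str]
    kind: str
    labels: np.ndarray | None = None
    values: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.parameters.ndim != 2:
            raise ValueError("parameters must be 2-D")
        if self.kind == "delta":
            if self.labels is None:
                raise ValueError("delta sample needs labels")
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.parameters.shape[0]:
                raise ValueError("label count does not match parameter rows")
            if self.labels.size and not np.all(np.isin(self.labels, (-1, 1))):
                raise ValueError("labels must be -1 or +1")
        elif self.kind == "phi":
            if self.values is None:
                raise ValueError("phi sample needs values")
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape[0] != self.parameters.shape[0]:
                raise ValueError("value count does not match parameter rows")
            if self.values.size and not np.all(self.values >= 0):
                raise ValueError("event times must be nonnegative")
        else:
            raise ValueError("kind must be 'delta' or 'phi'")

    def __len__(self) -> int:
        return self.parameters.shape[0]

    @property
    def response(self) -> np.ndarray:
        return self.labels if self.kind == "delta" else self.values

    def column(self, name: str) -> np.ndarray:
        return self.parameters[:, self.parameter_names.index(name)]

    def subset(self, index) -> "PropertySample":
        index = np.asarray(index)
        return PropertySample(
            self.parameters[index],
            self.parameter_names,
            self.kind,
            labels=None if self.labels is None else self.labels[index],
            values=None if self.values is None else self.values[index],
            provenance=dict(self.provenance),
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.parameters, columns=self.parameter_names)
        frame[self.kind] = self.response
        return frame

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + json.dumps({"kind": self.kind, **self.provenance}) + "\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PropertySample":
        provenance: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                try:
                    provenance = json.loads(first[1:].strip())
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: malformed provenance header") from exc
                frame = pd.read_csv(fh)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh)
        kind = provenance.pop("kind", None)
        if kind is None:
            kind = "delta" if "delta" in frame.columns else "phi"
        if kind not in frame.columns:
            raise ValueError(f"{path}: missing response column {kind!r}")
        response = frame.pop(kind)
        if response.isna().any():
            raise ValueError(f"{path}: NaN in the response column")
        return cls(
            frame.to_numpy(float),
            list(frame.columns),
            kind,
            labels=response.to_numpy(int) if kind == "delta" else None,
            values=response.to_numpy(float) if kind == "phi" else None,
            provenance=provenance,
        )


def build_samples(
    params: ParameterMatrix,
    trajectories: TrajectorySet,
    spec: ThresholdSpec,
    label_convention: str = "crossing_positive",
) -> tuple[PropertySample, PropertySample]:
    """Evaluate both functionals on an ensemble.

    Returns ``(s_delta, s_phi)``.  Under ``label_convention="crossing_positive"``
    the label is the decision functional itself (+1 = crossed); under
    ``"survival_positive"`` it is flipped, so that cells whose species never
    reaches the threshold — e.g. cells that survive an apoptotic stimulus —
    form the positive class.  ``s_phi`` holds the crossing cells only, with
    the crossing time (hours, plus any configured offset) as value.
    """
    if label_convention not in ("crossing_positive", "survival_positive"):
        raise ValueError(f"unknown label_convention {label_convention!r}")
    if len(params) != len(trajectories):
        raise ValueError("parameter matrix and trajectory set are misaligned")
    j = spec.species_index(trajectories.state_names)
    series = trajectories.species(j)
    n = len(params)
    labels = np.empty(n, dtype=int)
    times = np.full(n, np.nan)
    for i in range(n):
        t = crossing_time(trajectories.times, series[i], spec)
        if t is None:
            labels[i] = -1
        else:
            labels[i] = 1
            times[i] = t
    crossed = labels == 1
    delta = -labels if label_convention == "survival_positive" else labels
    provenance = {
        "seed": params.seed,
        "species": int(j),
        "threshold": spec.threshold,
        "horizon": spec.horizon,
        "death_offset": spec.death_offset,
        "label_convention": label_convention,
    }
    s_delta = PropertySample(
        params.values,
        list(params.parameter_names),
        "delta",
        labels=delta,
        provenance=provenance,
    )
    s_phi = PropertySample(
        params.values[crossed],
        list(params.parameter_names),
        "phi",
        values=times[crossed],
        provenance=provenance,
    )
    return s_delta, s_phi
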