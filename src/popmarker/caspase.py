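"""The heterogeneous caspase-cascade apoptosis model (bundled case study).

The single-cell model is the classic bistable caspase cascade: initiator
caspase 8 (C8 -> C8a) activates effector caspase 3 (C3 -> C3a); C3a feeds
back onto C8; the inhibitors IAP (binds and degrades with C3a) and CARP
(binds C8a) stabilize the "life" state.  All eight species are produced
and degraded by first-order turnover, so the unstimulated cell has a
stable resting state with zero active caspases.  A sufficiently large
initial amount of active caspase 8, C8a(0), switches the cascade on and
the cell commits to apoptosis when free C3a reaches 5,000 copies within
the 12 h observation window.

Cell-to-cell variability enters through five log-normally distributed
quantities (all CV 0.4): the four synthesis rates km8 (IAP), km9 (C8),
km10 (C3), km12 (CARP) with means at their published values, and the
stimulus C8a(0) with median 4,000 molecules.  Each cell starts from its
own resting state (determined by its synthesis rates) plus its sampled
C8a(0).

Rate constants live in ``data/caspase_constants.yaml`` (molecules &
minutes); the simulation interface is in hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .distributions import LogNormalSpec, ParameterMatrix, PopulationSpec
from .ensemble import SimulationGrid, SingleCellModel, simulate_ensemble
from .functionals import PropertySample, ThresholdSpec, build_samples
from .markers import MarkerSet, SVSettings, evaluate_combinations

__all__ = [
    "CaspaseConfig",
    "caspase_constants",
    "caspase_model",
    "build_caspase_population",
    "run_case_study",
]

logger = logging.getLogger(__name__)

STATE_NAMES = ["C8", "C8a", "C3", "C3a", "IAP", "C3a_IAP", "CARP", "C8a_CARP"]

#: heterogeneous parameters, in the fixed column order of the case study
VARYING_NAMES = ["C8a0", "km8", "km9", "km10", "km12"]

#: rate-constant order inside the parameter vector (after C8a0)
CONSTANT_ORDER = [
    "km8", "km9", "km10", "km12",
    "k8", "k9", "k10", "k12",
    "k_act_c8", "k_act_c3",
    "k_bind_c3a_iap", "k_unbind_c3a_iap", "k_degbind_iap",
    "k_bind_c8a_carp", "k_unbind_c8a_carp",
    "k_deg_c8a", "k_deg_c3a", "k_deg_c3a_iap", "k_deg_c8a_carp",
]

PARAMETER_NAMES = ["C8a0"] + CONSTANT_ORDER

_MIN_PER_H = 60.0  # constants are per minute, the interface is hours


@dataclass(frozen=True)
class CaspaseConfig:
    """Case-study configuration: heterogeneity, threshold, horizon."""

    c8a0_median: float = 4000.0
    cv: float = 0.4
    c3a_threshold: float = 5000.0
    horizon: float = 12.0
    rate_constants: dict = field(default_factory=lambda: dict(caspase_constants()))

    def __post_init__(self) -> None:
        missing = [k for k in CONSTANT_ORDER if k not in self.rate_constants]
        if missing:
            raise ValueError(f"missing rate constants: {missing}")
        for name in CONSTANT_ORDER:
            v = self.rate_constants[name]
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"rate constant {name} must be finite and > 0, got {v}")

    def threshold_spec(self) -> ThresholdSpec:
        return ThresholdSpec(
            species=STATE_NAMES.index("C3a"),
            threshold=self.c3a_threshold,
            horizon=self.horizon,
        )


def caspase_constants(path: str | Path | None = None) -> dict[str, float]:
    """Load the kinetic constants (molecules & minutes) from the YAML file."""
    if path is None:
        source = resources.files("popmarker.data") / "caspase_constants.yaml"
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    constants = {}
    for name, entry in raw["constants"].items():
        value = float(entry["value"])
        if not np.isfinite(value):
            raise ValueError(f"rate constant {name} is not finite")
        constants[name] = value
    return constants


@njit(cache=True)
def _rhs_tx(t, x, p):  # pragma: no cover - exercised through the solver
    # p follows PARAMETER_NAMES; constants are per minute, output per hour
    km8, km9, km10, km12 = p[1], p[2], p[3], p[4]
    k8, k9, k10, k12 = p[5], p[6], p[7], p[8]
    ka8, ka3 = p[9], p[10]
    kb3, ku3, kdb = p[11], p[12], p[13]
    kb8, ku8 = p[14], p[15]
    d8a, d3a, d3ai, d8ac = p[16], p[17], p[18], p[19]
    C8, C8a, C3, C3a, IAP, C3aIAP, CARP, C8aCARP = (
        x[0], x[1], x[2], x[3], x[4], x[5], x[6], x[7]
    )
    v_act8 = ka8 * C8 * C3a
    v_act3 = ka3 * C3 * C8a
    v_bind3 = kb3 * C3a * IAP - ku3 * C3aIAP
    v_degb = kdb * C3a * IAP
    v_bind8 = kb8 * C8a * CARP - ku8 * C8aCARP
    out = np.empty(8)
    out[0] = -v_act8 + km9 - k9 * C8
    out[1] = v_act8 - v_bind8 - d8a * C8a
    out[2] = -v_act3 + km10 - k10 * C3
    out[3] = v_act3 - v_bind3 - d3a * C3a
    out[4] = -v_bind3 - v_degb + km8 - k8 * IAP
    out[5] = v_bind3 - d3ai * C3aIAP
    out[6] = -v_bind8 + km12 - k12 * CARP
    out[7] = v_bind8 - d8ac * C8aCARP
    return out * 60.0


@njit(cache=True)
def _jac_tx(t, x, p):  # pragma: no cover - exercised through the solver
    km8, km9, km10, km12 = p[1], p[2], p[3], p[4]
    k8, k9, k10, k12 = p[5], p[6], p[7], p[8]
    ka8, ka3 = p[9], p[10]
    kb3, ku3, kdb = p[11], p[12], p[13]
    kb8, ku8 = p[14], p[15]
    d8a, d3a, d3ai, d8ac = p[16], p[17], p[18], p[19]
    C8, C8a, C3, C3a, IAP, C3aIAP, CARP, C8aCARP = (
        x[0], x[1], x[2], x[3], x[4], x[5], x[6], x[7]
    )
    J = np.zeros((8, 8))
    # dC8/dt = -ka8*C8*C3a + km9 - k9*C8
    J[0, 0] = -ka8 * C3a - k9
    J[0, 3] = -ka8 * C8
    # dC8a/dt = ka8*C8*C3a - kb8*C8a*CARP + ku8*C8aCARP - d8a*C8a
    J[1, 0] = ka8 * C3a
    J[1, 1] = -kb8 * CARP - d8a
    J[1, 3] = ka8 * C8
    J[1, 6] = -kb8 * C8a
    J[1, 7] = ku8
    # dC3/dt = -ka3*C3*C8a + km10 - k10*C3
    J[2, 1] = -ka3 * C3
    J[2, 2] = -ka3 * C8a - k10
    # dC3a/dt = ka3*C3*C8a - kb3*C3a*IAP + ku3*C3aIAP - d3a*C3a
    J[3, 1] = ka3 * C3
    J[3, 2] = ka3 * C8a
    J[3, 3] = -kb3 * IAP - d3a
    J[3, 4] = -kb3 * C3a
    J[3, 5] = ku3
    # dIAP/dt = -(kb3+kdb)*C3a*IAP + ku3*C3aIAP + km8 - k8*IAP
    J[4, 3] = -(kb3 + kdb) * IAP
    J[4, 4] = -(kb3 + kdb) * C3a - k8
    J[4, 5] = ku3
    # dC3aIAP/dt = kb3*C3a*IAP - ku3*C3aIAP - d3ai*C3aIAP
    J[5, 3] = kb3 * IAP
    J[5, 4] = kb3 * C3a
    J[5, 5] = -ku3 - d3ai
    # dCARP/dt = -kb8*C8a*CARP + ku8*C8aCARP + km12 - k12*CARP
    J[6, 1] = -kb8 * CARP
    J[6, 6] = -kb8 * C8a - k12
    J[6, 7] = ku8
    # dC8aCARP/dt = kb8*C8a*CARP - ku8*C8aCARP - d8ac*C8aCARP
    J[7, 1] = kb8 * CARP
    J[7, 6] = kb8 * C8a
    J[7, 7] = -ku8 - d8ac
    return J * 60.0


def _initial_map(theta: np.ndarray) -> np.ndarray:
    """Per-cell resting state plus the sampled stimulus.

    With all active species at zero the turnover equations decouple, so
    the unstimulated fixed point is synthesis/degradation for each of C8,
    C3, IAP and CARP; C8a is then overwritten with the cell's C8a(0).
    """
    c8a0, km8, km9, km10, km12, k8, k9, k10, k12 = theta[:9]
    x0 = np.zeros(8)
    x0[0] = km9 / k9
    x0[1] = c8a0
    x0[2] = km10 / k10
    x0[4] = km8 / k8
    x0[6] = km12 / k12
    return x0


def caspase_model(constants: dict[str, float] | None = None) -> SingleCellModel:
    """Build the single-cell caspase model (time unit: hours)."""
    constants = caspase_constants() if constants is None else dict(constants)
    missing = [k for k in CONSTANT_ORDER if k not in constants]
    if missing:
        raise ValueError(f"missing rate constants: {missing}")
    return SingleCellModel(
        name="caspase",
        state_names=STATE_NAMES,
        parameter_names=PARAMETER_NAMES,
        rhs=lambda x, p: _rhs_tx(0.0, np.asarray(x, float), np.asarray(p, float)),
        jac=lambda x, p: _jac_tx(0.0, np.asarray(x, float), np.asarray(p, float)),
        initial_map=_initial_map,
        rhs_tx=_rhs_tx,
        jac_tx=_jac_tx,
    )


def build_caspase_population(
    seed: int, n: int, config: CaspaseConfig | None = None
) -> PopulationSpec:
    """Population with the five heterogeneous parameters of the case study.

    Synthesis rates are log-normal with *mean* at the published constant
    and CV 0.4; the stimulus C8a(0) is log-normal with *median* 4,000 and
    CV 0.4.
    """
    if n <= 0:
        raise ValueError("ensemble size must be positive")
    config = config or CaspaseConfig()
    constants = config.rate_constants
    model = caspase_model(constants)
    varying = [
        LogNormalSpec("C8a0", config.c8a0_median, config.cv, "median"),
        LogNormalSpec("km8", constants["km8"], config.cv, "mean"),
        LogNormalSpec("km9", constants["km9"], config.cv, "mean"),
        LogNormalSpec("km10", constants["km10"], config.cv, "mean"),
        LogNormalSpec("km12", constants["km12"], config.cv, "mean"),
    ]
    fixed = {k: v for k, v in constants.items() if k not in VARYING_NAMES}
    return PopulationSpec(
        model=model, varying=varying, fixed=fixed, ensemble_size=n, seed=seed
    )


def simulate_caspase_samples(
    seed: int,
    n: int,
    config: CaspaseConfig | None = None,
    grid: SimulationGrid | None = None,
) -> tuple[PropertySample, PropertySample]:
    """Simulate an ensemble and build the survival/death-time samples.

    Labels follow the survival-positive convention: ``+1`` = the cell's
    free C3a never reached the threshold (cell survived), ``-1`` = it did
    (cell died).  The quantitative sample holds the death times in hours
    for the dying cells.
    """
    config = config or CaspaseConfig()
    grid = grid or SimulationGrid(t_end=config.horizon, n_points=721)
    pop = build_caspase_population(seed, n, config)
    params = pop.sample()
    trajectories = simulate_ensemble(pop.model, pop.full_matrix(params), grid)
    trajectories.parameter_matrix = params
    s_delta, s_phi = build_samples(
        params, trajectories, config.threshold_spec(),
        label_convention="survival_positive",
    )
    logger.info(
        "caspase ensemble (seed %d, N=%d): %.1f%% of cells died",
        seed, n, 100.0 * (s_delta.labels == -1).mean(),
    )
    return s_delta, s_phi


@dataclass
class CaseStudyResult:
    s_delta_train: PropertySample
    s_phi_train: PropertySample
    s_delta_test: PropertySample
    s_phi_test: PropertySample
    report: "pd.DataFrame"  # noqa: F821 - pandas imported via markers


def run_case_study(
    n_train: int = 10_000,
    n_test: int = 10_000,
    seed: int = 1,
    config: CaspaseConfig | None = None,
    settings: SVSettings | None = None,
    sizes: tuple[int, ...] = (1, 2),
    include_triplets: bool = True,
    regression: bool = True,
    phi_train_cap: int | None = None,
    outdir: str | Path | None = None,
) -> CaseStudyResult:
    """Full marker analysis of the apoptosis decision and the death time.

    Simulates disjoint training and test ensembles (seeds derived from
    ``seed``), scores every single marker and pair (classification TP/FP/
    AUC and, optionally, death-time regression error quantiles), plus the
    triplets extending the best pair.  Returns samples and the report
    table; when ``outdir`` is given, samples, report and figures are
    written there.
    """
    settings = settings or SVSettings()
    root = np.random.SeedSequence(seed)
    seed_train, seed_test = (int(s.generate_state(1)[0] >> 1) for s in root.spawn(2))
    s_delta_train, s_phi_train = simulate_caspase_samples(seed_train, n_train, config)
    s_delta_test, s_phi_test = simulate_caspase_samples(seed_test, n_test, config)

    if phi_train_cap is not None and len(s_phi_train) > phi_train_cap:
        keep = np.random.default_rng(seed).choice(
            len(s_phi_train), phi_train_cap, replace=False
        )
        s_phi_train_fit = s_phi_train.subset(np.sort(keep))
    else:
        s_phi_train_fit = s_phi_train

    report = evaluate_combinations(
        s_delta_train,
        s_delta_test,
        sizes=sizes,
        settings=settings,
        train_phi=s_phi_train_fit if regression else None,
        test_phi=s_phi_test if regression else None,
        seed=seed,
    )
    if include_triplets and max(sizes) >= 2:
        pairs = report[report["size"] == 2]
        best_pair = pairs.iloc[0]["markers"].split("+")
        names = s_delta_train.parameter_names
        extras = [
            MarkerSet.from_names([*best_pair, other], names)
            for other in names
            if other not in best_pair
        ]
        triplet_report = evaluate_combinations(
            s_delta_train,
            s_delta_test,
            sizes=(),
            settings=settings,
            train_phi=s_phi_train_fit if regression else None,
            test_phi=s_phi_test if regression else None,
            extra_sets=extras,
            seed=seed,
        )
        import pandas as pd

        report = pd.concat([report, triplet_report], ignore_index=True)

    result = CaseStudyResult(
        s_delta_train, s_phi_train, s_delta_test, s_phi_test, report
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), seed)
    return result


def _write_outputs(result: CaseStudyResult, outdir: Path, seed: int) -> None:
    from .parcoords import (
        PercentilePartition,
        RenderSpec,
        render_classes,
        render_percentile_classes,
    )
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    result.s_delta_train.to_csv(outdir / "s_delta_train.csv")
    result.s_phi_train.to_csv(outdir / "s_phi_train.csv")
    result.s_delta_test.to_csv(outdir / "s_delta_test.csv")
    result.s_phi_test.to_csv(outdir / "s_phi_test.csv")
    result.report.to_csv(outdir / "marker_report.csv", index=False)
    fig = render_classes(result.s_delta_train, RenderSpec(), out=outdir / "classes.png")
    plt.close(fig)
    fig = render_percentile_classes(
        result.s_phi_train, PercentilePartition(), out=outdir / "percentiles.png"
    )
    plt.close(fig)
    logger.info("case-study outputs written to %s (seed %d)", outdir, seed)
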