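"""Feature-based kinetic parameter estimation.

The free constants of the pathway model are estimated against a set of
quantitative *features* (peak times, activation levels at stated times,
binned areas under the activation curve, relative amplitude changes),
each with an experimental tolerance.  One parameter set must satisfy the
whole feature suite simultaneously; there is no per-experiment re-tuning.

Estimation is bound-constrained trust-region least squares on
log-transformed parameters.  Rate constants span orders of magnitude, so
the conventional ten-fold uncertainty box becomes a symmetric interval in
log space.  Fitting proceeds in rounds, each restarting from the previous
optimum, until the standardized goodness of fit reaches R^2 > 0.6 or an
iteration cap is hit; non-convergence returns the best-so-far result
rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .network import NetworkError
from .params import load_params, provenance
from .pathway import StimulusConfig, build_model
from .simulate import (
    SolverError,
    activation_series,
    binned_auc,
    find_peaks,
    run,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSpec",
    "FeatureTarget",
    "FitResult",
    "feature_residuals",
    "fit",
    "provenance_report",
    "default_parameter_specs",
]

#: residual assigned to a failed simulation (large, finite, differentiable
#: nowhere — the optimizer backs away from such regions)
FAILURE_RESIDUAL = 1e3

FUNCTIONALS = (
    "value_at_time",
    "peak_time",
    "peak_amplitude",
    "argmax_time",
    "max_in_window",
    "binned_area",
    "relative_change",
    "synergy_gain",
)


@dataclass
class ParameterSpec:
    """One free (or frozen) kinetic parameter.

    Bounds default to the ten-fold box ``[initial/10, initial*10]``.
    ``provenance`` records where the seed value came from
    (published_model / analogous_pair / fitted).
    """

    name: str
    initial: float
    provenance: str = "fitted"
    bounds: tuple[float, float] | None = None
    frozen: bool = False

    def __post_init__(self):
        if self.bounds is None:
            self.bounds = (self.initial / 10.0, self.initial * 10.0)
        lo, hi = self.bounds
        if not (0 < lo <= self.initial <= hi):
            raise ValueError(
                f"{self.name}: bounds {self.bounds} must be positive and "
                f"bracket the initial value {self.initial}"
            )


@dataclass
class FeatureTarget:
    """One printed validation feature.

    ``functional`` selects how the simulated time course is reduced to a
    scalar; ``which_peak`` chooses the earliest ("first") or
    highest-amplitude ("main") detected peak where relevant.
    ``relative_change`` compares ``peak_amplitude`` between ``config`` and
    ``config_b`` as a percentage of the former.  ``one_sided`` marks bound
    features ("lower": the source states "> target"; "upper": "< target");
    values satisfying the bound contribute zero residual.
    """

    id: str
    config: StimulusConfig
    observable: str
    functional: str
    target: float
    tolerance: float
    time_min: float | None = None
    window_min: tuple[float, float] | None = None
    bin_min: tuple[float, float] | None = None
    which_peak: str = "main"
    horizon_min: float = 60.0
    config_b: StimulusConfig | None = None
    config_c: StimulusConfig | None = None
    one_sided: str | None = None  # None | "lower" | "upper"
    weight: float = 1.0
    citation: str = ""

    def __post_init__(self):
        if self.functional not in FUNCTIONALS:
            raise ValueError(f"unknown functional {self.functional!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        for t in filter(None, [self.time_min, self.bin_min and self.bin_min[1],
                               self.window_min and self.window_min[1]]):
            if t > self.horizon_min:
                raise ValueError(f"{self.id}: time window outside horizon")


class _SimCache:
    """One simulation per distinct (config, horizon) per parameter vector."""

    def __init__(self, params: dict, method: str, dt_out: float):
        self.params = params
        self.method = method
        self.dt_out = dt_out
        self._store: dict[tuple[str, float], object] = {}

    def timecourse(self, cfg: StimulusConfig, horizon_min: float):
        key = (cfg.digest(), float(horizon_min))
        if key not in self._store:
            net = build_model(cfg, params=self.params)
            self._store[key] = run(
                net, horizon_min * 60.0, method=self.method,
                dt_out=self.dt_out,
            )
        return self._store[key]


def _evaluate(target: FeatureTarget, cache: _SimCache) -> float:
    tc = cache.timecourse(target.config, target.horizon_min)
    series = activation_series(tc, target.observable)
    t = tc.times
    f = target.functional
    if f == "value_at_time":
        return float(np.interp(target.time_min * 60.0, t, series))
    if f == "max_in_window":
        a, b = target.window_min
        m = (t >= a * 60.0) & (t <= b * 60.0)
        return float(series[m].max())
    if f == "argmax_time":
        if target.window_min is not None:
            a, b = target.window_min
            m = (t >= a * 60.0) & (t <= b * 60.0)
            return float(t[m][np.argmax(series[m])] / 60.0)
        return float(t[np.argmax(series)] / 60.0)
    if f == "binned_area":
        a, b = target.bin_min
        return float(binned_auc(t, series, np.array([a, b]))[0])
    if f == "synergy_gain":
        # combo AUC minus the sum of the two single-mediator AUCs per bin
        a, b = target.bin_min
        edges = np.array([a, b])
        total = float(binned_auc(t, series, edges)[0])
        for cfg in (target.config_b, target.config_c):
            tc_s = cache.timecourse(cfg, target.horizon_min)
            s = activation_series(tc_s, target.observable)
            total -= float(binned_auc(tc_s.times, s, edges)[0])
        return total
    if f in ("peak_time", "peak_amplitude"):
        peaks = find_peaks(t, series)
        if not peaks:
            return np.nan
        if target.which_peak == "first":
            pk = peaks[0]
        else:
            pk = max(peaks, key=lambda p: p.amplitude)
        return pk.time_min if f == "peak_time" else pk.amplitude
    if f == "relative_change":
        peaks_a = find_peaks(t, series)
        tc_b = cache.timecourse(target.config_b, target.horizon_min)
        series_b = activation_series(tc_b, target.observable)
        peaks_b = find_peaks(tc_b.times, series_b)
        if not peaks_a or not peaks_b:
            return np.nan
        amp_a = max(p.amplitude for p in peaks_a)
        amp_b = max(p.amplitude for p in peaks_b)
        return 100.0 * (amp_b - amp_a) / amp_a
    raise AssertionError(f)


def feature_residuals(
    params: dict[str, float],
    targets: list[FeatureTarget],
    method: str = "RK45",
    dt_out: float = 1.0,
    return_values: bool = False,
):
    """Standardized residual vector ``(simulated - target) / tolerance``.

    A failed simulation contributes a large finite penalty residual for
    every feature that depends on it (and is logged), so the optimizer
    treats pathological parameter regions as bad fits rather than errors.
    """
    cache = _SimCache(params, method, dt_out)
    res = np.empty(len(targets))
    values = np.empty(len(targets))
    for i, tg in enumerate(targets):
        try:
            value = _evaluate(tg, cache)
        except (SolverError, NetworkError) as exc:
            logger.warning("feature %s: simulation failed (%s)", tg.id, exc)
            value = np.nan
        values[i] = value
        if np.isfinite(value):
            miss = value - tg.target
            if tg.one_sided == "lower":
                miss = min(miss, 0.0)
            elif tg.one_sided == "upper":
                miss = max(miss, 0.0)
            res[i] = tg.weight * miss / tg.tolerance
        else:
            res[i] = FAILURE_RESIDUAL
    if return_values:
        return res, values
    return res


def r_squared(residuals: np.ndarray, targets: list[FeatureTarget]) -> float:
    """R^2 over standardized features: 1 - SS_res / SS_tot, where the
    standardized observations are target/tolerance."""
    y = np.array([t.target / t.tolerance for t in targets])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(np.minimum(np.abs(residuals), FAILURE_RESIDUAL) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class FitResult:
    params: dict[str, float]
    residuals: np.ndarray
    values: np.ndarray
    r2: float
    converged: bool
    n_rounds: int
    cost_history: list[float] = field(default_factory=list)

    def summary(self, targets: list[FeatureTarget]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [t.id for t in targets],
                "target": [t.target for t in targets],
                "tolerance": [t.tolerance for t in targets],
                "simulated": self.values,
                "residual": self.residuals,
            }
        )


def fit(
    specs: list[ParameterSpec],
    targets: list[FeatureTarget],
    seed: int = 0,
    max_rounds: int = 3,
    max_nfev_per_round: int = 60,
    r2_stop: float = 0.6,
    method: str = "RK45",
    dt_out: float = 1.0,
    jitter: float = 0.0,
    diff_step: float = 0.08,
) -> FitResult:
    """Trust-region least squares on log-parameters within the bound boxes.

    Rounds restart from the previous optimum; fitting stops early once the
    standardized R^2 exceeds ``r2_stop``.  Deterministic for a given seed
    (the seed only matters when ``jitter > 0``, which perturbs the starting
    point of each round after the first).
    """
    free = [s for s in specs if not s.frozen]
    base = {s.name: s.initial for s in specs}

    def full_params(x_log: np.ndarray) -> dict[str, float]:
        p = dict(base)
        for s, v in zip(free, np.exp(x_log)):
            p[s.name] = float(v)
        return p

    if not free:
        res, values = feature_residuals(
            base, targets, method=method, dt_out=dt_out, return_values=True
        )
        r2 = r_squared(res, targets)
        return FitResult(base, res, values, r2, r2 > r2_stop, 0)

    rng = np.random.default_rng(seed)
    x = np.log([s.initial for s in free])
    lo = np.log([s.bounds[0] for s in free])
    hi = np.log([s.bounds[1] for s in free])

    def objective(x_log):
        return feature_residuals(
            full_params(x_log), targets, method=method, dt_out=dt_out
        )

    best_x, best_cost = x.copy(), float(np.sum(objective(x) ** 2))
    history = [best_cost]
    converged = False
    n_rounds = 0
    for rnd in range(max_rounds):
        n_rounds = rnd + 1
        x0 = best_x.copy()
        if rnd > 0 and jitter > 0:
            x0 = np.clip(x0 + rng.normal(0, jitter, x0.size), lo, hi)
        sol = least_squares(
            objective,
            x0,
            bounds=(lo, hi),
            method="trf",
            diff_step=diff_step,
            max_nfev=max_nfev_per_round,
        )
        if sol.cost * 2 < best_cost:
            best_cost = sol.cost * 2
            best_x = sol.x.copy()
        history.append(best_cost)
        res = objective(best_x)
        if r_squared(res, targets) > r2_stop:
            converged = True
            break
    params = full_params(best_x)
    res, values = feature_residuals(
        params, targets, method=method, dt_out=dt_out, return_values=True
    )
    r2 = r_squared(res, targets)
    return FitResult(params, res, values, r2, converged or r2 > r2_stop,
                     n_rounds, history)


def default_parameter_specs(
    fitted_only: bool = False,
) -> list[ParameterSpec]:
    """Specs for the full shipped table, frozen except the fitted class."""
    prov = provenance()
    table = load_params()
    specs = []
    for name, value in table.items():
        cls = prov[name]
        if fitted_only and cls != "fitted":
            specs.append(
                ParameterSpec(name, value, cls, frozen=True)
            )
        else:
            specs.append(ParameterSpec(name, value, cls))
    return specs


def provenance_report(specs: list[ParameterSpec]) -> pd.DataFrame:
    """Parameters by provenance class (the fitted class must stay a
    documented minority)."""
    rows = [
        {
            "name": s.name,
            "provenance": s.provenance,
            "initial": s.initial,
            "lower": s.bounds[0],
            "upper": s.bounds[1],
            "frozen": s.frozen,
        }
        for s in specs
    ]
    return pd.DataFrame(rows).sort_values(
        ["provenance", "name"]
    ).reset_index(drop=True)
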