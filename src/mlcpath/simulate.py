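"""Integrate reaction networks and extract derived observables.

The solver mirrors the classic MATLAB ``ode45`` setup used for signalling
models: an adaptive Dormand-Prince 4(5) pair with absolute tolerance 1e-6
and relative tolerance 1e-3, sampled on a fixed 1 s output grid.  If the
explicit pair fails (step-size collapse on a stiff transient) the run is
retried with LSODA and the fallback is logged.

Derived quantities are the ones the endothelial MLC model reports:
activation time courses, peak sets, 10-min binned areas under the
activation curve, and combination-vs-additive synergy tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks as _scipy_find_peaks

from .network import NetworkError, ReactionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourse",
    "Peak",
    "PeakSet",
    "SynergyTable",
    "SolverError",
    "run",
    "activation_series",
    "find_peaks",
    "binned_auc",
    "synergy_analysis",
    "timecourse_to_tidy",
    "timecourse_to_wide",
]

#: canonical observable names -> how to compute them from species columns
_RAW_OBSERVABLES = {
    "ppMLC": ("ppMLC",),
    "Ca_i": ("Ca_i",),
    "IP3": ("IP3",),
    "active_ERK": ("ERKpp",),
    "active_Rho": ("RhoGTP", "ROCKo", "ROCKa"),
    "active_ROCK": ("ROCKa",),
    "active_MLCK": ("MLCKa", "MLCKap"),
    "NO": ("NO",),
    "active_PKG": ("PKGa",),
}
_MLC_FORMS = ("MLC", "pMLC", "ppMLC")


class SolverError(RuntimeError):
    """Integration failed even after the stiff fallback."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class TimeCourse:
    """Solver output: time grid (s) plus all species trajectories (uM)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_species, n_times)
    network: ReactionNetwork
    solver_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.states.shape != (self.network.n_species, self.times.size):
            raise ValueError("states shape does not match times/network")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, species_id: str) -> np.ndarray:
        return self.states[self.network.species_index(species_id)]

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0


@dataclass
class Peak:
    time_min: float
    amplitude: float
    prominence: float


PeakSet = list  # list[Peak]


@dataclass
class SynergyTable:
    """Binned AUCs for a combination run vs. its two single-mediator runs.

    Areas are on the activation-fraction (0-1) scale in fraction x min, so a
    bin-mean activation of 59% over a 10-min bin gives an area of 5.9.
    ``net_gain = area_combo - (area_single_A + area_single_B)``; positive
    values indicate super-additive (synergistic) signalling.
    """

    bin_edges_min: np.ndarray
    area_combo: np.ndarray
    area_single_A: np.ndarray
    area_single_B: np.ndarray
    label_A: str = "A"
    label_B: str = "B"

    @property
    def additive_sum(self) -> np.ndarray:
        return self.area_single_A + self.area_single_B

    @property
    def net_gain(self) -> np.ndarray:
        return self.area_combo - self.additive_sum

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{int(a)}-{int(b)}"
            for a, b in zip(self.bin_edges_min[:-1], self.bin_edges_min[1:])
        ]
        return pd.DataFrame(
            [
                self.area_combo,
                self.area_single_A,
                self.area_single_B,
                self.additive_sum,
                self.net_gain,
            ],
            index=[
                "combo",
                self.label_A,
                self.label_B,
                "additive_sum",
                "net_gain",
            ],
            columns=cols,
        )


def run(
    net: ReactionNetwork,
    horizon: float,
    abstol: float = 1e-6,
    reltol: float = 1e-3,
    dt_out: float = 1.0,
    method: str = "RK45",
    y0: np.ndarray | None = None,
) -> TimeCourse:
    """Integrate ``net`` over ``[0, horizon]`` seconds.

    Parameters
    ----------
    net : ReactionNetwork
    horizon : float
        Simulation end time in seconds, > 0.
    abstol, reltol : float
        Solver tolerances (defaults 1e-6 / 1e-3).
    dt_out : float
        Output sampling interval in seconds (default 1 s grid).
    method : str
        "RK45" is the Dormand-Prince pair; on failure the run falls back
        to LSODA and the switch is logged.
    y0 : array, optional
        Initial state override (defaults to the network's initial
        concentrations).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if y0 is None:
        y0 = net.initial_state()
    t_eval = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    if t_eval[-1] > horizon:
        t_eval[-1] = horizon
    tried = [method]
    sol = solve_ivp(
        net.rhs,
        (0.0, float(horizon)),
        y0,
        method=method,
        t_eval=t_eval,
        atol=abstol,
        rtol=reltol,
    )
    if not sol.success and method != "LSODA":
        logger.warning(
            "solver %s failed (%s); falling back to LSODA", method, sol.message
        )
        tried.append("LSODA")
        sol = solve_ivp(
            net.rhs,
            (0.0, float(horizon)),
            y0,
            method="LSODA",
            t_eval=t_eval,
            atol=abstol,
            rtol=reltol,
        )
    if not sol.success:
        raise SolverError(
            f"integration failed: {sol.message}",
            t_fail=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    stats = {
        "method": tried[-1],
        "fallback": len(tried) > 1,
        "nfev": int(sol.nfev),
        "abstol": abstol,
        "reltol": reltol,
    }
    return TimeCourse(sol.t, sol.y, net, stats)


def activation_series(tc: TimeCourse, observable: str) -> np.ndarray:
    """Extract one observable trajectory from a time course.

    ``mlc_activation_pct`` is 100 * (pMLC + ppMLC) / total MLC pool (the
    pool is conserved, so the denominator is constant in time);
    ``ppmlc_pct`` is the di-phosphorylated fraction alone.  All other
    observables are raw concentrations in uM.
    """
    if observable in ("mlc_activation_pct", "ppmlc_pct"):
        try:
            forms = np.array(
                [tc.species(s) for s in _MLC_FORMS]
            )
        except NetworkError as exc:
            raise NetworkError(
                f"observable {observable!r} undefined for this network"
            ) from exc
        total = forms.sum(axis=0)
        if observable == "mlc_activation_pct":
            return 100.0 * (forms[1] + forms[2]) / total
        return 100.0 * forms[2] / total
    try:
        ids = _RAW_OBSERVABLES[observable]
    except KeyError:
        raise NetworkError(f"unknown observable {observable!r}") from None
    try:
        return sum(tc.species(s) for s in ids)
    except NetworkError as exc:
        raise NetworkError(
            f"observable {observable!r} undefined for this network"
        ) from exc


def find_peaks(
    times_s: np.ndarray,
    series: np.ndarray,
    min_prominence: float = 2.0,
) -> list[Peak]:
    """Local maxima with prominence >= ``min_prominence``.

    Interior maxima come from the standard topographic-prominence
    definition; an endpoint is reported as a peak only when the series
    decreases away from it and it rises by at least the prominence
    threshold above the adjacent valley.  Ties are broken by earliest
    time.  Returns possibly-empty list of :class:`Peak` (times in min).
    """
    series = np.asarray(series, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    idx, props = _scipy_find_peaks(series, prominence=min_prominence)
    peaks = [
        Peak(times_s[i] / 60.0, series[i], float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    n = series.size
    if n >= 2:
        higher = np.where(series > series[0])[0]
        stop = higher[0] if higher.size else n
        valley = series[:stop].min()
        if series[1] < series[0] and series[0] - valley >= min_prominence:
            peaks.insert(0, Peak(times_s[0] / 60.0, series[0],
                                 float(series[0] - valley)))
        higher = np.where(series > series[-1])[0]
        start = higher[-1] + 1 if higher.size else 0
        valley = series[start:].min()
        if series[-2] < series[-1] and series[-1] - valley >= min_prominence:
            peaks.append(Peak(times_s[-1] / 60.0, series[-1],
                              float(series[-1] - valley)))
    peaks.sort(key=lambda p: p.time_min)
    return peaks


def binned_auc(
    times_s: np.ndarray,
    series_pct: np.ndarray,
    bin_edges_min: np.ndarray | None = None,
) -> np.ndarray:
    """Trapezoidal area of the activation *fraction* per time bin.

    ``series_pct`` is on the percent scale; areas are reported in
    fraction x min (a constant 50% over a 10-min bin gives 5.0), matching
    the combination-analysis table convention.
    """
    if bin_edges_min is None:
        bin_edges_min = np.arange(0.0, 90.0, 10.0)
    bin_edges_min = np.asarray(bin_edges_min, dtype=float)
    t_min = np.asarray(times_s, dtype=float) / 60.0
    frac = np.asarray(series_pct, dtype=float) / 100.0
    if bin_edges_min[0] < t_min[0] - 1e-9 or bin_edges_min[-1] > t_min[-1] + 1e-9:
        raise ValueError("bins extend outside the simulated horizon")
    areas = np.empty(bin_edges_min.size - 1)
    for k, (a, b) in enumerate(zip(bin_edges_min[:-1], bin_edges_min[1:])):
        grid = t_min[(t_min > a) & (t_min < b)]
        grid = np.concatenate(([a], grid, [b]))
        vals = np.interp(grid, t_min, frac)
        areas[k] = np.trapezoid(vals, grid)
    return areas


def synergy_analysis(
    cfg_combo,
    cfg_A,
    cfg_B,
    params: dict | None = None,
    horizon: float = 4800.0,
    bin_edges_min: np.ndarray | None = None,
    observable: str = "mlc_activation_pct",
    method: str = "RK45",
) -> SynergyTable:
    """Run combo + two single-mediator simulations and tabulate synergy.

    The three stimulus configurations must be identical apart from their
    mediator doses (same multipliers, switches and overrides); anything
    else would confound the additive expectation.
    """
    from .pathway import build_model

    for other in (cfg_A, cfg_B):
        if not cfg_combo.same_except_doses(other):
            raise NetworkError(
                "synergy configs may differ only in mediator doses"
            )
    areas = []
    for cfg in (cfg_combo, cfg_A, cfg_B):
        net = build_model(cfg, params=params)
        tc = run(net, horizon, method=method)
        series = activation_series(tc, observable)
        areas.append(binned_auc(tc.times, series, bin_edges_min))
    edges = (
        np.arange(0.0, 90.0, 10.0) if bin_edges_min is None
        else np.asarray(bin_edges_min, dtype=float)
    )
    return SynergyTable(edges, areas[0], areas[1], areas[2])


# -- writers ---------------------------------------------------------------


def timecourse_to_tidy(tc: TimeCourse) -> pd.DataFrame:
    """Long-format frame: (time_s, species, concentration_uM)."""
    frames = []
    for i, sp in enumerate(tc.network.species):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tc.times,
                    "species": sp.id,
                    "concentration_uM": tc.states[i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def timecourse_to_wide(
    tc: TimeCourse, observables: list[str] | None = None
) -> pd.DataFrame:
    """Wide frame of derived observables indexed by time."""
    if observables is None:
        observables = ["mlc_activation_pct", "ppMLC", "Ca_i", "IP3",
                       "active_ERK", "active_Rho"]
    data = {"time_s": tc.times}
    for name in observables:
        data[name] = activation_series(tc, name)
    return pd.DataFrame(data)


def run_report(tc: TimeCourse, cfg=None, features: dict | None = None) -> str:
    """JSON run report: config hash, solver stats, extracted features."""
    payload = {
        "config": None if cfg is None else cfg.to_dict(),
        "config_hash": None if cfg is None else cfg.digest(),
        "solver": tc.solver_stats,
        "features": features or {},
    }
    return json.dumps(payload, indent=2, sort_keys=True, default=float)
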