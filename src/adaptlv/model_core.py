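"""Treatment-modulated Lotka-Volterra competition model.

Competing tumour subpopulations x_i (cell units) follow

    dx_i/dt = beta_sc * r_i * x_i * (1 - sum_j a_ij x_j / K_i,eff)

where a_ii = 1, and androgen-blocking therapy acts purely through the
carrying capacity of treatment-sensitive types:

    K_i,eff = K_i * (1 - drop_i * Lambda),   Lambda in {0, 1}.

In the two-population specialisation used throughout the package, type 0 is
the abiraterone-sensitive population (drop 0.9: carrying capacity falls from
10,000 to 1,000 under treatment) and type 1 the resistant population
(drop 0).  Serum PSA is treated as a direct census of total cell burden via
a single cells-per-(ng/ml) conversion constant.

Time is measured in days everywhere; growth rates are per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "LVParams",
    "Trajectory",
    "lv_derivative",
    "integrate",
    "psa_observable",
    "default_params",
    "DEFAULT_CONVERSION",
    "EXTINCTION_FLOOR",
    "SENSITIVE",
    "RESISTANT",
]

#: index conventions for the two-population model
SENSITIVE, RESISTANT = 0, 1

#: cells per (ng/ml) of PSA; the generator's median baseline PSA of
#: 25 ng/ml corresponds to half the default carrying capacity.
DEFAULT_CONVERSION = 200.0

#: below one cell a population is reported as extinct (continuum ODE values
#: smaller than this are not biologically meaningful).
EXTINCTION_FLOOR = 1.0

_RTOL = 1e-8
_ATOL = 1e-10


class InvalidInputError(ValueError):
    """An input violated a model invariant; the message names the field."""


@dataclass(frozen=True)
class LVParams:
    """Full parameterisation of the N-type competition model.

    r, K, alpha and treatment_K_drop house r_i, K_i, a_ij and the fractional
    carrying-capacity reduction under therapy; beta_sc is the cohort-wide
    growth-rate scaling factor.
    """

    r: np.ndarray
    K: np.ndarray
    alpha: np.ndarray
    beta_sc: float = 1.0
    treatment_K_drop: np.ndarray = None

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        K = np.atleast_1d(np.asarray(self.K, dtype=float))
        if K.size == 1 and r.size > 1:
            K = np.full(r.size, K[0])
        alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        drop = self.treatment_K_drop
        if drop is None:
            drop = np.zeros(r.size)
        drop = np.atleast_1d(np.asarray(drop, dtype=float))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "treatment_K_drop", drop)
        object.__setattr__(self, "beta_sc", float(self.beta_sc))
        self._validate()

    def _validate(self):
        n = self.r.size
        if not np.all(np.isfinite(self.r)) or np.any(self.r <= 0):
            raise InvalidInputError("r: growth rates must be finite and > 0")
        if self.K.size != n or not np.all(np.isfinite(self.K)) or np.any(self.K <= 0):
            raise InvalidInputError("K: carrying capacities must be finite, > 0, one per type")
        if self.alpha.shape != (n, n) or not np.all(np.isfinite(self.alpha)):
            raise InvalidInputError("alpha: competition matrix must be finite and n x n")
        if not np.allclose(np.diag(self.alpha), 1.0, rtol=0, atol=0):
            raise InvalidInputError("alpha: diagonal must be exactly 1 (intra-type competition is the unit)")
        if not (np.isfinite(self.beta_sc) and self.beta_sc > 0):
            raise InvalidInputError("beta_sc: scaling factor must be finite and > 0")
        if self.treatment_K_drop.size != n or np.any(self.treatment_K_drop < 0) or np.any(
            self.treatment_K_drop >= 1
        ):
            raise InvalidInputError("treatment_K_drop: fractions must lie in [0, 1)")

    @property
    def n_types(self) -> int:
        return self.r.size

    @property
    def resistant_mask(self) -> np.ndarray:
        """Types unaffected by therapy (no carrying-capacity drop)."""
        return self.treatment_K_drop == 0

    def effective_K(self, on_treatment: bool) -> np.ndarray:
        lam = 1.0 if on_treatment else 0.0
        return self.K * (1.0 - self.treatment_K_drop * lam)

    def with_(self, **kwargs) -> "LVParams":
        return replace(self, **kwargs)


def default_params(
    r_s: float = 0.0156,
    r_r: float = 0.0091,
    beta_sc: float = 8.0,
    alpha_rs: float = 6.0,
    alpha_sr: float = 1.0,
    K: float = 10_000.0,
    drop: float = 0.9,
) -> LVParams:
    """Two-population parameter set at the cohort-wide fitted values.

    Sensitive growth 0.0156/day, resistant 0.0091/day, scaling factor 8,
    competitive effect of sensitive on resistant alpha_RS = 6 (alpha_SR
    fixed at 1), shared carrying capacity 10,000 cells, 90% capacity drop
    for the sensitive type under therapy.
    """
    return LVParams(
        r=np.array([r_s, r_r]),
        K=np.array([K, K]),
        alpha=np.array([[1.0, alpha_sr], [alpha_rs, 1.0]]),
        beta_sc=beta_sc,
        treatment_K_drop=np.array([drop, 0.0]),
    )


@dataclass
class Trajectory:
    """Dense simulated population curves with the therapy indicator."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_types)
    treatment_on: np.ndarray  # bool per time

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.treatment_on = np.asarray(self.treatment_on, dtype=bool)
        if not (len(self.times) == len(self.states) == len(self.treatment_on)):
            raise InvalidInputError("trajectory: times, states, treatment_on must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise InvalidInputError("trajectory: times must be non-decreasing")

    @property
    def total(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def psa(self, conversion: float = DEFAULT_CONVERSION) -> np.ndarray:
        return psa_observable(self, conversion)

    def at(self, t) -> np.ndarray:
        """Linearly interpolated state at time(s) t (exact on grid points)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, self.states.shape[1]))
        for j in range(self.states.shape[1]):
            out[:, j] = np.interp(t, self.times, self.states[:, j])
        return out[0] if out.shape[0] == 1 else out

    def to_frame(self, run_id: str = "run", conversion: float = DEFAULT_CONVERSION):
        """Tidy export: one row per (time, type)."""
        import pandas as pd

        n_t, n_types = self.states.shape
        psa = self.psa(conversion)
        return pd.DataFrame(
            {
                "patient_or_run_id": np.repeat(run_id, n_t * n_types),
                "day": np.repeat(self.times, n_types),
                "type_label": np.tile(np.arange(n_types), n_t),
                "population": self.states.ravel(),
                "on_therapy": np.repeat(self.treatment_on.astype(int), n_types),
                "psa": np.repeat(psa, n_types),
            }
        )


def lv_derivative(x, params: LVParams, on_treatment: bool) -> np.ndarray:
    """Per-type rate of change (cells/day) at state x under the given therapy flag."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != params.n_types:
        raise InvalidInputError("state: expected %d populations, got %d" % (params.n_types, x.size))
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("state: populations must be finite")
    if np.any(x < 0):
        raise InvalidInputError("state: populations must be >= 0")
    lam = 1.0 if on_treatment else 0.0
    return _kernels.lv_rhs(
        x, lam, params.r, params.K, params.alpha, params.treatment_K_drop, params.beta_sc
    )


def psa_observable(traj: Trajectory, conversion: float = DEFAULT_CONVERSION) -> np.ndarray:
    """PSA(t) = total burden / conversion (PSA as a direct census of cell number)."""
    if not (np.isfinite(conversion) and conversion > 0):
        raise InvalidInputError("conversion: must be finite and > 0")
    return traj.total / conversion


def _segments_from_schedule(schedule, t0: float, t1: float):
    """Normalise a schedule argument to (seg_starts, seg_on) arrays covering [t0, t1].

    Accepts a TreatmentSchedule, a bool (constant therapy), or a pre-built
    (seg_starts, seg_on) pair.
    """
    from .protocols import TreatmentSchedule

    if isinstance(schedule, TreatmentSchedule):
        return schedule.segments(t0, t1)
    if isinstance(schedule, (bool, np.bool_)):
        return np.array([t0]), np.array([1 if schedule else 0], dtype=np.int64)
    starts, flags = schedule
    return np.asarray(starts, dtype=float), np.asarray(flags, dtype=np.int64)


def integrate(
    params: LVParams,
    x0,
    schedule,
    t_grid,
    method: str = "LSODA",
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Reference adaptive-step integration of the model over a therapy schedule.

    The solve is restarted at every treatment switch so the discontinuity in
    the effective carrying capacity is handled exactly at the switch time.
    Floating-point undershoot below zero is clamped at output.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise InvalidInputError("x0: initial populations must be finite and >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    seg_starts, seg_on = _segments_from_schedule(schedule, t_grid[0], t_grid[-1])
    if seg_starts[0] > t_grid[0]:
        raise InvalidInputError("schedule: must cover the start of t_grid")

    bounds = [t_grid[0]]
    for s in seg_starts:
        if t_grid[0] < s < t_grid[-1]:
            bounds.append(float(s))
    bounds.append(t_grid[-1])

    states = np.empty((t_grid.size, x0.size))
    filled = np.zeros(t_grid.size, dtype=bool)
    on_at = np.empty(t_grid.size, dtype=bool)
    x = x0.copy()
    for k in range(len(bounds) - 1):
        ta, tb = bounds[k], bounds[k + 1]
        seg_idx = np.searchsorted(seg_starts, ta, side="right") - 1
        lam = bool(seg_on[seg_idx])
        mask = (~filled) & (t_grid >= ta) & (t_grid <= tb if k == len(bounds) - 2 else t_grid < tb)
        t_eval = t_grid[mask]
        if tb > ta:
            rhs = lambda t, y: _kernels.lv_rhs(
                np.maximum(y, 0.0), 1.0 if lam else 0.0, params.r, params.K,
                params.alpha, params.treatment_K_drop, params.beta_sc,
            )
            # always evaluate at the segment end so the carried state is the
            # state exactly at the switch time
            t_eval_seg = np.union1d(t_eval, [tb])
            sol = solve_ivp(
                rhs, (ta, tb), x, method=method, rtol=rtol, atol=atol,
                t_eval=t_eval_seg, dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(
                    "integration failed on interval (%.3f, %.3f): %s" % (ta, tb, sol.message)
                )
            if t_eval.size:
                keep = np.isin(sol.t, t_eval)
                states[mask] = np.maximum(sol.y.T[keep], 0.0)
                filled[mask] = True
                on_at[mask] = lam
            x = np.maximum(sol.y[:, -1], 0.0)
        else:
            if t_eval.size:
                states[mask] = x
                filled[mask] = True
                on_at[mask] = lam
    if not filled.all():  # t_grid points at the exact start
        mask = ~filled
        states[mask] = x0
        seg_idx = np.searchsorted(seg_starts, t_grid[mask], side="right") - 1
        on_at[mask] = seg_on[seg_idx].astype(bool)
    return Trajectory(times=t_grid, states=states, treatment_on=on_at)


def integrate_fast(params: LVParams, x0, schedule, t_grid, h_max: float = 0.25) -> Trajectory:
    """Fixed-step RK4 counterpart of :func:`integrate` (same contract)."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise InvalidInputError("x0: initial populations must be finite and >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    seg_starts, seg_on = _segments_from_schedule(schedule, t_grid[0], t_grid[-1])
    states = _kernels.sim_at_times(
        x0, seg_starts, seg_on.astype(np.int64), t_grid, h_max,
        params.r, params.K, params.alpha, params.treatment_K_drop, params.beta_sc,
    )
    seg_idx = np.searchsorted(seg_starts, t_grid, side="right") - 1
    return Trajectory(times=t_grid, states=np.maximum(states, 0.0),
                      treatment_on=seg_on[seg_idx].astype(bool))
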