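"""Treatment-scheduling policies and derived clinical observables.

Protocols start therapy at day 0 (the pre-abiraterone PSA is the baseline)
and modulate it on the PSA observable:

* ``continuous`` -- therapy until progression (standard of care);
* ``adaptive_ideal`` -- stop the instant PSA falls to ``stop_fraction`` of
  baseline, restart the instant it returns to ``restart_fraction`` of
  baseline (crossings located to 1e-6 day);
* ``adaptive_sampled`` -- the same thresholds, but evaluated only at
  discrete monitoring visits, optionally with extra confirmation delays
  between a threshold crossing being observed and therapy actually
  changing (models the trial's 4-6 week labs and 12-week imaging);
* ``fixed_interval`` -- blind alternation of fixed on/off periods
  (the fixed 8-month intermittent-ADT comparator).

Progression has no closed-form definition inside the model, so a surrogate
rule is used: PSA rising through ``psa_multiple`` x baseline while on
therapy, or an on-period dragging on past ``on_period_factor`` x the
longest previously completed on-period without reaching the stop threshold
(PSA failing to respond).  After progression therapy is locked on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .model_core import (
    DEFAULT_CONVERSION,
    EXTINCTION_FLOOR,
    InvalidInputError,
    LVParams,
    Trajectory,
)

__all__ = [
    "TreatmentSchedule",
    "Protocol",
    "ProgressionRule",
    "SimulationResult",
    "run_protocol",
    "time_to_progression",
    "count_cycles",
]


@dataclass
class TreatmentSchedule:
    """Ordered, contiguous, non-overlapping (start_day, end_day, on_flag) intervals."""

    intervals: list

    def __post_init__(self):
        iv = [(float(a), float(b), bool(f)) for a, b, f in self.intervals]
        if not iv:
            raise InvalidInputError("schedule: needs at least one interval")
        merged = [iv[0]]
        for a, b, f in iv[1:]:
            pa, pb, pf = merged[-1]
            if a != pb:
                raise InvalidInputError("schedule: intervals must be contiguous without gaps/overlaps")
            if b < a:
                raise InvalidInputError("schedule: interval end before start")
            if f == pf:
                merged[-1] = (pa, b, pf)
            else:
                merged.append((a, b, f))
        self.intervals = merged

    # -- constructors ---------------------------------------------------
    @classmethod
    def constant(cls, horizon: float, on: bool = True, start: float = 0.0) -> "TreatmentSchedule":
        return cls([(start, horizon, on)])

    @classmethod
    def from_switches(
        cls, start: float, end: float, switch_times: Sequence[float], initial_on: bool = True
    ) -> "TreatmentSchedule":
        """Alternating schedule flipping at each switch time."""
        times = [start] + [float(t) for t in switch_times] + [end]
        flags = [initial_on]
        for _ in switch_times:
            flags.append(not flags[-1])
        return cls([(times[i], times[i + 1], flags[i]) for i in range(len(flags))])

    # -- queries --------------------------------------------------------
    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    def flag_at(self, t: float) -> bool:
        for a, b, f in self.intervals:
            if a <= t < b:
                return f
        if t == self.end:
            return self.intervals[-1][2]
        raise InvalidInputError("schedule: time %.3f outside [%.3f, %.3f]" % (t, self.start, self.end))

    def segments(self, t0: float, t1: float):
        """(seg_starts, seg_on) arrays for the integrator; must cover [t0, t1]."""
        if t0 < self.start - 1e-9 or t1 > self.end + 1e-9:
            raise InvalidInputError("schedule: does not cover requested span")
        starts, flags = [], []
        for a, b, f in self.intervals:
            if b <= t0 or a >= t1:
                continue
            starts.append(max(a, t0))
            flags.append(1 if f else 0)
        if not starts:
            starts, flags = [t0], [1 if self.flag_at(t0) else 0]
        return np.asarray(starts, dtype=float), np.asarray(flags, dtype=np.int64)

    def switch_times(self) -> list:
        return [a for a, _, _ in self.intervals[1:]]

    def fraction_on(self, t0: Optional[float] = None, t1: Optional[float] = None) -> float:
        t0 = self.start if t0 is None else t0
        t1 = self.end if t1 is None else t1
        if t1 <= t0:
            raise InvalidInputError("schedule: zero-length span for fraction_on")
        on = 0.0
        for a, b, f in self.intervals:
            if f:
                on += max(0.0, min(b, t1) - max(a, t0))
        return on / (t1 - t0)


def count_cycles(schedule: TreatmentSchedule) -> int:
    """Completed adaptive cycles = number of off->on restarts after the initial on-period."""
    n = 0
    prev = None
    for _, _, f in schedule.intervals:
        if prev is False and f is True:
            n += 1
        prev = f
    return n


PROTOCOL_KINDS = ("continuous", "adaptive_ideal", "adaptive_sampled", "fixed_interval")


@dataclass
class Protocol:
    """A treatment-scheduling policy.

    ``confirmation_delay_days``, when given, is applied to therapy
    *withdrawal* (the protocol's radiographic-confirmation lag before a drug
    holiday); restart and withdrawal delays can also be set independently.
    """

    kind: str = "adaptive_ideal"
    stop_fraction: float = 0.5
    restart_fraction: float = 1.0
    observation_interval_days: float = 28.0
    confirmation_delay_days: Optional[float] = None
    withdrawal_delay_days: float = 0.0
    restart_delay_days: float = 0.0
    period_on_days: float = 240.0
    period_off_days: float = 240.0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise InvalidInputError("protocol: unknown kind %r (choose from %s)" % (self.kind, PROTOCOL_KINDS))
        if not (0 < self.stop_fraction < self.restart_fraction <= 1.5):
            raise InvalidInputError("protocol: need 0 < stop_fraction < restart_fraction <= 1.5")
        if self.kind == "adaptive_sampled" and not self.observation_interval_days > 0:
            raise InvalidInputError("protocol: observation_interval_days must be > 0")
        if self.kind == "fixed_interval" and not (self.period_on_days > 0 and self.period_off_days > 0):
            raise InvalidInputError("protocol: fixed-interval periods must be > 0")
        if self.confirmation_delay_days is not None:
            self.withdrawal_delay_days = float(self.confirmation_delay_days)


@dataclass(frozen=True)
class ProgressionRule:
    """Operational surrogate for radiographic progression in simulations."""

    psa_multiple: float = 1.2
    on_period_factor: float = 2.0


@dataclass
class SimulationResult:
    """A protocol run plus every derived clinical observable."""

    trajectory: Trajectory
    schedule: TreatmentSchedule
    baseline_psa: float
    ttp_days: Optional[float]
    n_cycles: int
    fraction_time_on: float
    resistant_extinct_cycle: Optional[int]
    conversion: float = DEFAULT_CONVERSION
    horizon_days: float = 0.0
    protocol: Optional[Protocol] = None

    @property
    def progressed(self) -> bool:
        return self.ttp_days is not None

    @property
    def ttp_or_horizon(self) -> float:
        return self.horizon_days if self.ttp_days is None else self.ttp_days


class _Engine:
    """Chunked RK4 closed-loop integrator with bisection-refined PSA crossings."""

    def __init__(self, params: LVParams, x0, conversion, record_dt=1.0, h_max=0.25):
        self.p = params
        self.x = np.array(x0, dtype=float)
        self.t = 0.0
        self.conv = conversion
        self.record_dt = record_dt
        self.h_max = h_max
        self.times = [0.0]
        self.states = [self.x.copy()]
        self.flags = []  # flag per recorded time, filled lazily
        self.flag_list = [True]

    def psa(self, x=None) -> float:
        return float(np.sum(self.x if x is None else x)) / self.conv

    def _advance_state(self, x, t_from, t_to, lam):
        if t_to <= t_from:
            return x.copy()
        n = max(1, int(math.ceil((t_to - t_from) / self.h_max)))
        return _kernels.rk4_advance(
            x, (t_to - t_from) / n, n, lam,
            self.p.r, self.p.K, self.p.alpha, self.p.treatment_K_drop, self.p.beta_sc,
        )

    def _refine_crossing(self, x_prev, t_prev, t_next, lam, level, tol=1e-6):
        """Bisection for psa(tau) == level in (t_prev, t_next]."""
        lo, hi = t_prev, t_next
        sign_lo = self.psa(x_prev) - level
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            x_mid = self._advance_state(x_prev, t_prev, mid, lam)
            if (self.psa(x_mid) - level) * (1 if sign_lo > 0 else -1) > 0:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        return tau, self._advance_state(x_prev, t_prev, tau, lam)

    def advance(self, t_to, on, watchers=(), chunk: int = 16):
        """Integrate to t_to under the given flag, stopping at the first
        watcher crossing.  Watchers are (name, level, direction) on PSA.
        Returns (name, tau) or None.  Records the trajectory as it goes."""
        lam = 1.0 if on else 0.0
        substeps = max(1, int(math.ceil(self.record_dt / self.h_max)))
        while self.t < t_to - 1e-12:
            n_full = int((t_to - self.t + 1e-12) // self.record_dt)
            n_out = min(chunk, n_full)
            if n_out >= 1:
                dense = _kernels.rk4_dense(
                    self.x, self.record_dt, n_out, substeps, lam,
                    self.p.r, self.p.K, self.p.alpha, self.p.treatment_K_drop, self.p.beta_sc,
                )
                psa_grid = np.concatenate(([self.psa()], dense.sum(axis=1) / self.conv))
            else:  # trailing fraction of a record step
                step = t_to - self.t
                x_new = self._advance_state(self.x, self.t, self.t + step, lam)
                dense = x_new[None, :]
                psa_grid = np.array([self.psa(), self.psa(x_new)])
            firsts = {}
            for name, level, direction in watchers:
                if direction < 0:
                    crossed = (psa_grid[:-1] > level) & (psa_grid[1:] <= level)
                else:
                    crossed = (psa_grid[:-1] < level) & (psa_grid[1:] >= level)
                idx = np.nonzero(crossed)[0]
                if idx.size:
                    firsts[name] = (int(idx[0]), level)
            if firsts:
                kmin = min(k for k, _ in firsts.values())
                # record full steps before the crossing step, then refine inside it
                step = self.record_dt if n_out >= 1 else (t_to - self.t)
                for j in range(kmin):
                    self.t += step
                    self.x = dense[j]
                    self._record(on)
                best = None
                for name, (k, level) in firsts.items():
                    if k != kmin:
                        continue
                    tau, x_tau = self._refine_crossing(self.x, self.t, self.t + step, lam, level)
                    if best is None or tau < best[1]:
                        best = (name, tau, x_tau)
                name, tau, x_tau = best
                self.t, self.x = tau, x_tau
                self._record(on)
                return name, tau
            step = self.record_dt if n_out >= 1 else (t_to - self.t)
            for j in range(dense.shape[0]):
                self.t += step
                self.x = dense[j]
                self._record(on)
        return None

    def _record(self, on):
        self.times.append(self.t)
        self.states.append(self.x.copy())
        self.flag_list.append(bool(on))

    def trajectory(self) -> Trajectory:
        return Trajectory(
            times=np.array(self.times),
            states=np.array(self.states),
            treatment_on=np.array(self.flag_list, dtype=bool),
        )


def run_protocol(
    params: LVParams,
    x0,
    protocol: Protocol,
    horizon_days: float,
    conversion: float = DEFAULT_CONVERSION,
    rule: Optional[ProgressionRule] = None,
    observation_times: Optional[Sequence[float]] = None,
    record_dt: float = 1.0,
    h_max: float = 0.25,
) -> SimulationResult:
    """Closed-loop simulation of a protocol, switching on the PSA observable."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0) or x0.sum() <= 0:
        raise InvalidInputError("x0: populations must be >= 0 with positive total")
    if not horizon_days > 0:
        raise InvalidInputError("horizon_days: must be > 0")
    rule = rule or ProgressionRule()
    eng = _Engine(params, x0, conversion, record_dt=record_dt, h_max=h_max)
    baseline = eng.psa()
    stop_level = protocol.stop_fraction * baseline
    restart_level = protocol.restart_fraction * baseline
    prog_level = rule.psa_multiple * baseline

    switch_times: list = []
    on = True
    on_start = 0.0
    longest_on = 0.0
    ttp: Optional[float] = None

    def close_on_period(tau):
        nonlocal longest_on
        longest_on = max(longest_on, tau - on_start)

    if protocol.kind == "continuous":
        ev = eng.advance(horizon_days, True, watchers=[("prog", prog_level, +1)])
        if ev is not None:
            ttp = ev[1]
            eng.advance(horizon_days, True)

    elif protocol.kind == "fixed_interval":
        t_next, seg_on = 0.0, True
        while eng.t < horizon_days and ttp is None:
            t_next = min(
                horizon_days,
                eng.t + (protocol.period_on_days if seg_on else protocol.period_off_days),
            )
            watchers = [("prog", prog_level, +1)] if seg_on else []
            ev = eng.advance(t_next, seg_on, watchers=watchers)
            if ev is not None:
                ttp = ev[1]
                if not seg_on:  # unreachable (no watcher off-therapy) but kept for clarity
                    switch_times.append(ev[1])
                eng.advance(horizon_days, True)
                break
            if eng.t < horizon_days:
                switch_times.append(eng.t)
                seg_on = not seg_on
        on = seg_on if ttp is None else True

    elif protocol.kind == "adaptive_ideal":
        while eng.t < horizon_days and ttp is None:
            if on:
                bound = on_start + rule.on_period_factor * longest_on if longest_on > 0 else np.inf
                t_to = min(horizon_days, bound)
                ev = eng.advance(
                    t_to, True,
                    watchers=[("stop", stop_level, -1), ("prog", prog_level, +1)],
                )
                if ev is None:
                    if t_to < horizon_days:  # on-period exceeded its bound
                        ttp = t_to
                        eng.advance(horizon_days, True)
                elif ev[0] == "prog":
                    ttp = ev[1]
                    eng.advance(horizon_days, True)
                else:
                    close_on_period(ev[1])
                    switch_times.append(ev[1])
                    on = False
            else:
                ev = eng.advance(horizon_days, False, watchers=[("restart", restart_level, +1)])
                if ev is not None:
                    switch_times.append(ev[1])
                    on = True
                    on_start = ev[1]

    elif protocol.kind == "adaptive_sampled":
        if observation_times is None:
            visits = np.arange(0.0, horizon_days + 1e-9, protocol.observation_interval_days)
        else:
            visits = np.asarray(observation_times, dtype=float)
            if visits[0] != 0.0:
                raise InvalidInputError("observation_times: must start at day 0")
        pending: Optional[tuple] = None  # (time, new_flag)

        def advance_applying(t_target):
            nonlocal pending, on, on_start, longest_on
            if pending is not None and pending[0] <= t_target:
                tau, new_flag = pending
                eng.advance(tau, on)
                if new_flag != on:
                    if on:
                        close_on_period(tau)
                    else:
                        on_start = tau
                    switch_times.append(tau)
                    on = new_flag
                pending = None
            eng.advance(t_target, on)

        for v in visits:
            if v > horizon_days:
                break
            advance_applying(v)
            if ttp is not None:
                continue
            psa_v = eng.psa()
            deriv = float(
                np.sum(
                    _kernels.lv_rhs(
                        eng.x, 1.0 if on else 0.0, params.r, params.K,
                        params.alpha, params.treatment_K_drop, params.beta_sc,
                    )
                )
            )
            if on:
                if psa_v >= prog_level and deriv >= 0:
                    ttp = v
                    pending = None
                elif longest_on > 0 and (v - on_start) > rule.on_period_factor * longest_on:
                    ttp = on_start + rule.on_period_factor * longest_on
                    pending = None
                elif pending is None and psa_v <= stop_level:
                    pending = (v + protocol.withdrawal_delay_days, False)
            else:
                if pending is None and psa_v >= restart_level:
                    pending = (v + protocol.restart_delay_days, True)
        if ttp is None:
            advance_applying(horizon_days)
        else:
            eng.advance(horizon_days, on)
    else:  # pragma: no cover - guarded by Protocol validation
        raise InvalidInputError("protocol: unknown kind %r" % protocol.kind)

    schedule = TreatmentSchedule.from_switches(0.0, horizon_days, switch_times, initial_on=True)
    traj = eng.trajectory()
    n_cycles = count_cycles(schedule)

    resistant = params.resistant_mask
    extinct_cycle: Optional[int] = None
    if resistant.any():
        x_res = traj.states[:, resistant].sum(axis=1)
        below = np.nonzero(x_res < EXTINCTION_FLOOR)[0]
        if below.size:
            t_ext = traj.times[below[0]]
            if t_ext == 0.0:
                extinct_cycle = 0
            else:
                restarts_before = sum(1 for a, _, f in schedule.intervals[1:] if f and a < t_ext)
                extinct_cycle = restarts_before + 1

    return SimulationResult(
        trajectory=traj,
        schedule=schedule,
        baseline_psa=baseline,
        ttp_days=ttp,
        n_cycles=n_cycles,
        fraction_time_on=schedule.fraction_on(0.0, horizon_days),
        resistant_extinct_cycle=extinct_cycle,
        conversion=conversion,
        horizon_days=horizon_days,
        protocol=protocol,
    )


def time_to_progression(result: SimulationResult, rule: Optional[ProgressionRule] = None):
    """First day the progression rule fires on a completed simulation, else None.

    Re-derives progression from the stored trajectory and schedule (linear
    interpolation between recorded points), independent of the bookkeeping
    done inside :func:`run_protocol`.
    """
    rule = rule or ProgressionRule()
    traj = result.trajectory
    psa = traj.psa(result.conversion)
    level = rule.psa_multiple * result.baseline_psa
    candidates = []

    on_intervals = [(a, b) for a, b, f in result.schedule.intervals if f]
    for a, b in on_intervals:
        mask = (traj.times >= a) & (traj.times <= b)
        idx = np.nonzero(mask)[0]
        for k in range(1, idx.size):
            i0, i1 = idx[k - 1], idx[k]
            if psa[i0] < level <= psa[i1]:
                frac = (level - psa[i0]) / (psa[i1] - psa[i0])
                candidates.append(traj.times[i0] + frac * (traj.times[i1] - traj.times[i0]))
                break

    durations = [b - a for a, b in on_intervals]
    longest = 0.0
    for k, (a, b) in enumerate(on_intervals):
        if k > 0 and longest > 0 and (b - a) > rule.on_period_factor * longest:
            candidates.append(a + rule.on_period_factor * longest)
        longest = max(longest, durations[k])

    return min(candidates) if candidates else None
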