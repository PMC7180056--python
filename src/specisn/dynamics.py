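"""Network dynamics: rectified rate equations and LIF spiking neurons.

Rate networks obey

    tau dr/dt = -r + ([W r + s]_+)^n

with half-wave rectification []_+ and optional expansive exponent n >= 1,
integrated by forward Euler.  Spiking networks are leaky integrate-and-fire
neurons,

    tau_m dV/dt = -V + s(t),

solved by exact integration of the leak between events: each presynaptic
spike (recurrent, from the previous time step, or external Poisson) deflects
the membrane instantaneously by its synaptic weight J (mV); crossing V_th
emits a spike and resets V to V_reset.

Input schedules are piecewise constant in time: a list of named windows, each
carrying a per-neuron input vector (rate models) or per-neuron external
Poisson rate (spiking models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InstabilityError",
    "Window",
    "Schedule",
    "baseline_input",
    "baseline_perturb_schedule",
    "RateParams",
    "LIFParams",
    "ActivityRecord",
    "simulate_rate",
    "steady_state",
    "steady_rates",
    "simulate_lif",
    "spike_counts",
]

# Default experiment schedule: baseline [0, 300), perturbation [300, 700),
# in the time units of the rate model (tau = 10).
BASELINE_WINDOW = (0.0, 300.0)
PERTURB_WINDOW = (300.0, 700.0)
DISCARD_FRACTION = 1.0 / 3.0


class InstabilityError(RuntimeError):
    """Raised when rates exceed the divergence ceiling during integration."""


@dataclass
class Window:
    name: str
    t_start: float
    t_stop: float
    inputs: np.ndarray  # per-neuron input (rate) or external Poisson rate (LIF)


@dataclass
class Schedule:
    windows: list[Window]

    @property
    def t_stop(self) -> float:
        return self.windows[-1].t_stop

    def validate(self, n: int) -> None:
        t = self.windows[0].t_start
        for w in self.windows:
            if w.t_start != t:
                raise ValueError("schedule windows must be contiguous and ordered")
            if np.asarray(w.inputs).shape[0] != n:
                raise ValueError(f"window {w.name!r}: inputs length != {n}")
            t = w.t_stop


def baseline_input(
    n_e: int,
    n_i: int,
    s_base: float = 2.0,
    jitter: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Constant baseline drive with frozen multiplicative jitter U[1-j, 1+j]."""
    rng = np.random.default_rng(seed)
    return s_base * rng.uniform(1.0 - jitter, 1.0 + jitter, n_e + n_i)


def baseline_perturb_schedule(
    s: np.ndarray,
    delta_s_i: np.ndarray,
    n_e: int,
    windows: tuple[tuple[float, float], tuple[float, float]] = (BASELINE_WINDOW, PERTURB_WINDOW),
) -> Schedule:
    """Two-window schedule: baseline drive s, then s with delta added to I cells."""
    s = np.asarray(s, dtype=float)
    s_pert = s.copy()
    s_pert[n_e:] += np.asarray(delta_s_i, dtype=float)
    (b0, b1), (p0, p1) = windows
    return Schedule(
        [
            Window("baseline", b0, b1, s),
            Window("perturbation", p0, p1, s_pert),
        ]
    )


@dataclass
class RateParams:
    tau: float = 10.0
    n_power: float = 1.0
    dt: float = 0.1
    rate_ceiling: float = 1e6

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.n_power < 1:
            raise ValueError("nonlinearity exponent must be >= 1")
        if not 0 < self.dt < self.tau:
            raise ValueError("dt must satisfy 0 < dt < tau")


@dataclass
class LIFParams:
    tau_m: float = 20.0  # ms
    v_th: float = 20.0  # mV
    v_reset: float = 0.0  # mV
    dt: float = 0.1  # ms
    j_ext: float = 2.0  # mV jump per external event
    ext_rate: float = 2400.0  # events/s per neuron, calibrated baseline

    def __post_init__(self) -> None:
        if not self.v_th > self.v_reset:
            raise ValueError("v_th must exceed v_reset")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")


@dataclass
class ActivityRecord:
    """Simulated activity with its schedule annotations.

    Rate runs: ``rates`` is (n_times, n_neurons) sampled at ``times``.
    Spiking runs: ``spike_ids``/``spike_times`` list individual events (ms).
    """

    kind: str  # "rate" | "spikes"
    n_e: int
    n_i: int
    schedule: Schedule
    times: np.ndarray | None = None
    rates: np.ndarray | None = None
    spike_ids: np.ndarray | None = None
    spike_times: np.ndarray | None = None
    seed: int | None = None
    repetition: int = 0

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def window(self, name: str) -> Window:
        for w in self.schedule.windows:
            if w.name == name:
                return w
        raise KeyError(name)


# rates below this are physically zero; flushing them avoids denormal-float
# slow paths as rectified units decay exponentially toward zero
RATE_FLOOR = 1e-12


def _drive(w: np.ndarray, r: np.ndarray, s: np.ndarray, n_power: float) -> np.ndarray:
    x = w @ r + s
    np.maximum(x, 0.0, out=x)
    if n_power != 1.0:
        x **= n_power
    return x


def _flush_tiny(r: np.ndarray) -> None:
    r[r < RATE_FLOOR] = 0.0


def simulate_rate(
    w,
    schedule: Schedule,
    params: RateParams | None = None,
    r0: np.ndarray | None = None,
    record_every: int = 1,
) -> ActivityRecord:
    """Forward-Euler integration of the rectified rate dynamics.

    ``w`` is a WeightMatrix or a dense array (E rows/cols first); the
    trajectory is recorded every ``record_every`` steps.  Rates exceeding
    ``params.rate_ceiling`` abort with :class:`InstabilityError`.
    """
    params = params or RateParams()
    w_arr, n_e, n_i = _as_weights(w)
    n = n_e + n_i
    schedule.validate(n)
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=float).copy()
    dt_tau = params.dt / params.tau
    times, rates = [], []
    t = schedule.windows[0].t_start
    step_idx = 0
    for win in schedule.windows:
        s = np.asarray(win.inputs, dtype=float)
        n_steps = int(round((win.t_stop - win.t_start) / params.dt))
        for _ in range(n_steps):
            if step_idx % record_every == 0:
                times.append(t)
                rates.append(r.copy())
            r += dt_tau * (_drive(w_arr, r, s, params.n_power) - r)
            _flush_tiny(r)
            t += params.dt
            step_idx += 1
            if not np.all(r < params.rate_ceiling):
                raise InstabilityError(
                    f"rate exceeded ceiling {params.rate_ceiling:g} at t={t:.2f}"
                )
    times.append(t)
    rates.append(r.copy())
    return ActivityRecord(
        kind="rate",
        n_e=n_e,
        n_i=n_i,
        schedule=schedule,
        times=np.array(times),
        rates=np.array(rates),
    )


def steady_state(
    w,
    s: np.ndarray,
    params: RateParams | None = None,
    r0: np.ndarray | None = None,
    t_settle: float = 200.0,
) -> np.ndarray:
    """Integrate to (approximate) steady state under constant input.

    ``s`` may be a vector or an (n, k) matrix of k independent input columns,
    integrated in parallel; returns the final state with matching shape.
    """
    params = params or RateParams()
    w_arr, n_e, n_i = _as_weights(w)
    s = np.asarray(s, dtype=float)
    if r0 is None:
        r = np.zeros_like(s)
    else:
        r0 = np.asarray(r0, dtype=float)
        r = np.broadcast_to(r0.reshape(-1, *([1] * (s.ndim - 1))), s.shape).copy()
    dt_tau = params.dt / params.tau
    n_steps = int(round(t_settle / params.dt))
    for _ in range(n_steps):
        r += dt_tau * (_drive(w_arr, r, s, params.n_power) - r)
        _flush_tiny(r)
        if not np.all(r < params.rate_ceiling):
            raise InstabilityError("rate exceeded ceiling during settling")
    return r


def steady_rates(
    record: ActivityRecord, discard_fraction: float = DISCARD_FRACTION
) -> dict[str, np.ndarray]:
    """Per-neuron mean rates per schedule window, transient discarded.

    For spiking records, rates are spike counts over the retained part of
    each window divided by its duration (spikes/s with times in ms).
    """
    out: dict[str, np.ndarray] = {}
    for win in record.schedule.windows:
        t0 = win.t_start + discard_fraction * (win.t_stop - win.t_start)
        if record.kind == "rate":
            mask = (record.times >= t0) & (record.times < win.t_stop)
            if not mask.any():
                raise ValueError(f"window {win.name!r} empty after discard")
            out[win.name] = record.rates[mask].mean(axis=0)
        else:
            duration_s = (win.t_stop - t0) / 1000.0
            mask = (record.spike_times >= t0) & (record.spike_times < win.t_stop)
            counts = np.bincount(record.spike_ids[mask], minlength=record.n)
            out[win.name] = counts / duration_s
    return out


def _as_weights(w) -> tuple[np.ndarray, int, int]:
    if hasattr(w, "w"):
        return w.w, w.n_e, w.n_i
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    return w, n // 2, n - n // 2


def simulate_lif(
    w,
    schedule: Schedule,
    params: LIFParams | None = None,
    seed: int | None = None,
    n_reps: int = 1,
    record_v: bool = False,
    v0: np.ndarray | None = None,
) -> list[ActivityRecord]:
    """Simulate the LIF network under a schedule of external Poisson rates.

    Per time step, the membrane decays exactly (V <- V e^{-dt/tau_m}), then
    receives recurrent jumps from spikes of the *previous* step plus external
    Poisson events of size ``params.j_ext``; V >= V_th emits a spike and
    resets.  ``schedule`` windows carry per-neuron external rates (events/s);
    times are in ms.  ``v0`` sets the initial membrane potentials (default
    zero).  Returns ``n_reps`` records with independent seeds.
    """
    params = params or LIFParams()
    w_arr, n_e, n_i = _as_weights(w)
    n = n_e + n_i
    schedule.validate(n)
    root = np.random.SeedSequence(seed)
    records = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        records.append(
            _lif_single(w_arr, n_e, n_i, schedule, params, rng, rep, seed, record_v, v0)
        )
    return records


def _lif_single(w_arr, n_e, n_i, schedule, params, rng, rep, seed, record_v, v0=None):
    n = n_e + n_i
    decay = np.exp(-params.dt / params.tau_m)
    v = np.zeros(n) if v0 is None else np.asarray(v0, dtype=float).copy()
    prev_spikes = np.empty(0, dtype=np.intp)
    ids_chunks: list[np.ndarray] = []
    t_chunks: list[np.ndarray] = []
    v_trace = [] if record_v else None
    for win in schedule.windows:
        lam = np.asarray(win.inputs, dtype=float) * (params.dt / 1000.0)
        n_steps = int(round((win.t_stop - win.t_start) / params.dt))
        t = win.t_start
        for _ in range(n_steps):
            v *= decay
            if prev_spikes.size:
                v += w_arr[:, prev_spikes].sum(axis=1)
            v += params.j_ext * rng.poisson(lam)
            spiking = np.flatnonzero(v >= params.v_th)
            if spiking.size:
                v[spiking] = params.v_reset
                ids_chunks.append(spiking)
                t_chunks.append(np.full(spiking.size, t + params.dt))
            if record_v:
                v_trace.append(v.copy())
            prev_spikes = spiking
            t += params.dt
    spike_ids = np.concatenate(ids_chunks) if ids_chunks else np.empty(0, dtype=np.intp)
    spike_times = np.concatenate(t_chunks) if t_chunks else np.empty(0)
    rec = ActivityRecord(
        kind="spikes",
        n_e=n_e,
        n_i=n_i,
        schedule=schedule,
        spike_ids=spike_ids,
        spike_times=spike_times,
        seed=seed,
        repetition=rep,
    )
    if record_v:
        rec.rates = np.array(v_trace)  # membrane trace, reused field
        rec.times = np.arange(1, len(v_trace) + 1) * params.dt + schedule.windows[0].t_start
    return rec


def spike_counts(record: ActivityRecord, t0: float, t1: float) -> np.ndarray:
    """Per-neuron spike counts in [t0, t1)."""
    mask = (record.spike_times >= t0) & (record.spike_times < t1)
    return np.bincount(record.spike_ids[mask], minlength=record.n)
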