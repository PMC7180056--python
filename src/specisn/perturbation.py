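"""Perturbation patterns and paired baseline/perturbed experiments.

A perturbation pattern is a vector of signed input offsets delta_s_I, one per
inhibitory neuron, added to the baseline drive during the perturbation
window.  Negative patterns *reduce* the input to inhibitory neurons; in an
inhibition-stabilized network this paradoxically *increases* their mean
activity, and when the pattern is aligned with the network's specific
eigenmode the per-neuron response changes anticorrelate with the per-neuron
perturbations (the specific paradoxical effect).

Protocols
---------
nonspecific       delta_s ~ U[-2 gamma, 0], independent of identity
ring_1d           delta_s = gamma (sin(2 theta*) - 1), orientation-patterned
similarity        delta_s = -gamma exp(kappa psi_ref), RF- or response-
                  correlation to a reference inhibitory cell
shuffled          any pattern, permuted over neurons (controls for the
                  marginal distribution)
partial           a fraction f of inhibitory neurons keeps its value,
                  the rest are zeroed
scaled / signed   multiply by a factor and/or flip sign (positive
                  perturbation control)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import dynamics
from .dynamics import (
    DISCARD_FRACTION,
    ActivityRecord,
    LIFParams,
    RateParams,
    Schedule,
    Window,
    baseline_perturb_schedule,
    steady_rates,
)

__all__ = [
    "PerturbationPattern",
    "PerturbationExperiment",
    "pattern_nonspecific",
    "pattern_ring_1d",
    "pattern_similarity",
    "shuffle_pattern",
    "partial_pattern",
    "scale_and_sign",
    "run_perturbation_experiment",
    "stimulus_response_traces",
    "response_similarity",
]

GAMMA_DEFAULT = 0.25
KAPPA_DEFAULT = 2.0
# Reference input scale used to convert input offsets into external-rate
# scaling factors for spiking networks (the rate-model baseline drive).
S_REF_SPIKING = 2.0


@dataclass
class PerturbationPattern:
    """Signed per-inhibitory-neuron input offsets with protocol metadata."""

    delta_s: np.ndarray
    protocol: str
    gamma: float = GAMMA_DEFAULT
    kappa: float | None = None
    reference: int | None = None
    fraction: float = 1.0
    seed: int | None = None

    @property
    def n_i(self) -> int:
        return self.delta_s.size

    @property
    def mean(self) -> float:
        return float(self.delta_s.mean())


def pattern_nonspecific(n_i: int, gamma: float = GAMMA_DEFAULT, seed: int | None = None):
    """Random negative perturbation, i.i.d. uniform on [-2 gamma, 0].

    The support matches the orientation-patterned protocol so slope
    comparisons between the two are like-for-like.
    """
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-2.0 * gamma, 0.0, n_i)
    return PerturbationPattern(delta_s=delta, protocol="nonspecific", gamma=gamma, seed=seed)


def pattern_ring_1d(
    theta_i: np.ndarray, gamma: float = GAMMA_DEFAULT, *, printed_sign: bool = False
):
    """Orientation-patterned perturbation gamma (sin(2 theta*) - 1) <= 0.

    Zero at theta* = pi/4, most negative (-2 gamma) at theta* = 3 pi/4.
    ``printed_sign`` flips the overall sign (the nonnegative convention).
    """
    theta_i = np.asarray(theta_i, dtype=float)
    delta = gamma * (np.sin(2.0 * theta_i) - 1.0)
    if printed_sign:
        delta = -delta
    return PerturbationPattern(delta_s=delta, protocol="ring_1d", gamma=gamma)


def pattern_similarity(
    psi_ref: np.ndarray,
    gamma: float = GAMMA_DEFAULT,
    kappa: float = KAPPA_DEFAULT,
    reference: int | None = None,
):
    """Similarity-patterned perturbation -gamma exp(kappa psi_ref).

    ``psi_ref`` is the similarity (RF or response correlation) of each
    inhibitory neuron to the reference cell; the most similar neurons receive
    the most negative perturbation.
    """
    psi_ref = np.asarray(psi_ref, dtype=float)
    if np.any(np.abs(psi_ref) > 1.0 + 1e-9):
        raise ValueError("similarity values must lie in [-1, 1]")
    delta = -gamma * np.exp(kappa * psi_ref)
    return PerturbationPattern(
        delta_s=delta, protocol="similarity", gamma=gamma, kappa=kappa, reference=reference
    )


def shuffle_pattern(pattern: PerturbationPattern, seed: int | None = None):
    """Permute the pattern over neurons (multiset of values preserved)."""
    rng = np.random.default_rng(seed)
    return replace(
        pattern,
        delta_s=rng.permutation(pattern.delta_s),
        protocol=pattern.protocol + "_shuffled",
        seed=seed,
    )


def partial_pattern(
    pattern: PerturbationPattern,
    fraction: float,
    seed: int | None = None,
    selection_mode: str = "random",
):
    """Keep the pattern on ceil(f * N_I) neurons, zero the rest.

    ``selection_mode='most_similar'`` retains the neurons with the most
    negative perturbation (the most similar ones under similarity patterns);
    the default picks the retained subset at random.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n_i = pattern.n_i
    n_keep = int(np.ceil(fraction * n_i))
    if selection_mode == "random":
        rng = np.random.default_rng(seed)
        keep = rng.choice(n_i, n_keep, replace=False)
    elif selection_mode == "most_similar":
        keep = np.argsort(pattern.delta_s)[:n_keep]
    else:
        raise ValueError(f"unknown selection_mode: {selection_mode!r}")
    delta = np.zeros(n_i)
    delta[keep] = pattern.delta_s[keep]
    return replace(
        pattern,
        delta_s=delta,
        protocol=pattern.protocol + "_partial",
        fraction=fraction,
        seed=seed,
    )


def scale_and_sign(pattern: PerturbationPattern, factor: float = 1.0, sign: int = -1):
    """Scale the pattern and set its sign convention.

    ``sign=-1`` keeps the negative (input-reducing) convention; ``sign=+1``
    flips every entry (positive perturbation control).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    flip = -1.0 if sign > 0 else 1.0
    return replace(
        pattern,
        delta_s=flip * factor * pattern.delta_s,
        gamma=pattern.gamma * factor,
        protocol=pattern.protocol + ("_positive" if sign > 0 else ""),
    )


@dataclass
class PerturbationExperiment:
    """Paired baseline/perturbed window-mean rates and their difference."""

    pattern: PerturbationPattern
    baseline: np.ndarray  # per-neuron mean rates, E then I
    perturbed: np.ndarray
    n_e: int
    records: list[ActivityRecord] | None = None

    @property
    def delta_r(self) -> np.ndarray:
        return self.perturbed - self.baseline

    @property
    def delta_r_i(self) -> np.ndarray:
        return self.delta_r[self.n_e :]

    @property
    def delta_r_e(self) -> np.ndarray:
        return self.delta_r[: self.n_e]

    def slope(self, perturbed_only: bool = False, **kwargs):
        """Fit the paradoxical-effect slope (see metrics.perturbation_slope).

        ``perturbed_only`` restricts the fit to neurons with a nonzero input
        offset — the natural axis for partial patterns, where unperturbed
        neurons measure network spillover rather than a perturbation
        response.
        """
        from .metrics import perturbation_slope

        dr, ds = self.delta_r_i, self.pattern.delta_s
        if perturbed_only:
            nz = ds != 0
            dr, ds = dr[nz], ds[nz]
        return perturbation_slope(dr, ds, **kwargs)


def run_perturbation_experiment(
    w,
    pattern: PerturbationPattern,
    s_base: np.ndarray,
    mode: str = "rate",
    rate_params: RateParams | None = None,
    lif_params: LIFParams | None = None,
    n_reps: int = 10,
    seed: int | None = None,
    discard_fraction: float = DISCARD_FRACTION,
    windows=None,
    keep_records: bool = False,
) -> PerturbationExperiment:
    """Simulate paired baseline and perturbed windows and collect rates.

    Rate mode runs a single baseline->perturbation schedule; spiking mode
    runs ``n_reps`` paired simulations under independent seeds, expressing
    the input offsets as scalings of each inhibitory neuron's external
    Poisson rate (factor 1 + delta_s / s_ref, floored at 0).
    """
    w_arr, n_e, n_i = dynamics._as_weights(w)
    if pattern.n_i != n_i:
        raise ValueError(f"pattern length {pattern.n_i} != N_I {n_i}")
    s_base = np.asarray(s_base, dtype=float)

    if mode == "rate":
        kw = {} if windows is None else {"windows": windows}
        schedule = baseline_perturb_schedule(s_base, pattern.delta_s, n_e, **kw)
        # start from the settled baseline state so window means measure the
        # perturbation, not residual convergence of slow rectified modes
        params0 = rate_params or RateParams()
        r0 = dynamics.steady_state(w, s_base, params0, t_settle=40.0 * params0.tau)
        record = dynamics.simulate_rate(w, schedule, params=rate_params, r0=r0)
        means = steady_rates(record, discard_fraction)
        return PerturbationExperiment(
            pattern=pattern,
            baseline=means["baseline"],
            perturbed=means["perturbation"],
            n_e=n_e,
            records=[record] if keep_records else None,
        )

    if mode == "spiking":
        lif_params = lif_params or LIFParams()
        base_rates = np.broadcast_to(s_base, (n_e + n_i,)).astype(float).copy()
        pert_rates = base_rates.copy()
        factor = np.maximum(1.0 + pattern.delta_s / S_REF_SPIKING, 0.0)
        pert_rates[n_e:] *= factor
        if windows is None:
            windows = ((0.0, 5000.0), (5000.0, 10000.0))
        (b0, b1), (p0, p1) = windows
        schedule = Schedule(
            [Window("baseline", b0, b1, base_rates), Window("perturbation", p0, p1, pert_rates)]
        )
        records = dynamics.simulate_lif(w, schedule, lif_params, seed=seed, n_reps=n_reps)
        base = np.mean([steady_rates(r, discard_fraction)["baseline"] for r in records], axis=0)
        pert = np.mean(
            [steady_rates(r, discard_fraction)["perturbation"] for r in records], axis=0
        )
        return PerturbationExperiment(
            pattern=pattern,
            baseline=base,
            perturbed=pert,
            n_e=n_e,
            records=records if keep_records else None,
        )

    raise ValueError(f"unknown mode: {mode!r}")


def stimulus_response_traces(
    w,
    drive: np.ndarray,
    rate_params: RateParams | None = None,
    stim_duration: float = 200.0,
    discard_fraction: float = DISCARD_FRACTION,
) -> np.ndarray:
    """Window-mean responses to a stimulus sequence, (neuron, stimulus).

    The network state carries over between consecutive stimuli; each
    stimulus drives the network for ``stim_duration`` time units and the
    response is the mean rate over the window after discarding the initial
    transient.
    """
    params = rate_params or RateParams()
    w_arr, n_e, n_i = dynamics._as_weights(w)
    n, n_stim = drive.shape
    dt_tau = params.dt / params.tau
    n_steps = int(round(stim_duration / params.dt))
    n_discard = int(round(discard_fraction * n_steps))
    r = np.zeros(n)
    traces = np.empty((n, n_stim))
    for k in range(n_stim):
        s = drive[:, k]
        acc = np.zeros(n)
        for step in range(n_steps):
            r += dt_tau * (dynamics._drive(w_arr, r, s, params.n_power) - r)
            dynamics._flush_tiny(r)
            if step >= n_discard:
                acc += r
            if not np.all(r < params.rate_ceiling):
                raise dynamics.InstabilityError(f"rate ceiling exceeded at stimulus {k}")
        traces[:, k] = acc / (n_steps - n_discard)
    return traces


def response_similarity(
    w,
    bank,
    stimuli,
    beta: float | None = None,
    responsiveness_percentile: float = 20.0,
    rate_params: RateParams | None = None,
    stim_duration: float = 200.0,
) -> dict:
    """Response-correlation matrix among responsive inhibitory neurons.

    Presents the stimulus ensemble (drive 1 + beta * corr(stimulus, RF)),
    keeps inhibitory units whose mean activity exceeds the given percentile
    of the inhibitory population, and correlates their per-stimulus response
    traces.  Returns the correlation matrix, the indices of responsive units
    (within the inhibitory population), and the raw traces.
    """
    from .rf_stimuli import stimulus_drive

    drive = stimulus_drive(bank, stimuli, beta=beta)
    traces = stimulus_response_traces(w, drive, rate_params, stim_duration)
    w_arr, n_e, n_i = dynamics._as_weights(w)
    traces_i = traces[n_e:]
    mean_act = traces_i.mean(axis=1)
    threshold = np.percentile(mean_act, responsiveness_percentile)
    responsive = np.flatnonzero(mean_act > threshold)
    if responsive.size < 3:
        raise ValueError("fewer than 3 responsive inhibitory units")
    sub = traces_i[responsive]
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    return {
        "correlation": np.clip(corr, -1.0, 1.0),
        "responsive": responsive,
        "traces": traces,
    }
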