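"""Quantification of paradoxical effects and ensemble dynamics.

Two families of metrics:

* perturbation metrics — the OLS slope of per-neuron inhibitory response
  change versus input perturbation, its significance, and the classification
  into nonspecific (mean response opposite to mean perturbation) and specific
  (significant negative slope) paradoxical effects;

* ensemble metrics — windowed population preferred orientation (pop. PO) and
  orientation selectivity (pop. OSI) on the doubled-angle circle, the
  spontaneous-transition index STI = (1 - H_osi) * <pop OSI> built from the
  histogram of selective-window POs, its shuffle-null bootstrap, and
  pattern-interval correlations of population activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import ActivityRecord

__all__ = [
    "SlopeResult",
    "SelectivityTrace",
    "STResult",
    "perturbation_slope",
    "windowed_activity",
    "population_selectivity",
    "st_index",
    "bootstrap_st",
    "pattern_interval_correlation",
    "reference_sweep",
]

OSI_THRESHOLD = 0.5
N_PO_BINS = 24  # bins of width pi/24 over [0, pi)
WINDOW_MS = 10.0
MIN_ACTIVE = 5
N_SHUFFLES = 100


@dataclass
class SlopeResult:
    """OLS fit of inhibitory response change versus input perturbation."""

    slope: float
    intercept: float
    p_value: float
    mean_delta_r: float
    mean_delta_s: float
    n_points: int

    @property
    def nonspecific_paradoxical(self) -> bool:
        """Mean response change opposite in sign to the mean perturbation."""
        return bool(np.sign(self.mean_delta_r) == -np.sign(self.mean_delta_s))

    @property
    def specific_paradoxical(self) -> bool:
        """Significant negative slope (the specific paradoxical effect)."""
        return bool(self.slope < 0 and self.p_value < 0.05)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)

    def summary(self) -> str:
        lines = [
            "Perturbation slope (inhibitory response change vs input perturbation)",
            f"  n points            {self.n_points}",
            f"  slope               {self.slope: .4f}  (p = {self.p_value:.3g})",
            f"  intercept           {self.intercept: .4f}",
            f"  mean delta r_I      {self.mean_delta_r: .4f}",
            f"  mean delta s_I      {self.mean_delta_s: .4f}",
            f"  nonspecific paradoxical  {self.nonspecific_paradoxical}",
            f"  specific paradoxical     {self.specific_paradoxical}",
        ]
        return "\n".join(lines)


def perturbation_slope(delta_r_i: np.ndarray, delta_s_i: np.ndarray) -> SlopeResult:
    """OLS regression of response changes on input perturbations.

    Two-sided t-test on the slope; requires >= 3 points and a non-degenerate
    perturbation axis.
    """
    delta_r_i = np.asarray(delta_r_i, dtype=float)
    delta_s_i = np.asarray(delta_s_i, dtype=float)
    if delta_r_i.size < 3:
        raise ValueError("need at least 3 points for the slope fit")
    if np.ptp(delta_s_i) == 0:
        raise ValueError("degenerate regressor: all perturbations identical")
    fit = stats.linregress(delta_s_i, delta_r_i)
    return SlopeResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        mean_delta_r=float(delta_r_i.mean()),
        mean_delta_s=float(delta_s_i.mean()),
        n_points=delta_r_i.size,
    )


@dataclass
class SelectivityTrace:
    """Per-window population PO / OSI of the excitatory population.

    ``po`` in [0, pi) (NaN where invalid), ``osi`` in [0, 1]; ``valid`` masks
    windows with at least the minimum number of active neurons.
    """

    po: np.ndarray
    osi: np.ndarray
    valid: np.ndarray
    window_ms: float
    min_active: int


def windowed_activity(
    record: ActivityRecord, window_ms: float = WINDOW_MS, population: str = "E"
) -> np.ndarray:
    """Per-window activity matrix (n_windows, n_neurons) of one population.

    Spiking records: spike counts per window.  Rate records: window-mean
    rates (the record's native sampling is aggregated into windows; the
    ``window_ms`` argument is then in the record's own time units).
    """
    lo, hi = (0, record.n_e) if population == "E" else (record.n_e, record.n)
    t0 = record.schedule.windows[0].t_start
    t1 = record.schedule.t_stop
    n_win = int(np.floor((t1 - t0) / window_ms))
    if record.kind == "spikes":
        mask = (record.spike_ids >= lo) & (record.spike_ids < hi)
        ids = record.spike_ids[mask] - lo
        wins = np.floor((record.spike_times[mask] - t0) / window_ms).astype(int)
        ok = (wins >= 0) & (wins < n_win)
        out = np.zeros((n_win, hi - lo))
        np.add.at(out, (wins[ok], ids[ok]), 1.0)
        return out
    # rate record: average samples falling into each window
    wins = np.floor((record.times - t0) / window_ms).astype(int)
    out = np.zeros((n_win, hi - lo))
    counts = np.zeros(n_win)
    ok = (wins >= 0) & (wins < n_win)
    np.add.at(out, wins[ok], record.rates[ok][:, lo:hi])
    np.add.at(counts, wins[ok], 1.0)
    counts[counts == 0] = 1.0
    return out / counts[:, None]


def population_selectivity(
    activity: np.ndarray | ActivityRecord,
    orientations: np.ndarray,
    window_ms: float = WINDOW_MS,
    min_active: int = MIN_ACTIVE,
    *,
    printed_angle: bool = False,
) -> SelectivityTrace:
    """Windowed population PO and OSI from the circular mean of activity.

    Per window, R = sum_j r_j exp(2 i theta*_j) / sum_j r_j over excitatory
    neurons; pop PO = arg(R)/2 mapped to [0, pi), pop OSI = |R|.  Windows
    with fewer than ``min_active`` active neurons are masked.  ``activity``
    is either a pre-windowed (n_windows, n_E) matrix or an ActivityRecord.
    ``printed_angle`` uses exp(2 pi i theta) instead of the doubled angle.
    """
    if isinstance(activity, ActivityRecord):
        activity = windowed_activity(activity, window_ms, population="E")
    activity = np.asarray(activity, dtype=float)
    theta = np.asarray(orientations, dtype=float)[: activity.shape[1]]
    phase = 2.0 * np.pi * theta if printed_angle else 2.0 * theta
    z = np.exp(1j * phase)
    total = activity.sum(axis=1)
    n_active = (activity > 0).sum(axis=1)
    valid = n_active >= min_active
    r = np.full(activity.shape[0], np.nan, dtype=complex)
    nz = total > 0
    r[nz] = (activity[nz] @ z) / total[nz]
    osi = np.abs(r)
    po = np.mod(np.angle(r) / 2.0, np.pi)
    po[~valid] = np.nan
    osi[~valid] = np.nan
    return SelectivityTrace(
        po=po, osi=osi, valid=valid, window_ms=window_ms, min_active=min_active
    )


@dataclass
class STResult:
    """Spontaneous-transition index with optional shuffle null."""

    sti: float
    h_osi: float
    mean_osi: float
    histogram: np.ndarray
    n_selective: int
    null_mean: float | None = None
    null_std: float | None = None

    @property
    def sti_bootstrapped(self) -> float | None:
        """Observed STI minus the shuffle-null mean."""
        if self.null_mean is None:
            return None
        return self.sti - self.null_mean

    @property
    def degenerate(self) -> bool:
        """No selective windows: STI defined as 0."""
        return self.n_selective == 0


def st_index(
    trace: SelectivityTrace,
    osi_threshold: float = OSI_THRESHOLD,
    n_bins: int = N_PO_BINS,
    *,
    average_all_valid: bool = True,
) -> STResult:
    """Spontaneous-transition index STI = (1 - H_osi) * <pop OSI>.

    H(theta) is the histogram (bin width pi/n_bins) of population POs of
    selective windows (pop OSI > threshold); H_osi is the circular
    selectivity of H on the doubled circle.  <pop OSI> is averaged over all
    valid windows by default; ``average_all_valid=False`` restricts it to
    selective windows, which structurally inflates the index for nonspecific
    networks (their rare chance-selective windows carry random POs and high
    OSI), so the all-window form preserves the ordering across conditions.
    Zero selective windows yield STI = 0 with the ``degenerate`` flag.
    """
    sel = trace.valid & (np.nan_to_num(trace.osi) > osi_threshold)
    n_sel = int(sel.sum())
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    if n_sel == 0:
        return STResult(
            sti=0.0, h_osi=1.0, mean_osi=0.0, histogram=np.zeros(n_bins), n_selective=0
        )
    hist, _ = np.histogram(trace.po[sel], bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h_osi = float(np.abs(hist @ np.exp(2j * centers)) / hist.sum())
    if average_all_valid:
        mean_osi = float(np.nanmean(trace.osi[trace.valid]))
    else:
        mean_osi = float(np.nanmean(trace.osi[sel]))
    sti = (1.0 - h_osi) * mean_osi
    return STResult(
        sti=sti, h_osi=h_osi, mean_osi=mean_osi, histogram=hist, n_selective=n_sel
    )


def bootstrap_st(
    activity: np.ndarray | ActivityRecord,
    orientations: np.ndarray,
    n_shuffles: int = N_SHUFFLES,
    seed: int | None = None,
    window_ms: float = WINDOW_MS,
    min_active: int = MIN_ACTIVE,
    osi_threshold: float = OSI_THRESHOLD,
    n_bins: int = N_PO_BINS,
) -> STResult:
    """STI with a shuffle null: each neuron's activity permuted in time.

    The observed STI is complemented by the mean/std of the STI over
    ``n_shuffles`` independent within-neuron time permutations; the
    bootstrapped STI is the observed value minus the null mean.
    """
    if isinstance(activity, ActivityRecord):
        activity = windowed_activity(activity, window_ms, population="E")
    activity = np.asarray(activity, dtype=float)
    obs = st_index(
        population_selectivity(activity, orientations, window_ms, min_active),
        osi_threshold,
        n_bins,
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    n_win = activity.shape[0]
    for k in range(n_shuffles):
        shuffled = np.empty_like(activity)
        for j in range(activity.shape[1]):
            shuffled[:, j] = activity[rng.permutation(n_win), j]
        null[k] = st_index(
            population_selectivity(shuffled, orientations, window_ms, min_active),
            osi_threshold,
            n_bins,
        ).sti
    return STResult(
        sti=obs.sti,
        h_osi=obs.h_osi,
        mean_osi=obs.mean_osi,
        histogram=obs.histogram,
        n_selective=obs.n_selective,
        null_mean=float(null.mean()),
        null_std=float(null.std()),
    )


def pattern_interval_correlation(
    activity: np.ndarray | ActivityRecord,
    window_ms: float = WINDOW_MS,
    max_interval: int | None = None,
    min_pairs: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean correlation of population-activity vectors vs time interval.

    For each interval Delta (in windows), averages the Pearson correlation
    between excitatory population-activity vectors in window pairs separated
    by Delta.  Intervals with fewer than ``min_pairs`` pairs (or undefined
    correlations) are NaN-masked.  Returns (intervals, correlations).
    """
    if isinstance(activity, ActivityRecord):
        activity = windowed_activity(activity, window_ms, population="E")
    activity = np.asarray(activity, dtype=float)
    n_win = activity.shape[0]
    centered = activity - activity.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    unit = np.zeros_like(centered)
    unit[ok] = centered[ok] / norms[ok, None]
    max_interval = n_win - 1 if max_interval is None else min(max_interval, n_win - 1)
    intervals = np.arange(max_interval + 1)
    corr = np.full(intervals.size, np.nan)
    for d in intervals:
        pairs_ok = ok[: n_win - d] & ok[d:]
        if pairs_ok.sum() < min_pairs and d > 0:
            continue
        if pairs_ok.sum() == 0:
            continue
        vals = np.einsum("ij,ij->i", unit[: n_win - d][pairs_ok], unit[d:][pairs_ok])
        corr[d] = vals.mean()
    return intervals, corr


def reference_sweep(
    w,
    similarity: np.ndarray,
    responsive: np.ndarray,
    s_base: np.ndarray,
    gamma: float = 0.25,
    kappa: float = 2.0,
    alpha_level: float = 0.05,
    rate_params=None,
    settle_time: float | None = None,
) -> dict:
    """Similarity-patterned perturbation for every responsive reference cell.

    For each responsive inhibitory neuron as the reference, builds the
    pattern -gamma exp(kappa psi_ref) over all inhibitory neurons
    (non-responsive units, whose similarity to the reference is undefined,
    receive the neutral value -gamma exp(0)), runs the perturbation to
    steady state against a shared baseline, and fits the slope over the
    responsive units.  Among references with significant slopes (p <
    ``alpha_level``), reports the fraction with a negative slope.

    All perturbed steady states are integrated in parallel (one column per
    reference) from the shared baseline state.
    """
    from . import dynamics
    from .dynamics import RateParams, steady_state

    params = rate_params or RateParams()
    w_arr, n_e, n_i = dynamics._as_weights(w)
    similarity = np.asarray(similarity, dtype=float)
    responsive = np.asarray(responsive, dtype=int)
    n_ref = responsive.size
    if settle_time is None:
        settle_time = 40.0 * params.tau

    s_base = np.asarray(s_base, dtype=float)
    r_base = steady_state(w, s_base, params, t_settle=settle_time)

    # pattern matrix: column per reference, rows = all inhibitory neurons
    delta = np.full((n_i, n_ref), -gamma)  # exp(kappa * 0) baseline for non-responsive
    for col, ref_local in enumerate(range(n_ref)):
        delta[responsive, col] = -gamma * np.exp(kappa * similarity[ref_local])
    s_matrix = np.repeat(s_base[:, None], n_ref, axis=1)
    s_matrix[n_e:, :] += delta
    r_pert = steady_state(w, s_matrix, params, r0=r_base, t_settle=settle_time)

    delta_r_i = r_pert[n_e:, :] - r_base[n_e:, None]
    slopes, pvals = np.empty(n_ref), np.empty(n_ref)
    for col in range(n_ref):
        res = perturbation_slope(delta_r_i[responsive, col], delta[responsive, col])
        slopes[col], pvals[col] = res.slope, res.p_value
    sig = pvals < alpha_level
    n_sig = int(sig.sum())
    if n_sig == 0:
        raise ValueError("no reference cell yielded a significant slope")
    fraction_negative = float((slopes[sig] < 0).sum() / n_sig)
    return {
        "slopes": slopes,
        "p_values": pvals,
        "significant": sig,
        "fraction_negative": fraction_negative,
        "n_references": n_ref,
    }
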