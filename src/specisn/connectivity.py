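"""Block-structured E/I weight matrices with feature-specific modulation.

Two generative rules are supported, both all-to-all:

* ring rule — neurons carry a preferred orientation theta* and the weight of
  an (i <- j) connection is J * (1 + m * cos(2 (theta*_i - theta*_j))), with
  block-specific base weight J and specificity m in [0, 1];
* receptive-field rule — the weight is J * (0.1 + m * exp(eta * psi_ij)) with
  psi the pairwise RF correlation and eta the sharpness of the dependence.

Optional per-synapse multiplicative noise zeta ~ U[0, 2] preserves mean
weights and Dale signs.  Variant transforms cover fewer-but-stronger
inhibitory neurons (80/20 E/I with 4x inhibitory weights) and broader
(less specific) inhibitory connectivity with a stability recalibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BlockParams",
    "WeightMatrix",
    "build_ring_weights",
    "build_rf_weights",
    "apply_ei_ratio_variant",
    "apply_broad_inhibition_variant",
    "stability_report",
    "StabilityReport",
]

BLOCKS = ("EE", "IE", "EI", "II")  # (post <- pre): EE=E<-E, IE=I<-E, EI=E<-I, II=I<-I


@dataclass
class BlockParams:
    """Generative parameters of the four weight blocks.

    j: base weight per block (arbitrary units for rate nets, mV for spiking);
    m: specificity per block in [0, 1]; eta: exponent of the RF rule;
    zeta: per-synapse multiplicative noise U[0, 2] on/off;
    heterogeneous_m: replace each block's m by per-synapse U[0, 1] draws.
    """

    j: dict[str, float] = field(
        default_factory=lambda: {"EE": 0.05, "IE": 0.05, "EI": -0.075, "II": -0.075}
    )
    m: dict[str, float] = field(
        default_factory=lambda: {"EE": 1.0, "IE": 1.0, "EI": 1.0, "II": 1.0}
    )
    eta: float = 2.0
    zeta: bool = True
    heterogeneous_m: bool = False

    def __post_init__(self) -> None:
        for b in BLOCKS:
            if not 0.0 <= self.m[b] <= 1.0:
                raise ValueError(f"specificity m[{b}] must lie in [0, 1], got {self.m[b]}")
        if self.j["EE"] < 0 or self.j["IE"] < 0:
            raise ValueError("excitatory base weights must be nonnegative")
        if self.j["EI"] > 0 or self.j["II"] > 0:
            raise ValueError("inhibitory base weights must be nonpositive")
        if not self.eta > 0:
            raise ValueError("eta must be positive")

    def with_uniform_m(self, value: float) -> "BlockParams":
        return replace(self, m={b: value for b in BLOCKS})


@dataclass
class WeightMatrix:
    """Dense weight matrix over (E then I) x (E then I), entry (post, pre)."""

    w: np.ndarray
    n_e: int
    n_i: int
    params: BlockParams | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    def block(self, name: str) -> np.ndarray:
        """View of one of the four blocks (post <- pre)."""
        ne = self.n_e
        sl = {"E": slice(0, ne), "I": slice(ne, self.n)}
        return self.w[sl[name[0]], sl[name[1]]]


def _block_slices(n_e: int, n_i: int) -> dict[str, tuple[slice, slice]]:
    e, i = slice(0, n_e), slice(n_e, n_e + n_i)
    return {"EE": (e, e), "IE": (i, e), "EI": (e, i), "II": (i, i)}


def _apply_noise(w: np.ndarray, n_e: int, n_i: int, params: BlockParams, rng) -> None:
    if params.zeta:
        w *= rng.uniform(0.0, 2.0, w.shape)


def build_ring_weights(
    orientations: np.ndarray,
    params: BlockParams,
    seed: int | None = None,
    n_e: int | None = None,
    zero_diagonal: bool = False,
) -> WeightMatrix:
    """Build the ring (1D orientation-specific) weight matrix.

    ``orientations``: theta* per neuron, E neurons first; ``n_e`` defaults to
    half the population.  Self-connections follow the same rule as every
    other pair (connectivity is all-to-all); ``zero_diagonal`` excludes them.
    Keeping them makes the uniform- and specific-mode eigenvalues exactly
    N*J and N*J*m/2, so simulations line up with the closed-form theory.
    """
    theta = np.asarray(orientations, dtype=float)
    n = theta.size
    n_e = n // 2 if n_e is None else n_e
    n_i = n - n_e
    rng = np.random.default_rng(seed)
    cosmat = np.cos(2.0 * (theta[:, None] - theta[None, :]))
    w = np.empty((n, n))
    for name, (rows, cols) in _block_slices(n_e, n_i).items():
        if params.heterogeneous_m:
            m = rng.uniform(0.0, 1.0, (rows.stop - rows.start, cols.stop - cols.start))
        else:
            m = params.m[name]
        w[rows, cols] = params.j[name] * (1.0 + m * cosmat[rows, cols])
    _apply_noise(w, n_e, n_i, params, rng)
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w, n_e=n_e, n_i=n_i, params=params, seed=seed)


def build_rf_weights(
    psi: np.ndarray,
    params: BlockParams,
    n_e: int | None = None,
    seed: int | None = None,
    zero_diagonal: bool = False,
) -> WeightMatrix:
    """Build the RF-correlation weight matrix J * (0.1 + m * exp(eta * psi))."""
    psi = np.asarray(psi, dtype=float)
    if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
        raise ValueError("psi must be a square similarity matrix")
    if np.any(np.abs(psi) > 1.0 + 1e-9):
        raise ValueError("psi entries must lie in [-1, 1]")
    n = psi.shape[0]
    n_e = n // 2 if n_e is None else n_e
    n_i = n - n_e
    rng = np.random.default_rng(seed)
    exppsi = np.exp(params.eta * psi)
    w = np.empty((n, n))
    for name, (rows, cols) in _block_slices(n_e, n_i).items():
        if params.heterogeneous_m:
            m = rng.uniform(0.0, 1.0, (rows.stop - rows.start, cols.stop - cols.start))
        else:
            m = params.m[name]
        w[rows, cols] = params.j[name] * (0.1 + m * exppsi[rows, cols])
    _apply_noise(w, n_e, n_i, params, rng)
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w, n_e=n_e, n_i=n_i, params=params, seed=seed)


def apply_ei_ratio_variant(
    n_e: int, n_i: int, params: BlockParams
) -> tuple[int, int, BlockParams]:
    """Biological E/I ratio: N_I = N_E / 4 with 4x stronger inhibitory weights.

    Total inhibition onto each cell (N_I * |J_EI|) is preserved.
    """
    if n_e % 4 != 0:
        warnings.warn(f"n_e={n_e} not divisible by 4; rounding n_i", stacklevel=2)
    new_n_i = max(n_e // 4, 1)
    j = dict(params.j)
    j["EI"] *= 4.0
    j["II"] *= 4.0
    return n_e, new_n_i, replace(params, j=j)


@dataclass
class StabilityReport:
    """Leading eigenvalues of the full matrix and of the E->E block.

    The network is an ISN when the excitatory subnetwork alone is unstable
    (leading Re eig(W_EE) > 1) while the full network is stable
    (all Re eig(W) < 1, the fixed-point condition of the linearized rate
    dynamics).
    """

    leading_full: float
    leading_ee: float

    @property
    def is_stable(self) -> bool:
        return self.leading_full < 1.0

    @property
    def is_isn(self) -> bool:
        return self.leading_ee > 1.0 and self.is_stable


def stability_report(wm: WeightMatrix) -> StabilityReport:
    """Eigenvalue-based stability / ISN classification of a weight matrix."""
    eig_full = np.linalg.eigvals(wm.w)
    eig_ee = np.linalg.eigvals(wm.block("EE"))
    return StabilityReport(
        leading_full=float(eig_full.real.max()),
        leading_ee=float(eig_ee.real.max()),
    )


def apply_broad_inhibition_variant(
    wm_builder,
    params: BlockParams,
    m_broad: float,
    *,
    margin: float = 0.05,
    max_scale: float = 64.0,
    tol: float = 1e-3,
) -> tuple[WeightMatrix, float]:
    """Broaden inhibitory-path specificity and recalibrate for stability.

    Blocks IE, EI, II get specificity ``m_broad`` (< m_EE broadens them).
    If the resulting network is unstable, |J_EI| and |J_II| are scaled by a
    common factor, bisected until the leading eigenvalue of the full matrix
    sits below 1 - ``margin``.  ``wm_builder(params)`` must return a
    WeightMatrix built from the given BlockParams.

    Returns the recalibrated matrix and the inhibitory scale factor used.
    """
    if m_broad > params.m["EE"]:
        raise ValueError("m_broad must not exceed m_EE")
    m = dict(params.m)
    for b in ("IE", "EI", "II"):
        m[b] = m_broad
    broad = replace(params, m=m)

    def build(scale: float) -> WeightMatrix:
        j = dict(broad.j)
        j["EI"] *= scale
        j["II"] *= scale
        return wm_builder(replace(broad, j=j))

    wm = build(1.0)
    if stability_report(wm).leading_full < 1.0 - margin:
        return wm, 1.0
    # find an upper bracket, then bisect the inhibitory scale
    hi = 2.0
    while stability_report(build(hi)).leading_full >= 1.0 - margin:
        hi *= 2.0
        if hi > max_scale:
            raise RuntimeError("broad-inhibition calibration failed to stabilize")
    lo = 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stability_report(build(mid)).leading_full >= 1.0 - margin:
            lo = mid
        else:
            hi = mid
    return build(hi), hi
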