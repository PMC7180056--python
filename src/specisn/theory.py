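"""Linear-response theory of patterned inhibitory perturbations.

At a fixed point of the linear (n = 1, unrectified) rate dynamics,

    r_E = W_EE r_E + W_EI r_I + s_E
    r_I = W_IE r_E + W_II r_I + s_I,

so a perturbation delta_s applied to inhibitory neurons alone changes the
inhibitory rates by

    delta_r_I = M delta_s,    M = [I - W_IE (I - W_EE)^{-1} W_EI - W_II]^{-1}.

When the perturbation is aligned with a *specific eigenmode* v* of the shared
excitatory profile W (W v* = lambda v*) and the inhibitory outgoing profile is
-g W (inhibition dominance g), the response along the mode collapses to a
scalar slope

    delta_r_I = (1 - lambda) / (1 - (1 - g) lambda) * v*,

which is negative exactly when lambda > 1 (the mode would be unstable without
inhibition) and g > 1 (inhibition dominates) — the specific-ISN condition.
That slope is the analytic counterpart of the regression slope measured on
simulated perturbation experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearResponseModel",
    "linear_response",
    "closed_form_slope",
    "specific_mode_spectrum",
    "eigenvector_similarity_profile",
    "rank_one_network",
]


@dataclass
class LinearResponseModel:
    """Inhibitory linear-response matrix M of a block-structured network."""

    w_ee: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    w_ii: np.ndarray
    m: np.ndarray

    @classmethod
    def from_weight_matrix(cls, wm) -> "LinearResponseModel":
        return cls.from_blocks(wm.block("EE"), wm.block("EI"), wm.block("IE"), wm.block("II"))

    @classmethod
    def from_blocks(cls, w_ee, w_ei, w_ie, w_ii) -> "LinearResponseModel":
        w_ee, w_ei, w_ie, w_ii = map(np.atleast_2d, (w_ee, w_ei, w_ie, w_ii))
        n_e = w_ee.shape[0]
        n_i = w_ii.shape[0]
        eye_e, eye_i = np.eye(n_e), np.eye(n_i)
        try:
            inv_e = np.linalg.solve(eye_e - w_ee, w_ei)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("(I - W_EE) is singular") from err
        bracket = eye_i - w_ie @ inv_e - w_ii
        try:
            m = np.linalg.inv(bracket)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "[I - W_IE (I - W_EE)^-1 W_EI - W_II] is singular"
            ) from err
        return cls(w_ee=w_ee, w_ei=w_ei, w_ie=w_ie, w_ii=w_ii, m=m)

    def predict(self, delta_s_i: np.ndarray) -> np.ndarray:
        return self.m @ np.asarray(delta_s_i, dtype=float)


def linear_response(wm_or_model, delta_s_i: np.ndarray) -> np.ndarray:
    """Predicted inhibitory rate change for an input perturbation delta_s_I."""
    if isinstance(wm_or_model, LinearResponseModel):
        model = wm_or_model
    else:
        model = LinearResponseModel.from_weight_matrix(wm_or_model)
    return model.predict(delta_s_i)


def closed_form_slope(lam: float, g: float) -> float:
    """Slope (1 - lambda) / (1 - (1 - g) lambda) of the specific-mode response.

    lam is the eigenvalue of the specific excitatory mode; g the inhibition
    dominance along that mode.  Negative throughout the specific-ISN regime
    (lam > 1 and g > 1); positive for a stable non-ISN mode (lam < 1, g > 1).
    """
    denom = 1.0 - (1.0 - g) * lam
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("pole of the specific-mode response: 1 - (1-g)*lambda = 0")
    return (1.0 - lam) / denom


def rank_one_network(v: np.ndarray, lam: float, g: float) -> dict[str, np.ndarray]:
    """Construct blocks realizing a pure specific mode.

    All excitatory outgoing blocks are lam * v v^T (unit-norm v), inhibitory
    outgoing blocks are -g times that; useful as an exact test bed for the
    closed-form slope.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    w = lam * np.outer(v, v)
    return {"EE": w, "IE": w, "EI": -g * w, "II": -g * w}


def specific_mode_spectrum(
    wm, seed: int | None = None, n_modes: int = 2
) -> dict[str, np.ndarray]:
    """Spectrum after isolating the specific E->E structure.

    Keeps W_EE intact while randomly permuting the entries of the E->I, I->E
    and I->I blocks (each block's entry multiset — hence mean, variance and
    Dale sign — is preserved).  This suppresses coherent specific structure in
    the inhibitory pathways so the leading non-uniform eigenmodes of the
    permuted matrix are the *specific* excitatory modes.

    Returns eigenvalues sorted by descending real part, the permuted matrix,
    and the top ``n_modes`` unit-norm eigenvectors (sign fixed so the
    largest-magnitude E component is positive).
    """
    rng = np.random.default_rng(seed)
    w = wm.w.copy()
    ne, n = wm.n_e, wm.n
    for rows, cols in [
        (slice(ne, n), slice(0, ne)),  # IE
        (slice(0, ne), slice(ne, n)),  # EI
        (slice(ne, n), slice(ne, n)),  # II
    ]:
        block = w[rows, cols]
        flat = block.ravel()
        w[rows, cols] = rng.permutation(flat).reshape(block.shape)
    eigvals, eigvecs = np.linalg.eig(w)
    order = np.argsort(-eigvals.real)
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    vectors = []
    for k in range(min(n_modes, n)):
        v = eigvecs[:, k]
        if np.max(np.abs(v.imag)) > 1e-8 * max(np.max(np.abs(v.real)), 1e-30):
            warnings.warn("complex eigenvector: using real part", stacklevel=2)
        v = v.real
        v = v / np.linalg.norm(v)
        e_comp = v[:ne]
        if e_comp[np.argmax(np.abs(e_comp))] < 0:
            v = -v
        vectors.append(v)
    return {"eigenvalues": eigvals, "matrix": w, "vectors": np.array(vectors)}


def eigenvector_similarity_profile(
    v: np.ndarray,
    psi: np.ndarray,
    orientations: np.ndarray,
    reference: int,
    n_e: int | None = None,
) -> dict[str, float | np.ndarray]:
    """Correlate eigenvector E-components with two similarity orderings.

    Pairs the E components of eigenvector ``v`` with (a) the RF correlation of
    each E cell to ``reference`` and (b) a 1D orientation-similarity ordering
    cos(2 (theta* - theta*_ref)).  Returns both profiles and the Pearson
    correlation of the component values with each ordering.
    """
    v = np.asarray(v)
    if np.iscomplexobj(v):
        if np.max(np.abs(v.imag)) > 1e-8:
            warnings.warn("complex eigenvector: using real part", stacklevel=2)
        v = v.real
    n_e = v.size if n_e is None else n_e
    comp = v[:n_e]
    rf_sim = np.asarray(psi)[reference, :n_e]
    ori_sim = np.cos(2.0 * (np.asarray(orientations)[:n_e] - orientations[reference]))
    comp_c = comp - comp.mean()

    def _corr(sim):
        sim_c = sim - sim.mean()
        denom = np.linalg.norm(comp_c) * np.linalg.norm(sim_c)
        return float(comp_c @ sim_c / denom) if denom > 0 else 0.0

    return {
        "components": comp,
        "rf_similarity": rf_sim,
        "orientation_similarity": ori_sim,
        "corr_rf": _corr(rf_sim),
        "corr_orientation": _corr(ori_sim),
    }
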