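"""Gabor receptive fields, stimulus ensembles, and their similarity structure.

This module is the synthetic-data stage of the package: every "observation"
downstream (connectivity, stimulus drive, response similarity) derives from
banks of 2D Gabor receptive fields and stimulus sets generated here.

A Gabor field on the visual plane is

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambda + phi)

with (x', y') the coordinates rotated by the preferred orientation theta about
the field centre (x0, y0), sigma the envelope width (degrees), gamma the
aspect ratio, lambda = 1/omega the wavelength (omega in cycles/degree) and phi
the spatial phase.  Similarity between two fields is the Pearson correlation
of their rasterized pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaborParams",
    "GridSpec",
    "RFBank",
    "StimulusSet",
    "make_gabor",
    "make_grating",
    "sample_gabor_params",
    "sample_rf_bank",
    "rf_correlation",
    "make_stimuli",
    "stimulus_drive",
]

# Defaults mirror the generative statistics of the receptive-field population:
# orientation and phase uniform on [0, pi), envelope width 2.5 deg, aspect 0.5,
# spatial frequency ~ Gamma(shape=2, scale=0.04) c/deg, centres jittered
# uniformly within +/- 1.25 deg of the field centre.
SIGMA_DEFAULT = 2.5
GAMMA_ASPECT_DEFAULT = 0.5
OMEGA_GAMMA_SHAPE = 2.0
OMEGA_GAMMA_SCALE = 0.04
CENTER_JITTER = 1.25


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single 2D Gabor field.

    theta, phi in radians on [0, pi); sigma (deg) > 0; gamma_aspect > 0;
    omega (cycles/deg) > 0; center = (x0, y0) in degrees.
    """

    theta: float
    phi: float
    sigma: float = SIGMA_DEFAULT
    gamma_aspect: float = GAMMA_ASPECT_DEFAULT
    omega: float = 0.08
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.gamma_aspect > 0:
            raise ValueError(f"gamma_aspect must be positive, got {self.gamma_aspect}")
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")


@dataclass(frozen=True)
class GridSpec:
    """Pixel grid of the visual field.

    ``extent`` L is the extent of the visual field in each direction in degrees; the field
    spans [-L/2, L/2) per axis at ``resolution`` pixels per degree.  The
    default (L = 50 deg at 4 ppd) rasterizes to 200 x 200 pixels.
    """

    extent: float = 50.0
    resolution: float = 4.0

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent * self.resolution))

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (x, y) in degrees."""
        n = self.n_pixels
        half = self.extent / 2.0
        coords = (np.arange(n) + 0.5) / self.resolution - half
        return coords, coords

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = self.axes()
        return np.meshgrid(x, y)


@dataclass
class RFBank:
    """Receptive-field bank: per-neuron Gabor parameters plus raster stack.

    ``fields`` is (n_neurons, n_pix, n_pix), excitatory neurons first.
    """

    params_e: list[GaborParams]
    params_i: list[GaborParams]
    grid: GridSpec
    fields: np.ndarray
    seed: int | None = None

    @property
    def n_e(self) -> int:
        return len(self.params_e)

    @property
    def n_i(self) -> int:
        return len(self.params_i)

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    @property
    def params(self) -> list[GaborParams]:
        return self.params_e + self.params_i

    def orientations(self) -> np.ndarray:
        """Preferred orientations theta* of all neurons (E then I)."""
        return np.array([p.theta for p in self.params])

    def to_frame(self):
        """Per-neuron parameter table (one row per neuron, E then I)."""
        import pandas as pd

        rows = [
            {
                "population": "E" if k < self.n_e else "I",
                "theta": p.theta,
                "phi": p.phi,
                "sigma": p.sigma,
                "gamma_aspect": p.gamma_aspect,
                "omega": p.omega,
                "x0": p.center[0],
                "y0": p.center[1],
            }
            for k, p in enumerate(self.params)
        ]
        return pd.DataFrame(rows)


@dataclass
class StimulusSet:
    """Rasterized stimulus ensemble sharing the grid of an RF bank."""

    kind: str  # rf_like | grating_fixed_sf | grating_var_sf | user_images
    grid: GridSpec
    fields: np.ndarray  # (n_stimuli, n_pix, n_pix)
    params: list | None = None
    seed: int | None = None

    @property
    def n_stimuli(self) -> int:
        return self.fields.shape[0]


def make_gabor(
    params: GaborParams, grid: GridSpec, *, printed_envelope: bool = False
) -> np.ndarray:
    """Rasterize a Gabor field on the grid.

    ``printed_envelope`` switches the envelope exponent from the standard
    gamma^2 * y'^2 to gamma * y'^2 (an alternative convention).
    """
    x, y = grid.mesh()
    x0, y0 = params.center
    dx, dy = x - x0, y - y0
    ct, st = np.cos(params.theta), np.sin(params.theta)
    xp = dx * ct + dy * st
    yp = -dx * st + dy * ct
    g = params.gamma_aspect if printed_envelope else params.gamma_aspect**2
    envelope = np.exp(-(xp**2 + g * yp**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * np.pi * params.omega * xp + params.phi)
    return envelope * carrier


def make_grating(theta: float, phi: float, omega: float, grid: GridSpec) -> np.ndarray:
    """Full-field sinusoidal grating cos(2 pi omega x' + phi)."""
    x, y = grid.mesh()
    xp = x * np.cos(theta) + y * np.sin(theta)
    return np.cos(2.0 * np.pi * omega * xp + phi)


def sample_gabor_params(n: int, rng: np.random.Generator) -> list[GaborParams]:
    """Draw n parameter sets from the population statistics."""
    theta = rng.uniform(0.0, np.pi, n)
    phi = rng.uniform(0.0, np.pi, n)
    omega = rng.gamma(OMEGA_GAMMA_SHAPE, OMEGA_GAMMA_SCALE, n)
    centers = rng.uniform(-CENTER_JITTER, CENTER_JITTER, (n, 2))
    return [
        GaborParams(
            theta=float(theta[k]),
            phi=float(phi[k]),
            omega=float(max(omega[k], 1e-6)),
            center=(float(centers[k, 0]), float(centers[k, 1])),
        )
        for k in range(n)
    ]


def sample_rf_bank(
    n_e: int,
    n_i: int,
    grid: GridSpec | None = None,
    seed: int | None = None,
    *,
    dtype=np.float64,
) -> RFBank:
    """Sample an RF bank of n_e excitatory and n_i inhibitory Gabor fields."""
    if n_e <= 0 or n_i <= 0:
        raise ValueError("population sizes must be positive")
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    params_e = sample_gabor_params(n_e, rng)
    params_i = sample_gabor_params(n_i, rng)
    n_pix = grid.n_pixels
    fields = np.empty((n_e + n_i, n_pix, n_pix), dtype=dtype)
    for k, p in enumerate(params_e + params_i):
        fields[k] = make_gabor(p, grid)
    return RFBank(params_e=params_e, params_i=params_i, grid=grid, fields=fields, seed=seed)


def _zscore_flat(fields: np.ndarray) -> np.ndarray:
    flat = fields.reshape(fields.shape[0], -1).astype(np.float64)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance field: correlation undefined")
    return flat / norms[:, None]


def rf_correlation(bank: RFBank) -> np.ndarray:
    """Pairwise Pearson correlation psi of rasterized fields (E then I).

    Fields are centred and normalized so the correlation is the dot product
    of unit-norm residuals; psi is symmetric with unit diagonal.
    """
    z = _zscore_flat(bank.fields)
    psi = z @ z.T
    np.fill_diagonal(psi, 1.0)
    return np.clip(psi, -1.0, 1.0)


def make_stimuli(
    kind: str,
    n: int = 200,
    grid: GridSpec | None = None,
    seed: int | None = None,
    *,
    omega_fixed: float = 0.04,
    dtype=np.float64,
) -> StimulusSet:
    """Generate a stimulus ensemble.

    kind:
      - ``rf_like``: fields drawn from the same generative statistics as the
        receptive fields (the stimulus ensemble matching RF statistics).
      - ``grating_fixed_sf``: full-field gratings, theta/phi uniform [0, pi),
        spatial frequency fixed at ``omega_fixed`` (default 0.04 c/deg).
      - ``grating_var_sf``: gratings with omega drawn from the RF spatial-
        frequency distribution Gamma(2, 0.04).
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    n_pix = grid.n_pixels
    fields = np.empty((n, n_pix, n_pix), dtype=dtype)

    if kind == "rf_like":
        params = sample_gabor_params(n, rng)
        for k, p in enumerate(params):
            fields[k] = make_gabor(p, grid)
    elif kind in ("grating_fixed_sf", "grating_var_sf"):
        theta = rng.uniform(0.0, np.pi, n)
        phi = rng.uniform(0.0, np.pi, n)
        if kind == "grating_fixed_sf":
            omega = np.full(n, omega_fixed)
        else:
            omega = np.maximum(rng.gamma(OMEGA_GAMMA_SHAPE, OMEGA_GAMMA_SCALE, n), 1e-6)
        params = list(zip(theta, phi, omega))
        for k in range(n):
            fields[k] = make_grating(theta[k], phi[k], omega[k], grid)
    else:
        raise ValueError(f"unknown stimulus kind: {kind!r}")

    return StimulusSet(kind=kind, grid=grid, fields=fields, params=params, seed=seed)


def stimulus_drive(bank: RFBank, stimuli: StimulusSet, beta: float | None = None) -> np.ndarray:
    """External-drive modulation matrix, entry (neuron, stimulus).

    Each neuron's drive under a stimulus is 1 + beta * corr(stimulus, RF).
    beta defaults to 0.5 for rf_like stimuli and 1.0 for gratings (RF-like
    stimuli correlate more strongly with the RFs on average).
    """
    if stimuli.grid != bank.grid:
        raise ValueError("stimuli and RF bank must share the same grid")
    if beta is None:
        beta = 0.5 if stimuli.kind == "rf_like" else 1.0
    z_rf = _zscore_flat(bank.fields)
    z_st = _zscore_flat(stimuli.fields)
    corr = z_rf @ z_st.T
    return 1.0 + beta * corr
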