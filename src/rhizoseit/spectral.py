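"""Debye decomposition of complex resistivity spectra and polarization
length scales.

A cell's complex resistivity spectrum is described by a superposition of N
Debye relaxation terms on a fixed, log-spaced relaxation-time grid,

    rho*(omega) = rho_0 ( 1 - sum_k m_k [ 1 - 1/(1 + i omega tau_k) ] ),

with the direct-current resistivity rho_0 and non-negative chargeabilities
m_k.  The integral parameters are the total chargeability m_tot = sum m_k
(overall polarization strength) and the mean logarithmic relaxation time
tau_mean = exp( sum m_k ln tau_k / sum m_k ) (characteristic timescale).

The fit is solved as a smoothness-regularized non-negative least-squares
problem that is exactly linear in (rho_0, c_k) with c_k = rho_0 m_k, which
keeps per-cell decomposition fast and deterministic over whole images.

Relaxation times map to polarization length scales through ion diffusion in
the electrical double layer: tau = r^2 / (2 D), and to measurement frequency
through tau = 1/(2 pi f).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .forward import ComplexField

__all__ = [
    "RelaxationGrid",
    "DebyeFit",
    "DecompositionResult",
    "debye_forward",
    "fit_debye",
    "decompose_field",
    "relaxation_length",
    "length_to_tau",
    "frequency_to_tau",
    "tau_to_frequency",
]

#: ion diffusion coefficient in the Stern layer (m^2/s), standard value
DEFAULT_DIFFUSION = 1e-9
#: chargeability below which a cell is considered non-polarizable background
BACKGROUND_CHARGEABILITY = 1e-3


@dataclass(frozen=True)
class RelaxationGrid:
    """Log-spaced relaxation-time grid tau_k (seconds)."""

    taus: np.ndarray

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, float)
        if taus.ndim != 1 or len(taus) < 2 or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be a strictly increasing vector of length >= 2")
        object.__setattr__(self, "taus", taus)

    def __len__(self) -> int:
        return len(self.taus)

    @classmethod
    def from_band(
        cls, f_min: float = 0.79, f_max: float = 1000.0, points_per_decade: int = 20
    ) -> "RelaxationGrid":
        """Grid spanning one extra decade beyond the band's relaxation times:
        [tau(f_max)/10, 10 tau(f_min)] with ``points_per_decade`` points."""
        if not 0 < f_min < f_max:
            raise ValueError("need 0 < f_min < f_max")
        lo = frequency_to_tau(f_max) / 10.0
        hi = frequency_to_tau(f_min) * 10.0
        n = max(2, int(np.ceil(np.log10(hi / lo) * points_per_decade)) + 1)
        return cls(np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass
class DebyeFit:
    """Result of a single-cell Debye decomposition."""

    rho0: float
    m: np.ndarray
    grid: RelaxationGrid
    residual: float

    @property
    def m_tot(self) -> float:
        return float(self.m.sum())

    @property
    def tau_mean(self) -> float:
        """Chargeability-weighted geometric mean relaxation time (s); NaN for
        a non-polarizable cell."""
        s = self.m.sum()
        if s <= 0:
            return float("nan")
        return float(np.exp(self.m @ np.log(self.grid.taus) / s))


def debye_forward(
    rho0: float,
    m: Sequence[float],
    taus: Sequence[float],
    frequencies: Sequence[float],
) -> np.ndarray:
    """Complex resistivity spectrum of a Debye superposition."""
    m = np.atleast_1d(np.asarray(m, float))
    taus = np.atleast_1d(np.asarray(taus, float))
    if m.size != taus.size:
        raise ValueError("m and taus must have equal length")
    if m.sum() >= 1:
        raise ValueError("total chargeability must be < 1")
    w = 2 * np.pi * np.asarray(frequencies, float)
    if m.size == 0:
        return np.full(w.shape, rho0, complex)
    iwt = 1j * w[:, None] * taus[None, :]
    return rho0 * (1.0 - (m[None, :] * (iwt / (1.0 + iwt))).sum(axis=1))


def _design_matrix(grid: RelaxationGrid, frequencies: np.ndarray) -> np.ndarray:
    w = 2 * np.pi * frequencies
    g = (1j * w[:, None] * grid.taus[None, :]) / (1.0 + 1j * w[:, None] * grid.taus[None, :])
    n_f, n_k = len(frequencies), len(grid)
    a = np.zeros((2 * n_f, 1 + n_k))
    a[:n_f, 0] = 1.0
    a[:n_f, 1:] = -g.real
    a[n_f:, 1:] = -g.imag
    return a


def fit_debye(
    frequencies: Sequence[float],
    spectrum: Sequence[complex],
    grid: RelaxationGrid,
    regularization: float = 0.05,
) -> DebyeFit:
    """Fit rho_0 and a non-negative chargeability spectrum to rho*(omega).

    With c_k = rho_0 m_k the model is linear in (rho_0, c), so the problem is
    a convex NNLS with first-order smoothness rows (strength
    ``regularization``) on the c spectrum.  Residual is the RMS relative
    data misfit.
    """
    f = np.asarray(frequencies, float)
    rho = np.asarray(spectrum, complex)
    if not (np.isfinite(rho).all() and np.isfinite(f).all()):
        raise ValueError("non-finite spectrum values")
    if f.ndim != 1 or rho.shape != f.shape:
        raise ValueError("frequencies and spectrum must be equal-length vectors")
    a = _design_matrix(grid, f)
    d = np.concatenate([rho.real, rho.imag])
    scale = float(np.mean(np.abs(rho)))
    n_k = len(grid)
    diff = np.zeros((n_k - 1, 1 + n_k))
    idx = np.arange(n_k - 1)
    diff[idx, 1 + idx] = 1.0
    diff[idx, 2 + idx] = -1.0
    a_full = np.vstack([a / scale, regularization * diff])
    d_full = np.concatenate([d / scale, np.zeros(n_k - 1)])
    x, _ = nnls(a_full, d_full)
    rho0, c = float(x[0]), x[1:]
    if rho0 <= 0:
        raise RuntimeError("degenerate fit: non-positive rho_0")
    m = c / rho0
    pred = a[:, 0] * rho0 + a[:, 1:] @ c
    resid = float(np.sqrt(np.mean(((d - pred) / scale) ** 2)))
    return DebyeFit(rho0=rho0, m=m, grid=grid, residual=resid)


@dataclass
class DecompositionResult:
    """Per-cell integral-parameter images from decomposing a field stack."""

    m_tot: np.ndarray
    tau_mean: np.ndarray
    rho0: np.ndarray
    residual: np.ndarray
    failed: np.ndarray  # bool mask of cells whose fit was rejected

    @property
    def background(self) -> np.ndarray:
        """Cells considered non-polarizable background (m_tot < 1e-3)."""
        return self.m_tot < BACKGROUND_CHARGEABILITY


def decompose_field(
    fields: Sequence[ComplexField],
    grid: RelaxationGrid | None = None,
    regularization: float = 0.05,
) -> DecompositionResult:
    """Independent Debye decomposition of every cell of an inverted field
    stack (one ComplexField per frequency, shared mesh)."""
    if len(fields) < 2:
        raise ValueError("need spectra at >= 2 frequencies")
    fields = sorted(fields, key=lambda f: f.frequency)
    freqs = np.array([f.frequency for f in fields])
    n_cells = fields[0].sigma.shape[0]
    if any(f.sigma.shape[0] != n_cells for f in fields):
        raise ValueError("fields live on different meshes")
    if grid is None:
        grid = RelaxationGrid.from_band(freqs.min(), freqs.max())
    rho_cells = np.column_stack([f.rho for f in fields])  # (n_cells, n_freq)
    m_tot = np.full(n_cells, np.nan)
    tau_mean = np.full(n_cells, np.nan)
    rho0 = np.full(n_cells, np.nan)
    residual = np.full(n_cells, np.nan)
    failed = np.zeros(n_cells, bool)
    for c in range(n_cells):
        try:
            fit = fit_debye(freqs, rho_cells[c], grid, regularization)
        except (RuntimeError, ValueError):
            failed[c] = True
            continue
        m_tot[c] = fit.m_tot
        tau_mean[c] = fit.tau_mean
        rho0[c] = fit.rho0
        residual[c] = fit.residual
    return DecompositionResult(m_tot, tau_mean, rho0, residual, failed)


def relaxation_length(tau: float, diffusion: float = DEFAULT_DIFFUSION) -> float:
    """Polarization length scale r = sqrt(2 D tau) in metres."""
    if tau <= 0 or diffusion <= 0:
        raise ValueError("tau and D must be positive")
    return float(np.sqrt(2.0 * diffusion * tau))


def length_to_tau(r: float, diffusion: float = DEFAULT_DIFFUSION) -> float:
    """Relaxation time tau = r^2/(2D) of a polarization length scale r (m)."""
    if r <= 0 or diffusion <= 0:
        raise ValueError("r and D must be positive")
    return float(r**2 / (2.0 * diffusion))


def frequency_to_tau(f: float) -> float:
    """Relaxation time probed by measurement frequency f: tau = 1/(2 pi f)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return float(1.0 / (2.0 * np.pi * f))


def tau_to_frequency(tau: float) -> float:
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(1.0 / (2.0 * np.pi * tau))
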