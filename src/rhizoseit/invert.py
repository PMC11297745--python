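"""Smoothness-constrained Gauss-Newton complex-resistivity inversion.

Each frequency is inverted independently in two stages:

1. magnitude stage — damped Gauss-Newton on the log-resistivity model fitting
   log impedance magnitudes, first-order smoothness regularization, with the
   regularization strength cooled from a trace heuristic until the
   error-weighted RMS reaches ~1 (discrepancy principle);
2. phase stage — resistivity phases are small (tens of mrad), so the phase
   image solves a single linearized system about the converged magnitude
   model, using the same sensitivity matrix and smoothness operator, with its
   own regularization strength bisected to bring the phase RMS to ~1.

Data weights come from the linear magnitude / constant phase error models, so
an inversion of data contaminated with matching noise converges at RMS close
to 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .design import first_order_smoothness
from .forward import (
    ComplexDataset,
    ComplexField,
    FemOperator,
    MeasurementScheme,
    _scheme_impedances,
    geometric_factors,
    sensitivity_matrix,
)
from .geometry import TriMesh
from .noise import ErrorModel

__all__ = [
    "InversionOptions",
    "InversionResult",
    "rms_error",
    "invert_frequency",
    "invert_band",
    "average_inversions",
]

#: analysis band of the instrument data actually inverted (Hz)
DEFAULT_BAND = (0.79, 1000.0)


@dataclass(frozen=True)
class InversionOptions:
    max_iterations: int = 30
    rms_target: tuple[float, float] = (0.9, 1.1)
    lambda_cooling: float = 0.5
    min_lambda_factor: float = 1e-8
    line_search_steps: int = 6
    divergence_tolerance: float = 1.5  # RMS growth factor treated as divergence


@dataclass
class InversionResult:
    field: ComplexField
    rms: float
    rms_magnitude: float
    rms_phase: float
    iterations: int
    lambda_magnitude: float
    lambda_phase: float
    converged: bool
    log: list[dict] = dc_field(default_factory=list)


def rms_error(
    observed: ComplexDataset, predicted: ComplexDataset, error_model: ErrorModel
) -> float:
    """Error-weighted RMS pooling magnitude and phase residuals.

    Magnitude residuals are normalized by a|Z|+b (evaluated on the observed
    magnitudes), phase residuals by the constant phase error c; the two pools
    are concatenated before taking the root mean square.  Equals 0 for a
    perfect fit and 1 when every residual matches its error estimate.
    """
    r_mag, r_phi = _residuals(observed, predicted, error_model)
    r = np.concatenate([r_mag.ravel(), r_phi.ravel()])
    return float(np.sqrt(np.mean(r**2)))


def _residuals(observed: ComplexDataset, predicted: ComplexDataset, em: ErrorModel):
    if observed.z.shape != predicted.z.shape:
        raise ValueError("observed and predicted datasets differ in shape")
    sd_mag = em.magnitude_std(observed.magnitude)
    if np.any(sd_mag <= 0):
        raise ValueError("zero magnitude error estimate")
    r_mag = (observed.magnitude - predicted.magnitude) / sd_mag
    r_phi = (observed.phase_mrad - predicted.phase_mrad) / em.c
    return r_mag, r_phi


def _weighted_rms(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residuals**2)))


def invert_frequency(
    dataset: ComplexDataset,
    mesh: TriMesh,
    error_model: ErrorModel,
    options: InversionOptions | None = None,
    starting_resistivity: float | None = None,
) -> InversionResult:
    """Invert a single-frequency dataset into a complex resistivity field."""
    if len(dataset.frequencies) != 1:
        raise ValueError("invert_frequency expects a single-frequency dataset")
    opts = options or InversionOptions()
    scheme = dataset.scheme
    op = FemOperator(mesh)
    k = dataset.k if dataset.k is not None else geometric_factors(mesh, scheme)
    z_obs = dataset.magnitude[:, 0]
    d_obs = np.log(z_obs)
    # weights for the log-magnitude misfit: sigma_ln|Z| ~ (a|Z|+b)/|Z|
    wd = z_obs / error_model.magnitude_std(z_obs)
    wm = first_order_smoothness(mesh)
    wmtwm = (wm.T @ wm).toarray()

    if starting_resistivity is None:
        # median apparent resistivity: robust to near-null configurations
        starting_resistivity = float(np.median(np.abs(k) * z_obs))
    m = np.full(mesh.n_cells, np.log(starting_resistivity))

    def forward_ln(m_vec: np.ndarray) -> np.ndarray:
        z = _scheme_impedances(op, mesh, np.exp(-m_vec).astype(complex), scheme)
        return np.log(np.abs(z.real))

    def mag_rms(f_ln: np.ndarray) -> float:
        # residuals in ln|Z| scaled back to the a|Z|+b convention
        return _weighted_rms(wd * (d_obs - f_ln))

    f_ln = forward_ln(m)
    rms = mag_rms(f_ln)
    lam = None
    log: list[dict] = []
    converged = False
    it = 0
    lo, hi = opts.rms_target
    for it in range(1, opts.max_iterations + 1):
        j = sensitivity_matrix(mesh, np.exp(m), scheme, operator=op)
        if lam is None:
            jw = j * wd[:, None]
            lam0 = float(np.einsum("ij,ij->", jw, jw) / np.abs(wmtwm).sum())
            lam = lam0
        jw = j * wd[:, None]
        a = jw.T @ jw + lam * wmtwm
        # Wm annihilates constants, so no reference-model term is needed
        rhs = jw.T @ (wd * (d_obs - f_ln)) - lam * (wmtwm @ m)
        step = np.linalg.solve(a, rhs)
        # halving line search on the weighted data misfit
        alpha, best_rms, best_f = 1.0, None, None
        for _ in range(opts.line_search_steps):
            f_try = forward_ln(m + alpha * step)
            r_try = mag_rms(f_try)
            if best_rms is None or r_try < best_rms:
                best_rms, best_f, best_alpha = r_try, f_try, alpha
            if r_try < rms:
                break
            alpha *= 0.5
        if best_rms > rms * opts.divergence_tolerance:
            raise RuntimeError(f"inversion diverged at iteration {it} (RMS {best_rms:.2f})")
        improved = best_rms < rms - 1e-4
        if improved:
            m = m + best_alpha * step
            f_ln, rms = best_f, best_rms
        log.append({"iteration": it, "lambda": lam, "rms_magnitude": rms})
        if rms <= hi:
            converged = True
            break
        if not improved:
            if lam <= lam0 * opts.min_lambda_factor:
                break
            lam *= opts.lambda_cooling

    rho = np.exp(m)
    # phase stage: Gauss-Newton on the cell phases about the converged
    # magnitude model.  The sensitivity of apparent phase to cell phase equals
    # the (real) log-log magnitude Jacobian to first order, but predictions
    # use the full complex forward solve — a one-shot linearized step leaves a
    # quadratic misfit comparable to a 0.5 mrad phase error, which would drag
    # the discrepancy search into over-fitting.
    j = sensitivity_matrix(mesh, rho, scheme, operator=op)
    phi_obs = dataset.phase_mrad[:, 0]
    wphi = 1.0 / error_model.c
    jw = j * wphi
    b = jw.T @ jw
    mrad = 1e-3

    def phase_forward(phi_cell: np.ndarray) -> np.ndarray:
        sigma = np.exp(-m - 1j * mrad * phi_cell)
        z = _scheme_impedances(op, mesh, sigma, scheme)
        return np.angle(z) / mrad

    def phase_converge(lam_phi: float, phi0: np.ndarray, n_inner: int = 3):
        phi = phi0
        pred = phase_forward(phi)
        for _ in range(n_inner):
            rhs = jw.T @ (wphi * (phi_obs - pred)) - lam_phi * (wmtwm @ phi)
            delta = np.linalg.solve(b + lam_phi * wmtwm, rhs)
            if not np.any(np.abs(delta) > 1e-9):
                break
            phi = phi + delta
            pred = phase_forward(phi)
        return phi, _weighted_rms(wphi * (phi_obs - pred))

    # discrepancy principle: the largest lambda whose converged phase model
    # fits the data at RMS <= the band's upper edge (approached from above,
    # i.e. the smoothest admissible phase image)
    lam_phi = float(np.trace(b) / np.abs(wmtwm).sum())
    phi0 = np.zeros(mesh.n_cells)
    phi, r_phi = phase_converge(lam_phi, phi0)
    if r_phi > hi:
        lam_out = lam_phi
        lam_in = None
        for _ in range(40):
            lam_phi *= opts.lambda_cooling
            phi, r_phi = phase_converge(lam_phi, phi)
            if r_phi <= hi:
                lam_in = lam_phi
                break
            lam_out = lam_phi
        if lam_in is None:
            lam_in = lam_phi  # bottomed out; keep best effort
    else:
        # heuristic start already in band: warm up to find the admissible edge
        lam_in, lam_out = lam_phi, lam_phi
        for _ in range(12):
            lam_out *= 4.0
            phi_try, r_try = phase_converge(lam_out, phi)
            if r_try > hi:
                break
            lam_in, phi, r_phi = lam_out, phi_try, r_try
    # tighten the bracket toward the band edge
    for _ in range(12):
        if lam_out / lam_in < 1.3 or lo <= r_phi <= hi and r_phi >= 0.5 * (lo + hi):
            break
        lam_mid = float(np.sqrt(lam_in * lam_out))
        phi_mid, r_mid = phase_converge(lam_mid, phi)
        if r_mid <= hi:
            lam_in, phi, r_phi = lam_mid, phi_mid, r_mid
        else:
            lam_out = lam_mid
    lam_phi = lam_in

    field = ComplexField.from_resistivity(dataset.frequencies[0], rho, phi)
    pred = ComplexDataset(
        scheme,
        dataset.frequencies,
        (np.exp(f_ln) * np.exp(1j * mrad * phase_forward(phi)))[:, None],
        dataset.k,
    )
    total = rms_error(dataset, pred, error_model)
    result = InversionResult(
        field=field,
        rms=total,
        rms_magnitude=rms,
        rms_phase=r_phi,
        iterations=it,
        lambda_magnitude=lam if lam is not None else np.nan,
        lambda_phase=lam_phi,
        converged=converged and r_phi <= hi + 0.1,
        log=log,
    )
    return result


def invert_band(
    dataset: ComplexDataset,
    mesh: TriMesh,
    error_model: ErrorModel,
    f_min: float = DEFAULT_BAND[0],
    f_max: float = DEFAULT_BAND[1],
    options: InversionOptions | None = None,
) -> list[InversionResult]:
    """Independent per-frequency inversions of the in-band frequencies.

    Frequencies outside [f_min, f_max] (phase accuracy of the instrument
    degrades above 1 kHz) are skipped.
    """
    in_band = [f for f in dataset.frequencies if f_min <= f <= f_max]
    if not in_band:
        raise ValueError(f"no dataset frequencies inside [{f_min}, {f_max}] Hz")
    return [
        invert_frequency(dataset.at_frequency(f), mesh, error_model, options) for f in in_band
    ]


def average_inversions(fields: Sequence[ComplexField]) -> ComplexField:
    """Cell-wise average over noise realizations: mean log-magnitude and mean
    phase (mitigates outliers of individual noise draws)."""
    if not fields:
        raise ValueError("no fields to average")
    n = fields[0].sigma.shape
    if any(f.sigma.shape != n for f in fields):
        raise ValueError("fields live on different meshes")
    log_mag = np.mean([np.log(f.magnitude) for f in fields], axis=0)
    phase = np.mean([f.phase_mrad for f in fields], axis=0)
    return ComplexField.from_resistivity(fields[0].frequency, np.exp(log_mag), phase)
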