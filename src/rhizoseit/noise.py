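"""Measurement error models, synthetic noise ensembles and data corrections.

Impedance magnitude errors follow the linear model d|Z*| = a|Z*| + b (relative
part a, absolute part b in Ohm); phase errors are a constant c per frequency
(mrad).  The same model generates Gaussian noise for synthetic ensembles and
weights the inversion misfit, so "error estimates matching the assumed noise"
is true by construction in synthetic experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import MRAD, ComplexDataset

__all__ = [
    "ErrorModel",
    "contaminate",
    "estimate_phase_error",
    "correct_with_water_reference",
]

#: smallest admissible phase error (mrad); avoids zero data weights when all
#: phases at a frequency coincide
PHASE_ERROR_FLOOR_MRAD = 0.1


@dataclass(frozen=True)
class ErrorModel:
    """Linear magnitude error a|Z|+b and constant phase error c (mrad)."""

    a: float = 0.02
    b: float = 0.01
    c: float = 0.5

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("require a >= 0, b > 0, c > 0")

    def magnitude_std(self, magnitude: np.ndarray) -> np.ndarray:
        """Standard deviation of |Z*| in Ohm."""
        return self.a * np.asarray(magnitude, float) + self.b

    def phase_std_mrad(self, magnitude: np.ndarray | None = None) -> float:
        return self.c


def contaminate(
    dataset: ComplexDataset,
    a: float,
    b: float,
    c: float,
    seed: int | np.random.Generator,
    max_retries: int = 100,
) -> ComplexDataset:
    """Perturb a dataset with independent zero-mean Gaussian noise.

    Magnitudes get std a|Z|+b, phases std c (mrad).  Draws that would make a
    magnitude non-positive are redrawn (bounded retries).  Reproducible for a
    fixed integer seed.  a = b = c = 0 returns an identical copy.
    """
    if a == 0 and b == 0 and c == 0:
        return dataset.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mag = dataset.magnitude.copy()
    sd = a * mag + b
    noisy = mag + rng.normal(0.0, 1.0, mag.shape) * sd
    for _ in range(max_retries):
        bad = noisy <= 0
        if not bad.any():
            break
        noisy[bad] = mag[bad] + rng.normal(0.0, 1.0, int(bad.sum())) * sd[bad]
    else:
        raise RuntimeError("could not draw positive magnitudes within retry budget")
    phase = dataset.phase_mrad + rng.normal(0.0, c, mag.shape)
    z = noisy * np.exp(1j * MRAD * phase)
    return ComplexDataset(dataset.scheme, dataset.frequencies, z, dataset.k)


def estimate_phase_error(dataset: ComplexDataset, frequency: float) -> float:
    """Data-driven constant phase error: half the spread of the phases.

    Returns c = std(phase at the frequency) / 2 in mrad, population
    convention, floored at :data:`PHASE_ERROR_FLOOR_MRAD`.
    """
    sub = dataset.at_frequency(frequency)
    phases = sub.phase_mrad[:, 0]
    if len(phases) < 2:
        raise ValueError("need at least two measurements to estimate a phase error")
    c = float(np.std(phases)) / 2.0
    return max(c, PHASE_ERROR_FLOOR_MRAD)


def correct_with_water_reference(
    dataset: ComplexDataset,
    measured_water: ComplexDataset,
    modelled_homogeneous: ComplexDataset,
) -> ComplexDataset:
    """Water-reference correction for measured data.

    Removes setup effects that a 2D model cannot represent (3D current flow,
    instrument polarization): each magnitude is multiplied by the ratio of the
    modelled homogeneous |Z| to the measured water-only |Z| for the same
    configuration and frequency, and the measured water phase is subtracted.
    Quadrupole/frequency entries whose reference is non-finite are dropped.
    """
    for other in (measured_water, modelled_homogeneous):
        if len(other.scheme) != len(dataset.scheme) or not np.array_equal(
            other.scheme.abmn, dataset.scheme.abmn
        ):
            raise ValueError("datasets must share one measurement scheme")
        if not np.allclose(other.frequencies, dataset.frequencies):
            raise ValueError("datasets must share the frequency list")
    factor = modelled_homogeneous.magnitude / measured_water.magnitude
    mag = dataset.magnitude * factor
    phase = dataset.phase_mrad - measured_water.phase_mrad
    ok = np.isfinite(mag).all(axis=1) & np.isfinite(phase).all(axis=1) & (mag > 0).all(axis=1)
    z = mag * np.exp(1j * MRAD * phase)
    if ok.all():
        return ComplexDataset(dataset.scheme, dataset.frequencies, z, dataset.k)
    from .forward import MeasurementScheme

    kept = np.nonzero(ok)[0]
    scheme = MeasurementScheme([dataset.scheme.quadrupoles[i] for i in kept])
    k = None if dataset.k is None else dataset.k[kept]
    return ComplexDataset(scheme, dataset.frequencies, z[kept], k)
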