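"""Root-zone integration of polarization images and root-trait estimation.

The link from electrical images to root traits: the volume-weighted mean total
chargeability of the root zone,

    m_bar = sum_k V_k m_tot,k / sum_k V_k,

integrated over the zone volume, m_rz = V_rz m_bar (reported in cm^3), scales
with the amount of root matter.  Calibrated power laws convert m_rz to total
root surface area A_surf (cm^2) and dry biomass M_bio (g):

    A_surf ~ 221 x m_rz^0.93,      M_bio ~ 0.169 x m_rz^0.94.

The analogous volume-weighted mean of the per-cell mean relaxation time,
tau_bar, is the candidate predictor of the (squared) average root diameter.
Reconstruction quality of tomograms is scored with the Pearson correlation
coefficient on cell values and SSIM on rasterized images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import linregress
from shapely.geometry import Point, Polygon
from skimage.metrics import structural_similarity

from .geometry import TriMesh
from .spectral import BACKGROUND_CHARGEABILITY

__all__ = [
    "RootZoneMask",
    "RootTraits",
    "RootZoneSummary",
    "ImageMetrics",
    "PowerLawCalibration",
    "DEFAULT_CALIBRATION",
    "average_chargeability",
    "integrated_chargeability",
    "averaged_relaxation_time",
    "summarize_root_zone",
    "predict_traits",
    "fit_powerlaw",
    "image_metrics",
    "rasterize",
    "mask_background",
]

M3_TO_CM3 = 1e6


@dataclass
class RootZoneMask:
    """Cells belonging to the root zone of one plant.

    Built from an explicit cell-id list or from a polygon in domain
    coordinates (cells assigned by centroid inclusion, matching how root
    outlines traced on tank photographs are transferred to the grid).
    """

    cells: np.ndarray  # int indices into the mesh cells
    mesh: TriMesh

    def __post_init__(self) -> None:
        self.cells = np.unique(np.asarray(self.cells, np.int64))
        if self.cells.size and (self.cells.min() < 0 or self.cells.max() >= self.mesh.n_cells):
            raise ValueError("mask references cells outside the mesh")

    @classmethod
    def from_polygon(cls, polygon: Polygon | Sequence, mesh: TriMesh) -> "RootZoneMask":
        poly = polygon if isinstance(polygon, Polygon) else Polygon(polygon)
        cent = mesh.cell_centroids
        members = [i for i, c in enumerate(cent) if poly.contains(Point(c))]
        return cls(np.array(members, np.int64), mesh)

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def volume(self) -> float:
        """Root-zone volume V_rz in m^3."""
        return float(self.mesh.cell_volumes[self.cells].sum())

    def depth_sections(self, band_height: float = 0.10, top: float | None = None):
        """Partition into horizontal bands of ``band_height`` metres measured
        downward from ``top`` (default: water level = domain top); returns a
        list of (depth_range_m, RootZoneMask) for non-empty bands."""
        if top is None:
            top = float(self.mesh.nodes[:, 1].max())
        cy = self.mesh.cell_centroids[self.cells, 1]
        depth = top - cy
        out = []
        d0 = 0.0
        while d0 < depth.max():
            sel = (depth >= d0) & (depth < d0 + band_height)
            if sel.any():
                out.append(((d0, d0 + band_height), RootZoneMask(self.cells[sel], self.mesh)))
            d0 += band_height
        return out


@dataclass(frozen=True)
class RootTraits:
    """Validation traits of one plant (from scanning/weighing)."""

    biomass_g: float
    surface_area_cm2: float
    mean_diameter_mm: float
    species: str = ""
    das: int | None = None  # plant age, days after sowing

    def __post_init__(self) -> None:
        if min(self.biomass_g, self.surface_area_cm2, self.mean_diameter_mm) < 0:
            raise ValueError("root traits must be non-negative")


@dataclass(frozen=True)
class RootZoneSummary:
    """Integral electrical parameters of a root zone."""

    mean_chargeability: float      # volume-weighted m_bar, dimensionless
    integrated_chargeability: float  # m_rz in cm^3
    mean_relaxation_time: float    # tau_bar in s (NaN if no polarizable cells)
    volume_cm3: float
    n_cells: int


@dataclass(frozen=True)
class ImageMetrics:
    pcc: float
    ssim: float


@dataclass(frozen=True)
class PowerLawCalibration:
    """trait = coefficient * m_rz^exponent; diagnostics in log10 space."""

    coefficient: float
    exponent: float
    r_squared: float = float("nan")
    pcc: float = float("nan")

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")

    def __call__(self, m_rz) -> np.ndarray:
        m_rz = np.asarray(m_rz, float)
        if np.any(m_rz < 0):
            raise ValueError("m_rz must be non-negative")
        return self.coefficient * m_rz**self.exponent


#: calibration constants of the rhizotron study (m_rz in cm^3)
DEFAULT_CALIBRATION = {
    "surface_area_cm2": PowerLawCalibration(221.0, 0.93),
    "biomass_g": PowerLawCalibration(0.169, 0.94),
}


def average_chargeability(m_tot: np.ndarray, mask: RootZoneMask) -> float:
    """Volume-weighted mean total chargeability m_bar over the root zone."""
    if mask.n == 0:
        raise ValueError("empty root-zone mask")
    v = mask.mesh.cell_volumes[mask.cells]
    return float(v @ np.asarray(m_tot, float)[mask.cells] / v.sum())


def integrated_chargeability(mean_chargeability: float, volume_m3: float) -> float:
    """m_rz = V_rz * m_bar, reported in cm^3."""
    if volume_m3 <= 0:
        raise ValueError("root-zone volume must be positive")
    return float(mean_chargeability * volume_m3 * M3_TO_CM3)


def averaged_relaxation_time(tau_mean: np.ndarray, mask: RootZoneMask) -> float:
    """Volume-weighted arithmetic mean of the per-cell mean relaxation time,
    skipping cells with no fitted relaxation time (NaN)."""
    if mask.n == 0:
        raise ValueError("empty root-zone mask")
    tau = np.asarray(tau_mean, float)[mask.cells]
    v = mask.mesh.cell_volumes[mask.cells]
    ok = np.isfinite(tau)
    if not ok.any():
        raise ValueError("no cells with a defined relaxation time in the mask")
    return float(v[ok] @ tau[ok] / v[ok].sum())


def summarize_root_zone(
    m_tot: np.ndarray, tau_mean: np.ndarray, mask: RootZoneMask
) -> RootZoneSummary:
    m_bar = average_chargeability(m_tot, mask)
    v = mask.volume
    try:
        tau_bar = averaged_relaxation_time(tau_mean, mask)
    except ValueError:
        tau_bar = float("nan")
    return RootZoneSummary(
        mean_chargeability=m_bar,
        integrated_chargeability=integrated_chargeability(m_bar, v),
        mean_relaxation_time=tau_bar,
        volume_cm3=v * M3_TO_CM3,
        n_cells=mask.n,
    )


def predict_traits(
    m_rz: float, calibration: dict[str, PowerLawCalibration] | None = None
) -> dict[str, float]:
    """Predict root traits from the integrated root-zone chargeability (cm^3)."""
    if m_rz < 0:
        raise ValueError("m_rz must be non-negative")
    cal = calibration or DEFAULT_CALIBRATION
    return {name: float(law(m_rz)) for name, law in cal.items()}


def fit_powerlaw(m_rz: Sequence[float], trait: Sequence[float]) -> PowerLawCalibration:
    """Least-squares power-law calibration in log10-log10 space.

    R^2 and PCC are reported in log space, matching how the trait relations
    are plotted and fitted.
    """
    x = np.asarray(m_rz, float)
    y = np.asarray(trait, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 (m_rz, trait) pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    res = linregress(np.log10(x), np.log10(y))
    return PowerLawCalibration(
        coefficient=float(10**res.intercept),
        exponent=float(res.slope),
        r_squared=float(res.rvalue**2),
        pcc=float(res.rvalue),
    )


def rasterize(values: np.ndarray, mesh: TriMesh, resolution: float = 0.002) -> np.ndarray:
    """Nearest-cell sampling of a cell image onto a regular pixel grid
    (needed by SSIM, which is defined on rasters)."""
    values = np.asarray(values, float)
    x0, y0 = mesh.nodes.min(axis=0)
    x1, y1 = mesh.nodes.max(axis=0)
    xs = np.arange(x0 + resolution / 2, x1, resolution)
    ys = np.arange(y0 + resolution / 2, y1, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    tree = cKDTree(mesh.cell_centroids)
    _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    return values[idx].reshape(len(xs), len(ys))


def image_metrics(
    true_values: np.ndarray,
    reconstructed: np.ndarray,
    mesh: TriMesh,
    resolution: float = 0.002,
) -> ImageMetrics:
    """PCC on cell values and SSIM on 2 mm rasters of true vs reconstruction.

    SSIM uses the standard constants and window of scikit-image with the joint
    dynamic range of both images.  A constant image has no defined PCC and is
    rejected.
    """
    t = np.asarray(true_values, float)
    r = np.asarray(reconstructed, float)
    if t.shape != r.shape or t.shape[0] != mesh.n_cells:
        raise ValueError("images must be per-cell values on the same mesh")
    if np.std(t) == 0 or np.std(r) == 0:
        raise ValueError("PCC undefined for a constant image")
    pcc = float(np.corrcoef(t, r)[0, 1])
    rt = rasterize(t, mesh, resolution)
    rr = rasterize(r, mesh, resolution)
    lo = min(rt.min(), rr.min())
    hi = max(rt.max(), rr.max())
    ssim = float(structural_similarity(rt, rr, data_range=hi - lo))
    return ImageMetrics(pcc=pcc, ssim=ssim)


def mask_background(
    m_tot: np.ndarray, threshold: float = BACKGROUND_CHARGEABILITY
) -> np.ndarray:
    """Boolean background flags: cells with m_tot below the threshold carry no
    resolvable polarization and are excluded from root-zone statistics."""
    return np.asarray(m_tot, float) < threshold
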