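"""Optimized measurement-scheme design by model-resolution maximisation.

A measurement scheme for the closed rhizotron is assembled greedily: starting
from a sparse skeleton, candidate quadrupoles are ranked by the marginal
increase of the spatially weighted sum of the model-resolution-matrix diagonal

    R = (J^T Wd^2 J + lambda Wm^T Wm)^{-1} J^T Wd^2 J,

where J is the log-log sensitivity matrix of the already-selected
configurations on a homogeneous model, Wd the data weights from the error
model, and Wm a first-order smoothness operator.  The weighting focuses
resolution on the expected rooting zone; the number of distinct current
injection dipoles is capped (the instrument measures all potentials per
injection, so dipoles dominate acquisition time).  Only the real part of the
sensitivity is used: expected polarization is weak, so real and imaginary
sensitivity patterns are nearly proportional.

Rank-one updates make the per-candidate gain exact and cheap; candidates are
pre-sorted lexicographically by (A, B, M, N) so ties break deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .forward import FemOperator, MeasurementScheme, Quadrupole, sensitivity_matrix
from .geometry import RhizotronGeometry, TriMesh
from .noise import ErrorModel

__all__ = [
    "DipolePoolRules",
    "SchemeDesignState",
    "enumerate_candidates",
    "first_order_smoothness",
    "resolution_diagonal",
    "roi_cell_weights",
    "make_design_state",
    "optimize_scheme",
    "exclude_electrodes",
]


def first_order_smoothness(mesh: TriMesh) -> sp.csr_matrix:
    """First-order (edge-difference) roughness operator Wm, one row per
    interior cell edge with entries +1/-1."""
    pairs = mesh.cell_neighbors()
    n_e = len(pairs)
    rows = np.repeat(np.arange(n_e), 2)
    cols = pairs.ravel()
    vals = np.tile([1.0, -1.0], n_e)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_e, mesh.n_cells))


@dataclass(frozen=True)
class DipolePoolRules:
    """Rules restricting the candidate quadrupole pool.

    ``allowed_dipoles``: explicit set of permitted injection pairs (unordered);
    ``skips``: permitted electrode-index separations |A-B| and |M-N| (a cheap
    proxy for dipole length on a sequentially numbered layout); ``None`` means
    unrestricted.
    """

    allowed_dipoles: frozenset | None = None
    skips: tuple[int, ...] | None = None

    def dipole_ok(self, a: int, b: int) -> bool:
        if self.allowed_dipoles is not None and frozenset((a, b)) not in self.allowed_dipoles:
            return False
        if self.skips is not None and abs(a - b) not in self.skips:
            return False
        return True

    def mn_ok(self, m: int, n: int) -> bool:
        return self.skips is None or abs(m - n) in self.skips


def enumerate_candidates(
    electrodes: Sequence[int] | int,
    rules: DipolePoolRules | None = None,
) -> list[Quadrupole]:
    """All valid, reciprocal-unique quadrupoles obeying the pool rules.

    Electrodes may be given as a count or an explicit index list.  Each
    candidate uses four distinct electrodes; of a reciprocal pair (AB->MN vs
    MN->AB) only the lexicographically smaller is kept unless the rules forbid
    its injection dipole.  Ordering is lexicographic in (A, B, M, N), which
    downstream greedy selection relies on for deterministic tie-breaking.
    """
    idx = list(range(electrodes)) if isinstance(electrodes, int) else sorted(electrodes)
    if len(idx) < 4:
        raise ValueError("need at least four electrodes")
    rules = rules or DipolePoolRules()
    out: list[Quadrupole] = []
    for a, b in combinations(idx, 2):
        if not rules.dipole_ok(a, b):
            continue
        rest = [e for e in idx if e not in (a, b)]
        for m, n in combinations(rest, 2):
            if not rules.mn_ok(m, n):
                continue
            # reciprocal uniqueness: keep AB->MN only if it is the canonical
            # representative, or if the reciprocal's injection is not allowed
            if (m, n) < (a, b) and rules.dipole_ok(m, n) and rules.mn_ok(a, b):
                continue
            out.append(Quadrupole(a, b, m, n))
    return sorted(out)


def resolution_diagonal(
    j: np.ndarray,
    data_weights: np.ndarray,
    smoothness: sp.spmatrix | np.ndarray,
    lam: float,
) -> np.ndarray:
    """Diagonal of the model resolution matrix for a linearized inversion."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    w = np.asarray(data_weights, float)
    jw = j * w[:, None]
    b = jw.T @ jw
    wm = smoothness.toarray() if sp.issparse(smoothness) else np.asarray(smoothness)
    a = b + lam * (wm.T @ wm)
    return np.diag(np.linalg.solve(a, b)).copy()


def roi_cell_weights(
    mesh: TriMesh, roi: tuple[float, float, float, float], outside: float = 0.1
) -> np.ndarray:
    """Per-cell spatial weights: 1 inside the rooting-zone ROI, ``outside``
    elsewhere (some weight outside keeps background resolution for the
    inversion's benefit)."""
    c = mesh.cell_centroids
    x0, y0, x1, y1 = roi
    inside = (c[:, 0] >= x0) & (c[:, 0] <= x1) & (c[:, 1] >= y0) & (c[:, 1] <= y1)
    return np.where(inside, 1.0, outside)


@dataclass
class SchemeDesignState:
    """Bookkeeping for the greedy scheme construction (see module docstring)."""

    mesh: TriMesh
    candidates: list[Quadrupole]
    j_pool: np.ndarray            # (n_candidates, n_cells)
    data_weights: np.ndarray      # (n_candidates,) weights for ln|Z| data
    smoothness: sp.csr_matrix
    lam: float
    cell_weights: np.ndarray
    selected: list[int] = field(default_factory=list)
    objective_log: list[float] = field(default_factory=list)

    @property
    def scheme(self) -> MeasurementScheme:
        return MeasurementScheme([self.candidates[i] for i in self.selected])

    def regularizer(self) -> np.ndarray:
        wm = self.smoothness
        return self.lam * (wm.T @ wm).toarray()

    def normal_matrix(self) -> np.ndarray:
        jw = self.j_pool[self.selected] * self.data_weights[self.selected, None]
        return jw.T @ jw

    def objective(self) -> float:
        """Spatially weighted sum of the resolution diagonal of the current
        selection."""
        if not self.selected:
            return 0.0
        b = self.normal_matrix()
        diag = np.diag(np.linalg.solve(b + self.regularizer(), b))
        return float(self.cell_weights @ diag)


def make_design_state(
    mesh: TriMesh,
    geometry: RhizotronGeometry,
    candidates: Iterable[Quadrupole],
    background_resistivity: float = 95.15,
    error_model: ErrorModel | None = None,
    lam: float | None = None,
    roi_outside_weight: float = 0.1,
    lam_reference_rows: int = 800,
    min_impedance_factor: float = 0.05,
    max_sensitivity_l1: float = 5.0,
) -> SchemeDesignState:
    """Assemble the design state: candidate Jacobian on the homogeneous
    background, canonical M,N orientation (positive homogeneous impedance),
    error-model data weights and the smoothness regularizer.

    ``lam`` defaults to the inversion's trace heuristic
    trace(J^T Wd^2 J)/trace(Wm^T Wm) evaluated for a scheme of
    ``lam_reference_rows`` average-strength rows (the intended final scheme
    size), so the resolution computation is regularized like the inversion
    that will use the scheme — not like the whole candidate pool.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("empty candidate pool")
    scheme = MeasurementScheme(cands)
    op = FemOperator(mesh)
    rho = np.full(mesh.n_cells, background_resistivity)
    from .forward import _scheme_impedances

    z_hom = _scheme_impedances(op, mesh, (1.0 / rho).astype(complex), scheme).real
    # drop near-null configurations: tiny |Z| means a huge geometric factor,
    # absolute-error-dominated data and runaway normalized sensitivities —
    # the instrument cannot use them either
    keep = np.abs(z_hom) >= min_impedance_factor * np.median(np.abs(z_hom))
    cands = [q for q, k_ in zip(cands, keep) if k_]
    if not cands:
        raise ValueError("every candidate is near-null on the homogeneous model")
    z_hom = z_hom[keep]
    # canonical orientation: flip M,N where the homogeneous impedance is
    # negative, so K > 0 and apparent-resistivity phases stay near zero
    flipped = []
    for q, z in zip(cands, z_hom):
        flipped.append(Quadrupole(q.a, q.b, q.n, q.m) if z < 0 else q)
    cands = flipped
    z_hom = np.abs(z_hom)
    j_pool = sensitivity_matrix(mesh, rho, MeasurementScheme(cands), operator=op)
    # phase-linearity guard: a configuration's apparent phase is (to first
    # order) its sensitivity row dotted with the cell phases, so rows with a
    # large L1 norm amplify a ~-25 mrad anomaly out of the small-phase regime
    # (and out of what the instrument measures reliably)
    if max_sensitivity_l1 is not None:
        keep = np.abs(j_pool).sum(axis=1) <= max_sensitivity_l1
        if not keep.any():
            raise ValueError("sensitivity cap removed every candidate")
        cands = [q for q, k_ in zip(cands, keep) if k_]
        j_pool = j_pool[keep]
        z_hom = z_hom[keep]
    em = error_model or ErrorModel(a=0.01, b=0.001, c=0.5)
    # weights for log-magnitude data: sigma_ln|Z| = a + b/|Z|
    data_weights = 1.0 / (em.a + em.b / z_hom)
    wm = first_order_smoothness(mesh)
    if lam is None:
        # trace heuristic for a scheme of the intended size, scaled down to
        # the level a discrepancy-converged inversion cools to (~1e-2 of the
        # warm start); at that level the resolution diagonal stays in [0, 1]
        # and greedy gains remain positive up to the target scheme size
        jw = j_pool * data_weights[:, None]
        mean_row_sq = float(np.einsum("ij,ij->", jw, jw)) / len(cands)
        lam = 0.01 * mean_row_sq * lam_reference_rows / float(wm.multiply(wm).sum())
    return SchemeDesignState(
        mesh=mesh,
        candidates=cands,
        j_pool=j_pool,
        data_weights=data_weights,
        smoothness=wm,
        lam=lam,
        cell_weights=roi_cell_weights(mesh, geometry.roi, roi_outside_weight),
    )


def _marginal_gains(
    a_inv_jt: np.ndarray, b: np.ndarray, j_cand: np.ndarray, w: np.ndarray, wroi: np.ndarray
) -> np.ndarray:
    """Exact objective gain of appending each candidate row, via the
    Sherman-Morrison rank-one update of A = B + lambda Wm'Wm."""
    u = a_inv_jt  # (n_cells, m): A^{-1} j per candidate
    jt = j_cand.T
    d1 = np.einsum("cm,cm->m", jt, u)
    denom = 1.0 + w**2 * d1
    uw = u * wroi[:, None]
    t1 = np.einsum("cm,cm->m", uw, jt)
    t2 = np.einsum("cm,cm->m", uw, b @ u)
    return w**2 * t1 - (w**2 / denom) * t2 - (w**4 * d1 / denom) * t1


def optimize_scheme(
    state: SchemeDesignState,
    target_size: int = 800,
    dipole_budget: int = 40,
    batch_size: int = 10,
    starting_scheme: Sequence[int] | None = None,
) -> MeasurementScheme:
    """Greedy construction of the optimized measurement scheme.

    Per iteration the exact marginal gain of every eligible candidate is
    computed by a rank-one resolution update and the best ``batch_size`` are
    appended; once ``dipole_budget`` distinct injection dipoles are in use,
    candidates introducing new dipoles become ineligible.  The weighted
    objective is non-decreasing by construction.  ``starting_scheme`` gives
    indices into the candidate pool for the sparse skeleton (default: every
    ``len(pool)//8``-th candidate, 8 configurations).
    """
    n_cand = len(state.candidates)
    if target_size < 1 or dipole_budget < 1:
        raise ValueError("target_size and dipole_budget must be positive")
    dipoles = [q.dipole for q in state.candidates]
    if len({d for d in dipoles}) < 1:
        raise ValueError("candidate pool has no injection dipoles")
    if starting_scheme is None:
        starting_scheme = list(range(0, n_cand, max(1, n_cand // 8)))[:8]
    selected: list[int] = []
    used_dipoles: set[frozenset] = set()
    for i in starting_scheme:
        if len(used_dipoles | {dipoles[i]}) <= dipole_budget and len(selected) < target_size:
            selected.append(i)
            used_dipoles.add(dipoles[i])
    if not selected:
        raise ValueError("infeasible: starting scheme exceeds the dipole budget")
    state.selected = selected
    state.objective_log = [state.objective()]

    reg = state.regularizer()
    w_all = state.data_weights
    j_all = state.j_pool
    in_scheme = np.zeros(n_cand, bool)
    in_scheme[selected] = True
    while len(selected) < target_size:
        b = state.normal_matrix()
        a = b + reg
        eligible = np.nonzero(~in_scheme)[0]
        if len(used_dipoles) >= dipole_budget:
            eligible = np.array(
                [i for i in eligible if dipoles[i] in used_dipoles], dtype=np.int64
            )
        if len(eligible) == 0:
            break
        j_cand = j_all[eligible]
        u = np.linalg.solve(a, j_cand.T)
        gains = _marginal_gains(u, b, j_cand, w_all[eligible], state.cell_weights)
        take = min(batch_size, target_size - len(selected))
        # stable sort on -gain: ties resolve to the lexicographically first
        # candidate because the pool is lexicographically ordered
        order = np.argsort(-gains, kind="stable")
        batch = []
        tentative_dipoles = set(used_dipoles)
        for pos in order:
            if len(batch) >= take:
                break
            if gains[pos] <= 0:
                break
            i = int(eligible[pos])
            if dipoles[i] not in tentative_dipoles and len(tentative_dipoles) >= dipole_budget:
                continue
            batch.append(i)
            tentative_dipoles.add(dipoles[i])
        if not batch:
            break
        prev_obj = state.objective_log[-1]
        state.selected = selected + batch
        new_obj = state.objective()
        if new_obj < prev_obj and len(batch) > 1:
            # batch interaction overshoot: the single best candidate's
            # rank-one gain is exact and positive, so fall back to it
            batch = batch[:1]
            state.selected = selected + batch
            new_obj = state.objective()
        if new_obj < prev_obj:
            state.selected = selected
            break
        selected.extend(batch)
        for i in batch:
            used_dipoles.add(dipoles[i])
            in_scheme[i] = True
        state.objective_log.append(new_obj)
    return state.scheme


def exclude_electrodes(scheme: MeasurementScheme, excluded: Iterable[int]) -> MeasurementScheme:
    """Reduced scheme: drop every quadrupole touching an excluded electrode."""
    excluded = set(excluded)
    kept = [q for q in scheme if not ({q.a, q.b, q.m, q.n} & excluded)]
    if not kept and len(scheme) > 0:
        raise ValueError("exclusion removed every configuration")
    return MeasurementScheme(kept)
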