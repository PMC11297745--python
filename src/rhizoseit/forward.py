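"""Complex-conductivity finite-element forward modelling.

Physics: in the thin water-filled tank the complex potential u* of an injected
AC current obeys the 2D conductance equation

    div( sigma* t grad u* ) = -I* [ delta(x_A) - delta(x_B) ]

with insulating (no-flux) outer boundaries, where sigma* = sigma' + i sigma''
is the complex conductivity (S/m), t the tank thickness, and the current I* is
normalised to 1 A so that the voltage across a potential dipole M,N equals the
transfer impedance Z* = u*(M) - u*(N).  Linear (P1) triangular elements are
used; the pure-Neumann nullspace is removed with a zero-mean potential gauge
(Lagrange multiplier), under which a unit monopole source at one electrode is
admissible — dipole fields are differences of these pole fields, so one sparse
factorisation per conductivity model serves every injection dipole.

Apparent complex resistivity follows rho_a* = K Z* with the geometric factor K
computed numerically from a homogeneous reference solve, so K carries all the
geometry of the closed tank (no half-space formula applies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import TriMesh

__all__ = [
    "ComplexField",
    "Quadrupole",
    "MeasurementScheme",
    "ForwardSolution",
    "ComplexDataset",
    "FemOperator",
    "solve_dipole",
    "simulate_scheme",
    "geometric_factors",
    "sensitivity_matrix",
]

MRAD = 1e-3  # phase unit used in data files


@dataclass
class ComplexField:
    """Per-cell complex conductivity at a single frequency.

    The same object serves as inversion unknown and phantom ground truth.
    Conversions between conductivity and resistivity representations are exact
    inverses (rho* = 1/sigma*).
    """

    frequency: float
    sigma: np.ndarray  # complex, (n_cells,)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, complex)
        if np.any(self.sigma.real <= 0):
            raise ValueError("sigma' must be positive everywhere")
        if np.any(np.abs(np.angle(1.0 / self.sigma)) >= np.pi / 2):
            raise ValueError("|phase of rho*| must be < pi/2")

    @classmethod
    def from_resistivity(
        cls, frequency: float, magnitude: np.ndarray, phase_mrad: np.ndarray | float = 0.0
    ) -> "ComplexField":
        """Build from |rho*| (Ohm m) and resistivity phase (mrad, negative =
        capacitive polarization)."""
        rho = np.asarray(magnitude, float) * np.exp(1j * MRAD * np.asarray(phase_mrad, float))
        return cls(frequency, 1.0 / rho)

    @property
    def rho(self) -> np.ndarray:
        return 1.0 / self.sigma

    @property
    def magnitude(self) -> np.ndarray:
        """|rho*| in Ohm m."""
        return np.abs(self.rho)

    @property
    def phase_mrad(self) -> np.ndarray:
        """Resistivity phase in mrad (negative for polarizable media)."""
        return np.angle(self.rho) / MRAD


@dataclass(frozen=True, order=True)
class Quadrupole:
    """Four-point configuration: current through A,B; voltage across M,N."""

    a: int
    b: int
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.a == self.b or self.m == self.n:
            raise ValueError("current and potential dipoles need distinct electrodes")
        if {self.a, self.b} & {self.m, self.n}:
            raise ValueError("current and potential electrodes must not overlap")

    @property
    def dipole(self) -> frozenset:
        return frozenset((self.a, self.b))

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.m, self.n)


class MeasurementScheme:
    """Ordered, duplicate-free list of quadrupoles."""

    def __init__(self, quadrupoles: Iterable[Quadrupole | Sequence[int]]):
        quads = []
        for q in quadrupoles:
            if not isinstance(q, Quadrupole):
                q = Quadrupole(*map(int, q))
            quads.append(q)
        if len(set(quads)) != len(quads):
            raise ValueError("duplicate quadrupoles in scheme")
        self.quadrupoles: list[Quadrupole] = quads
        self.abmn = np.array([q.as_tuple() for q in quads], np.int64).reshape(-1, 4)

    def __len__(self) -> int:
        return len(self.quadrupoles)

    def __iter__(self):
        return iter(self.quadrupoles)

    def __eq__(self, other) -> bool:
        return isinstance(other, MeasurementScheme) and self.quadrupoles == other.quadrupoles

    @property
    def injection_dipoles(self) -> set[frozenset]:
        return {q.dipole for q in self.quadrupoles}

    @property
    def electrodes(self) -> set[int]:
        return set(self.abmn.ravel().tolist())


@dataclass
class ForwardSolution:
    """Nodal complex potentials for one injection dipole at unit current."""

    dipole: tuple[int, int]
    potentials: np.ndarray  # (n_nodes,), zero-mean gauge
    electrode_nodes: dict[int, int]

    def voltage(self, m: int, n: int) -> complex:
        """Transfer impedance contribution u*(M) - u*(N) (Ohm at 1 A)."""
        return complex(
            self.potentials[self.electrode_nodes[m]] - self.potentials[self.electrode_nodes[n]]
        )


class ComplexDataset:
    """Complex impedances of a scheme over a set of frequencies.

    ``z`` has shape (n_quadrupoles, n_frequencies); ``k`` holds the geometric
    factors when attached.  Phases are exposed in mrad.
    """

    def __init__(
        self,
        scheme: MeasurementScheme,
        frequencies: Sequence[float],
        z: np.ndarray,
        k: np.ndarray | None = None,
    ):
        self.scheme = scheme
        self.frequencies = np.asarray(frequencies, float)
        if self.frequencies.ndim != 1 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        self.z = np.asarray(z, complex).reshape(len(scheme), len(self.frequencies))
        if np.any(np.abs(self.z) <= 0):
            raise ValueError("|Z*| must be positive")
        self.k = None if k is None else np.asarray(k, float).reshape(len(scheme))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_mrad(self) -> np.ndarray:
        return np.angle(self.z) / MRAD

    @property
    def apparent_resistivity(self) -> np.ndarray:
        if self.k is None:
            raise ValueError("geometric factors not attached")
        return self.k[:, None] * self.z

    def at_frequency(self, frequency: float) -> "ComplexDataset":
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        if not np.isclose(self.frequencies[i], frequency, rtol=1e-9):
            raise KeyError(f"frequency {frequency} not in dataset")
        return ComplexDataset(self.scheme, [self.frequencies[i]], self.z[:, [i]], self.k)

    def copy(self) -> "ComplexDataset":
        return ComplexDataset(
            self.scheme, self.frequencies.copy(), self.z.copy(),
            None if self.k is None else self.k.copy(),
        )


class FemOperator:
    """P1 finite-element operator on a :class:`TriMesh`.

    Precomputes per-cell basis gradients once; ``factorize`` assembles the
    complex conductance matrix for a conductivity model and returns a reusable
    sparse LU of the gauge-augmented system.
    """

    def __init__(self, mesh: TriMesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.cells]  # (n_cells, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        self.areas = 0.5 * np.abs(det)
        # gradients of the three barycentric basis functions, (n_cells, 3, 2)
        grads = np.empty((mesh.n_cells, 3, 2))
        grads[:, 1, 0] = v2[:, 1] / det
        grads[:, 1, 1] = -v2[:, 0] / det
        grads[:, 2, 0] = -v1[:, 1] / det
        grads[:, 2, 1] = v1[:, 0] / det
        grads[:, 0] = -grads[:, 1] - grads[:, 2]
        self.grads = grads
        # local stiffness without conductivity: area * grad_i . grad_j
        self.local_k = np.einsum("cie,cje,c->cij", grads, grads, self.areas)
        rows = np.repeat(mesh.cells, 3, axis=1).reshape(-1, 3, 3)
        cols = rows.transpose(0, 2, 1)
        self._rows = rows.ravel()
        self._cols = cols.ravel()
        self.n = mesh.n_nodes

    def factorize(self, sigma: np.ndarray):
        """LU of [[K, 1], [1^T, 0]] with K the conductance matrix for sigma."""
        sigma = np.asarray(sigma, complex)
        if np.any(sigma.real <= 0):
            raise ValueError("sigma' must be positive for a solvable system")
        vals = (self.local_k * (sigma * self.mesh.thickness)[:, None, None]).ravel()
        k = sp.coo_matrix((vals, (self._rows, self._cols)), shape=(self.n, self.n)).tocsr()
        ones = np.ones((self.n, 1))
        aug = sp.bmat([[k, ones], [ones.T, None]], format="csc")
        return splu(aug)

    def pole_potentials(self, lu, electrode_nodes: Mapping[int, int]) -> dict[int, np.ndarray]:
        """Zero-mean potential field of a +1 A monopole at each electrode.

        Under the zero-mean gauge the Lagrange multiplier absorbs the net
        source, and differences of pole fields are exact dipole solutions.
        """
        out = {}
        for e, node in electrode_nodes.items():
            rhs = np.zeros(self.n + 1, complex)
            rhs[node] = 1.0
            out[e] = lu.solve(rhs)[:-1]
        return out

    def cell_gradient(self, u: np.ndarray) -> np.ndarray:
        """Piecewise-constant gradient of a nodal field, (n_cells, 2)."""
        return np.einsum("cie,ci->ce", self.grads, u[self.mesh.cells])


def solve_dipole(
    mesh: TriMesh, field: ComplexField, dipole: tuple[int, int], operator: FemOperator | None = None
) -> ForwardSolution:
    """Potential field of a unit current injected through electrode pair (A, B)."""
    a, b = dipole
    for e in (a, b):
        if e not in mesh.electrode_nodes:
            raise KeyError(f"electrode {e} not on the mesh")
    op = operator or FemOperator(mesh)
    lu = op.factorize(field.sigma)
    rhs = np.zeros(op.n + 1, complex)
    rhs[mesh.electrode_nodes[a]] += 1.0
    rhs[mesh.electrode_nodes[b]] -= 1.0
    u = lu.solve(rhs)[:-1]
    return ForwardSolution((a, b), u, dict(mesh.electrode_nodes))


def _scheme_impedances(
    op: FemOperator, mesh: TriMesh, sigma: np.ndarray, scheme: MeasurementScheme
) -> np.ndarray:
    """Z* for every quadrupole of a scheme at one conductivity model."""
    elec = set(scheme.electrodes)
    missing = elec - set(mesh.electrode_nodes)
    if missing:
        raise KeyError(f"scheme references unknown electrodes {sorted(missing)}")
    lu = op.factorize(sigma)
    poles = op.pole_potentials(lu, {e: mesh.electrode_nodes[e] for e in elec})
    z = np.empty(len(scheme), complex)
    for i, q in enumerate(scheme):
        ud = poles[q.a] - poles[q.b]
        z[i] = ud[mesh.electrode_nodes[q.m]] - ud[mesh.electrode_nodes[q.n]]
    return z


def simulate_scheme(
    mesh: TriMesh,
    fields: Sequence[ComplexField],
    scheme: MeasurementScheme,
    k: np.ndarray | None = None,
) -> ComplexDataset:
    """Simulate Z* for every quadrupole at every field's frequency."""
    fields = sorted(fields, key=lambda f: f.frequency)
    freqs = [f.frequency for f in fields]
    op = FemOperator(mesh)
    z = np.column_stack([_scheme_impedances(op, mesh, f.sigma, scheme) for f in fields])
    return ComplexDataset(scheme, freqs, z, k=k)


def geometric_factors(
    mesh: TriMesh, scheme: MeasurementScheme, reference_resistivity: float = 100.0
) -> np.ndarray:
    """Numeric geometric factors K = rho_ref / Z_hom per quadrupole.

    By construction K·Z* equals the apparent complex resistivity and is exact
    (rho_a = rho_ref) on the homogeneous model; K is independent of the chosen
    reference resistivity.  Near-null configurations (|Z_hom| under 1e-12 of
    the reference) are rejected.
    """
    op = FemOperator(mesh)
    sigma = np.full(mesh.n_cells, 1.0 / reference_resistivity, complex)
    z_hom = _scheme_impedances(op, mesh, sigma, scheme).real
    floor = 1e-12 * reference_resistivity
    if np.any(np.abs(z_hom) < floor):
        bad = np.nonzero(np.abs(z_hom) < floor)[0]
        raise ValueError(f"near-null configurations (|Z_hom| ~ 0) at rows {bad.tolist()}")
    return reference_resistivity / z_hom


def sensitivity_matrix(
    mesh: TriMesh,
    resistivity: np.ndarray,
    scheme: MeasurementScheme,
    operator: FemOperator | None = None,
) -> np.ndarray:
    """Log-log Jacobian J[i, c] = d ln rho_a,i / d ln rho_c by the adjoint method.

    For P1 elements the row is sigma_c t A_c (grad u_AB . grad u_MN) / Z_i with
    u_MN the adjoint (reciprocal) dipole field; on a homogeneous model each row
    sums to 1 (apparent resistivity is degree-1 homogeneous in the cell
    resistivities).  Real-valued fields only — survey design and the magnitude
    inversion both linearize about a real model.
    """
    resistivity = np.asarray(resistivity, float)
    sigma = 1.0 / resistivity
    op = operator or FemOperator(mesh)
    elec = set(scheme.electrodes)
    lu = op.factorize(sigma.astype(complex))
    poles = op.pole_potentials(lu, {e: mesh.electrode_nodes[e] for e in elec})
    grads = {e: op.cell_gradient(u.real) for e, u in poles.items()}
    pots = {e: u.real for e, u in poles.items()}
    scale = sigma * op.areas * mesh.thickness
    j = np.empty((len(scheme), mesh.n_cells))
    for i, q in enumerate(scheme):
        g_ab = grads[q.a] - grads[q.b]
        g_mn = grads[q.m] - grads[q.n]
        z = (
            pots[q.a][mesh.electrode_nodes[q.m]]
            - pots[q.a][mesh.electrode_nodes[q.n]]
            - pots[q.b][mesh.electrode_nodes[q.m]]
            + pots[q.b][mesh.electrode_nodes[q.n]]
        )
        j[i] = scale * np.einsum("ce,ce->c", g_ab, g_mn) / z
    return j
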