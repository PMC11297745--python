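"""Independent reference computations used by the test suite.

These deliberately avoid the package's own numerical paths: the FEM solver is
checked against a truncated cosine-series (method-of-images) solution of the
Neumann problem on a rectangle, enumeration against itertools brute force, and
power-law fitting against a refined grid search.
"""

from itertools import combinations

import numpy as np


def series_potential(
    points: np.ndarray,
    src: tuple[float, float],
    snk: tuple[float, float],
    lx: float,
    ly: float,
    sigma: float,
    thickness: float,
    n_terms: int = 400,
) -> np.ndarray:
    """Potential of a +1/-1 A dipole in a homogeneous, insulated rectangle.

    Eigenfunction expansion in Neumann cosine modes; the (0,0) mode is the
    gauge constant and is omitted, so the result has the same zero-mean gauge
    as the FEM solver up to a constant offset (compare differences only).
    """
    m = np.arange(0, n_terms + 1)
    n = np.arange(0, n_terms + 1)
    kx = m * np.pi / lx
    ky = n * np.pi / ly
    lam = kx[:, None] ** 2 + ky[None, :] ** 2
    lam[0, 0] = np.inf  # drop the constant mode
    # mode normalisation: integral of cos^2 over the rectangle
    cm = np.where(m == 0, lx, lx / 2)
    cn = np.where(n == 0, ly, ly / 2)
    norm = cm[:, None] * cn[None, :]

    def mode_values(p):
        return np.cos(kx * p[0])[:, None] * np.cos(ky * p[1])[None, :]

    source_term = mode_values(src) - mode_values(snk)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = np.sum(source_term * mode_values(p) / (lam * norm)) / (sigma * thickness)
    return out


def brute_force_quadrupoles(n_electrodes: int) -> set[tuple[int, int, int, int]]:
    """All reciprocal-unique quadrupoles on n electrodes: unordered disjoint
    dipole pairs {A,B}, {M,N}, keeping the representative whose injection pair
    is lexicographically smaller."""
    idx = range(n_electrodes)
    out = set()
    for ab in combinations(idx, 2):
        rest = [e for e in idx if e not in ab]
        for mn in combinations(rest, 2):
            if mn < ab:
                continue
            out.add((*ab, *mn))
    return out


def powerlaw_grid_search(
    x: np.ndarray, y: np.ndarray, coef_range=(1e-3, 1e3), exp_range=(-3.0, 3.0)
) -> tuple[float, float]:
    """Coarse-to-fine grid search minimizing log10-space SSE, refined to 1e-3
    in the exponent and in log10 of the coefficient."""
    lx, ly = np.log10(x), np.log10(y)
    lc_lo, lc_hi = np.log10(coef_range[0]), np.log10(coef_range[1])
    e_lo, e_hi = exp_range
    for _ in range(6):
        lcs = np.linspace(lc_lo, lc_hi, 41)
        exps = np.linspace(e_lo, e_hi, 41)
        sse = ((ly[None, None, :] - (lcs[:, None, None] + exps[None, :, None] * lx)) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        dc = (lc_hi - lc_lo) / 40
        de = (e_hi - e_lo) / 40
        lc_lo, lc_hi = lcs[i] - dc, lcs[i] + dc
        e_lo, e_hi = exps[j] - de, exps[j] + de
        if dc < 2.5e-4 and de < 2.5e-4:
            break
    return 10 ** ((lc_lo + lc_hi) / 2), (e_lo + e_hi) / 2
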