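import numpy as np
import pytest
import scipy.sparse as sp

from rhizoseit import DipolePoolRules, enumerate_candidates, exclude_electrodes
from rhizoseit.design import optimize_scheme, resolution_diagonal
from oracles import brute_force_quadrupoles


class TestEnumerateCandidates:
    def test_four_electrodes_match_brute_force(self):
        got = {q.as_tuple() for q in enumerate_candidates(4)}
        assert got == brute_force_quadrupoles(4)
        assert len(got) == 3  # three reciprocal-unique pairings

    def test_restricted_dipole_pool(self):
        allowed = frozenset({frozenset((0, 1)), frozenset((2, 3))})
        cands = enumerate_candidates(6, DipolePoolRules(allowed_dipoles=allowed))
        assert cands
        assert all(q.dipole in allowed for q in cands)

    def test_duplicate_free_and_lexicographic(self):
        cands = enumerate_candidates(8, DipolePoolRules(skips=(1, 2, 3)))
        tuples = [q.as_tuple() for q in cands]
        assert len(set(tuples)) == len(tuples)
        assert tuples == sorted(tuples)

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidates(3)


class TestResolutionDiagonal:
    @pytest.fixture()
    def system(self, rng):
        n = 30
        j = rng.normal(size=(60, n))  # overdetermined, full column rank
        w = np.ones(60)
        # full-rank regularizer so the infinite-lambda limit is exactly zero
        # (a pure first-difference operator leaves constants unpenalized)
        wm = sp.csr_matrix(np.eye(n))
        return j, w, wm

    def test_vanishing_regularization_gives_perfect_resolution(self, system):
        j, w, wm = system
        diag = resolution_diagonal(j, w, wm, 1e-12)
        assert np.allclose(diag, 1.0, atol=1e-4)

    def test_infinite_regularization_gives_no_resolution(self, system):
        j, w, wm = system
        diag = resolution_diagonal(j, w, wm, 1e12)
        assert np.allclose(diag, 0.0, atol=1e-4)

    def test_nonpositive_lambda_rejected(self, system):
        j, w, wm = system
        with pytest.raises(ValueError):
            resolution_diagonal(j, w, wm, 0.0)

    def test_trace_monotone_under_row_append(self, rng):
        """Appending a measurement row never decreases trace(R) at fixed
        lambda (Loewner-order property, checked on 50 random systems)."""
        n = 15
        wm = sp.csr_matrix(np.diff(np.eye(n), axis=0))
        for _ in range(50):
            j = rng.normal(size=(rng.integers(5, 25), n))
            row = rng.normal(size=(1, n))
            lam = float(10 ** rng.uniform(-3, 3))
            before = resolution_diagonal(j, np.ones(len(j)), wm, lam).sum()
            after = resolution_diagonal(
                np.vstack([j, row]), np.ones(len(j) + 1), wm, lam
            ).sum()
            assert after >= before - 1e-9


class TestOptimizeScheme:
    def test_reaches_target_within_dipole_budget(self, design_state):
        state = design_state
        state.selected, state.objective_log = [], []
        scheme = optimize_scheme(state, target_size=150, dipole_budget=40, batch_size=20)
        assert len(scheme) == 150
        assert len(scheme.injection_dipoles) <= 40

    def test_objective_monotone_and_resolution_bounded(self, design_state):
        state = design_state
        state.selected, state.objective_log = [], []
        optimize_scheme(state, target_size=150, dipole_budget=40, batch_size=20)
        log = state.objective_log
        assert all(b >= a - 1e-9 for a, b in zip(log, log[1:]))
        diag = resolution_diagonal(
            state.j_pool[state.selected],
            state.data_weights[state.selected],
            state.smoothness,
            state.lam,
        )
        # strict nonnegativity is not a theorem for smoothness-regularized
        # resolution matrices; excursions stay at the per-mil level
        assert diag.min() > -5e-3 and diag.max() < 1 + 1e-8

    def test_deterministic_rerun(self, design_state):
        state = design_state
        state.selected, state.objective_log = [], []
        s1 = optimize_scheme(state, target_size=60, dipole_budget=40, batch_size=10)
        state.selected, state.objective_log = [], []
        s2 = optimize_scheme(state, target_size=60, dipole_budget=40, batch_size=10)
        assert s1 == s2

    def test_beats_random_schemes_on_roi_objective(self, design_state, rng):
        """The greedy selection dominates 20 random equal-size schemes in the
        ROI-weighted resolution objective."""
        state = design_state
        state.selected, state.objective_log = [], []
        optimize_scheme(state, target_size=100, dipole_budget=40, batch_size=20)
        greedy_obj = state.objective()
        greedy_sel = list(state.selected)
        for _ in range(20):
            state.selected = list(rng.choice(len(state.candidates), 100, replace=False))
            assert state.objective() <= greedy_obj
        state.selected = greedy_sel

    def test_infeasible_budget_rejected(self, design_state):
        state = design_state
        state.selected, state.objective_log = [], []
        with pytest.raises(ValueError):
            optimize_scheme(state, target_size=0, dipole_budget=40)


class TestExcludeElectrodes:
    def test_empty_exclusion_is_identity(self, small_scheme):
        assert exclude_electrodes(small_scheme, set()) == small_scheme

    def test_excluding_all_electrodes_flags_empty_scheme(self, small_scheme):
        with pytest.raises(ValueError, match="every configuration"):
            exclude_electrodes(small_scheme, set(range(36)))

    def test_central_batch_exclusion_lowers_roi_resolution(
        self, design_state, small_scheme, geometry
    ):
        reduced = exclude_electrodes(small_scheme, geometry.central_batch)
        assert 0 < len(reduced) < len(small_scheme)
        assert all(
            not ({q.a, q.b, q.m, q.n} & set(geometry.central_batch)) for q in reduced
        )
        state = design_state
        index = {q: i for i, q in enumerate(state.candidates)}
        full_idx = [index[q] for q in small_scheme]
        red_idx = [index[q] for q in reduced]

        def roi_objective(sel):
            diag = resolution_diagonal(
                state.j_pool[sel], state.data_weights[sel], state.smoothness, state.lam
            )
            return float(state.cell_weights @ diag)

        assert roi_objective(red_idx) < roi_objective(full_idx)
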