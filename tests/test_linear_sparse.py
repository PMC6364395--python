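"""Unit and property tests for the sparse-system solvers."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import null_space

from akronkf import (
    BoundInputs,
    SparseSolution,
    UnderdeterminedSystem,
    akron,
    akron_noisy,
    basis_pursuit,
    delta_bound_prop1,
    delta_bound_prop2,
    kron_exact,
    solve_with_zero_set,
)
from akronkf.example import EXAMPLE_L1, example_system

from conftest import make_planted_system


# ---------------------------------------------------------------- containers


def test_system_rejects_overdetermined_and_rank_deficient():
    with pytest.raises(ValueError, match="p > n"):
        UnderdeterminedSystem(np.eye(3), np.zeros(3))
    phi = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])  # rank 1
    with pytest.raises(ValueError, match="rank"):
        UnderdeterminedSystem(phi, np.zeros(2))


def test_solution_invariants_hold_on_solver_outputs(rng):
    for _ in range(20):
        system, _ = make_planted_system(rng, 3, 7, 2)
        for sol in (
            basis_pursuit(system),
            solve_with_zero_set(system, rng.choice(7, 4, replace=False)),
            akron(system, basis_pursuit(system), delta=1),
        ):
            sol.validate(system)


# ------------------------------------------------------------- basis pursuit


def test_basis_pursuit_matches_printed_example():
    """The worked example's minimum-l1 solution, to the printed precision."""
    sol = basis_pursuit(example_system())
    assert np.allclose(sol.x, EXAMPLE_L1, atol=1e-3)
    assert sol.zero_set == (0, 3)


def test_basis_pursuit_identity_padded_column_is_unused():
    # the third column never helps the l1 objective
    system = UnderdeterminedSystem(np.array([[1.0, 0, 0], [0, 1.0, 0]]), np.array([1.0, 2.0]))
    sol = basis_pursuit(system)
    assert np.allclose(sol.x, [1.0, 2.0, 0.0], atol=1e-9)


def test_basis_pursuit_recovers_dominant_spike(rng):
    """A single large spike is recovered; checked against exhaustive search."""
    phi = rng.standard_normal((4, 8))
    x0 = np.zeros(8)
    x0[5] = 10.0
    system = UnderdeterminedSystem(phi, phi @ x0)
    sol = basis_pursuit(system)
    # independent oracle: try every single-entry candidate
    feasible = [
        (j, phi[:, [j]] @ np.linalg.lstsq(phi[:, [j]], system.y, rcond=None)[0])
        for j in range(8)
    ]
    exact = [j for j, yhat in feasible if np.allclose(yhat, system.y, atol=1e-8)]
    assert exact == [5]
    assert np.allclose(sol.x, x0, atol=1e-6)


def test_basis_pursuit_l1_objective_optimality(rng):
    """No feasible perturbation along the kernel beats the LP optimum."""
    system, _ = make_planted_system(rng, 4, 9, 3)
    sol = basis_pursuit(system)
    kernel = null_space(system.phi)
    for _ in range(1000):
        z = sol.x + kernel @ rng.normal(0.0, 1.0, size=kernel.shape[1])
        assert np.abs(sol.x).sum() <= np.abs(z).sum() + 1e-7


# --------------------------------------------------------- solve_with_zero_set


def test_solve_with_zero_set_example_candidates():
    """Re-solving the example with prescribed zeros matches a direct solve."""
    system = example_system()
    # independent oracle: direct 3x3 solve on the kept columns
    keep = [2, 3, 4]
    expected = np.zeros(5)
    expected[keep] = np.linalg.solve(system.phi[:, keep], system.y)
    sol = solve_with_zero_set(system, [0, 1])
    assert np.allclose(sol.x, expected, atol=1e-12)
    # the printed sparsest solution's nonzeros are reproduced only to the
    # rounding floor of the 4-decimal transcription (~1e-2)
    assert np.allclose(sol.x[3:], [-1.2372, 1.04858], atol=2e-2)


def test_solve_with_zero_set_single_equation():
    system = UnderdeterminedSystem(np.array([[1.0, 2.0]]), np.array([4.0]))
    sol = solve_with_zero_set(system, [0])
    assert np.allclose(sol.x, [0.0, 2.0])
    assert sol.residual == 0.0


def test_solve_with_zero_set_residual_matches_recomputation():
    system = example_system()
    sol = solve_with_zero_set(system, [0, 3])
    assert abs(sol.residual - np.linalg.norm(system.phi @ sol.x - system.y)) <= 1e-10


def test_solve_with_zero_set_wrong_size_errors():
    with pytest.raises(ValueError, match="exactly s=2"):
        solve_with_zero_set(example_system(), [0, 1, 2])


# ----------------------------------------------------------------- kron_exact


def _enumerate_l0_oracle(system, tol=1e-9):
    """Independent brute force: try every support of every size, smallest first."""
    p = system.p
    for size in range(p + 1):
        best = None
        for support in itertools.combinations(range(p), size):
            x = np.zeros(p)
            if support:
                coef, *_ = np.linalg.lstsq(system.phi[:, list(support)], system.y, rcond=None)
                x[list(support)] = coef
            if np.linalg.norm(system.phi @ x - system.y) <= tol:
                if best is None or np.abs(x).sum() < np.abs(best).sum():
                    best = x
        if best is not None:
            return best
    raise AssertionError("unreachable for a full-rank system")


def test_kron_exact_recovers_planted_solution_vs_bruteforce(rng):
    for _ in range(10):
        system, x0 = make_planted_system(rng, 3, 6, 2)
        oracle = _enumerate_l0_oracle(system)
        sol = kron_exact(system)
        assert np.allclose(sol.x, oracle, atol=1e-8)
        assert np.allclose(sol.x, x0, atol=1e-8)
        assert sol.num_zeros == 4


def test_kron_exact_zero_rhs_returns_zero_vector():
    system = UnderdeterminedSystem(np.random.default_rng(0).standard_normal((3, 6)), np.zeros(3))
    sol = kron_exact(system)
    assert np.allclose(sol.x, 0.0)
    assert sol.num_zeros == 6


def test_kron_exact_example_at_rounding_floor():
    """At the transcription's rounding floor the 3-zero solution wins."""
    sol = kron_exact(example_system(), tol=1e-3)
    assert sol.num_zeros == 3
    assert np.allclose(sol.x[:3], 0.0)
    assert np.allclose(sol.x[3:], [-1.2372, 1.04858], atol=1e-2)


def test_kron_exact_p_cap():
    rng = np.random.default_rng(1)
    system, _ = make_planted_system(rng, 5, 25, 2)
    with pytest.raises(ValueError, match="akron"):
        kron_exact(system)


# ---------------------------------------------------------------------- akron


def test_akron_example_delta1_selects_sparsest_candidate():
    """delta=1 pools the three smallest l1 entries and finds the 3-zero optimum."""
    system = example_system()
    seed = basis_pursuit(system)
    # pool = {0, 1, 3}: the two exact zeros plus the 0.034-magnitude entry
    order = np.argsort(np.abs(seed.x), kind="stable")
    assert sorted(order[:3]) == [0, 1, 3]
    assert math.comb(3, 2) == 3
    sol = akron(system, seed, delta=1, fit_tol=1e-3)
    # independent oracle: least squares on the last two columns only
    expected = np.zeros(5)
    expected[[3, 4]] = np.linalg.lstsq(system.phi[:, [3, 4]], system.y, rcond=None)[0]
    assert np.allclose(sol.x, expected, atol=1e-9)
    assert sol.num_zeros == 3


def test_akron_delta0_equals_zeroing_smallest_seed_entries(rng):
    system, _ = make_planted_system(rng, 4, 7, 2)
    seed = basis_pursuit(system)
    order = np.argsort(np.abs(seed.x), kind="stable")
    expected = solve_with_zero_set(system, sorted(int(j) for j in order[: system.s]))
    sol = akron(system, seed, delta=0)
    assert np.allclose(sol.x, expected.x, atol=1e-12)


def test_akron_delta_n_matches_kron_exact(rng):
    for _ in range(10):
        system, _ = make_planted_system(rng, 3, 6, 2)
        seed = basis_pursuit(system)
        full = akron(system, seed, delta=system.n)
        exact = kron_exact(system)
        assert full.num_zeros == exact.num_zeros
        assert full.residual <= 1e-8


def test_akron_residual_monotone_in_delta(rng):
    for _ in range(20):
        system, _ = make_planted_system(rng, 7, 10, 3, noise_sigma=0.3)
        seed = basis_pursuit(UnderdeterminedSystem(system.phi, system.y))
        residuals = [akron(system, seed, d).residual for d in range(4)]
        assert all(a >= b - 1e-12 for a, b in zip(residuals, residuals[1:]))


def test_akron_rejects_excessive_delta_and_combinations(rng):
    system, _ = make_planted_system(rng, 4, 30, 2)
    seed = np.zeros(30)
    with pytest.raises(ValueError, match="exceeds n"):
        akron(system, seed, delta=5)
    with pytest.raises(ValueError, match="combinations exceed"):
        akron(system, seed, delta=4, max_combinations=10)


# ---------------------------------------------------------------- akron_noisy


def test_akron_noisy_requires_positive_eps(rng):
    system, _ = make_planted_system(rng, 3, 6, 2)
    with pytest.raises(ValueError, match="akron"):
        akron_noisy(system, np.zeros(6))


def test_akron_noisy_infinite_eps_accepts_first_candidate(rng):
    base, _ = make_planted_system(rng, 3, 6, 2, noise_sigma=0.1)
    system = UnderdeterminedSystem(base.phi, base.y, noise_eps=np.inf)
    seed = basis_pursuit(UnderdeterminedSystem(base.phi, base.y))
    sol = akron_noisy(system, seed)
    noiseless = UnderdeterminedSystem(base.phi, base.y)
    expected = akron(noiseless, seed, delta=0)
    assert np.allclose(sol.x, expected.x)
    assert sol.converged


def test_akron_noisy_example_accepts_at_delta_zero():
    """The example's l1 support already fits exactly, so no escalation happens."""
    base = example_system()
    system = UnderdeterminedSystem(base.phi, base.y, noise_eps=1e-6)
    seed = basis_pursuit(base)
    sol = akron_noisy(system, seed)
    assert sol.converged
    assert sol.zero_set == (0, 3)  # the l1 solution's own support complement
    assert sol.residual <= 1e-6


def test_akron_noisy_recovers_planted_support_at_high_snr(rng):
    """When the seed ranks the true zeros smallest, the support survives.

    Any s-zero candidate re-solves a consistent square system exactly, so the
    escalation accepts at delta=0 and recovery hinges on the seed's ranking;
    at high SNR the l1 seed ranks correctly in the majority of draws, and in
    every such draw the planted support must be preserved.
    """
    well_seeded = 0
    recovered = 0
    for _ in range(20):
        system, x0 = make_planted_system(rng, 6, 10, 3, noise_sigma=1e-3)
        seed = basis_pursuit(UnderdeterminedSystem(system.phi, system.y), tol=1e-2)
        true_zeros = set(np.flatnonzero(x0 == 0))
        order = np.argsort(np.abs(seed.x), kind="stable")
        if set(int(j) for j in order[: system.s]) <= true_zeros:
            well_seeded += 1
            sol = akron_noisy(system, seed)
            if set(np.flatnonzero(x0)) <= set(np.flatnonzero(np.abs(sol.x) > 1e-2)):
                recovered += 1
    assert well_seeded >= 10
    assert recovered == well_seeded


def test_akron_noisy_nested_mode_overzeroes():
    base = example_system()
    system = UnderdeterminedSystem(base.phi, base.y, noise_eps=1e-6)
    seed = basis_pursuit(base)
    sol = akron_noisy(system, seed, mode="nested")
    assert sol.zero_set == (0, 3)


# --------------------------------------------------------------- delta bounds


@pytest.mark.parametrize(
    "x1, eps, k, s, expected",
    [
        # threshold 0.1/sqrt(2) ~ 0.0707: three entries below -> J=3, J-s=1
        ([0.0, 0.0, 0.0, 5.0, 5.0], 0.1, 3, 2, 1),
        # eps = 0 counts only exact zeros
        ([0.0, 0.0, 0.0, 5.0, 5.0], 0.0, 3, 2, 1),
        # everything above threshold -> J = 0 -> clamped to 0
        ([1.0, 1.0, 1.0, 5.0, 5.0], 0.1, 3, 2, 0),
    ],
)
def test_delta_bound_from_small_entry_count(x1, eps, k, s, expected):
    b = BoundInputs(eps=eps, k=k, s=s)
    assert delta_bound_prop1(np.array(x1), b) == expected


def test_delta_bound_prop1_requires_k_above_s():
    with pytest.raises(ValueError, match="k > s"):
        delta_bound_prop1(np.zeros(5), BoundInputs(eps=0.1, k=2, s=2))


@pytest.mark.parametrize(
    "eps, eta, expected",
    [
        (0.4, 1.0, 0),   # eps < eta/2 -> delta = 0 suffices
        (0.0, 1.0, 0),   # exact l1 solution
        (0.75, 1.0, 9),  # floor((0.75 / 0.25)^2) = 9
        (0.6, 1.0, 2),   # floor((0.6 / 0.4)^2) = floor(2.25)
    ],
)
def test_delta_bound_from_magnitude_floor(eps, eta, expected):
    assert delta_bound_prop2(BoundInputs(eps=eps, eta=eta)) == expected


def test_delta_bound_prop2_inapplicable_when_eps_reaches_eta():
    with pytest.raises(ValueError, match="inapplicable"):
        delta_bound_prop2(BoundInputs(eps=1.0, eta=1.0))


def test_small_entry_bound_guarantees_recovery(rng):
    """When delta is set from the small-entry count, the search finds the optimum."""
    checked = 0
    for _ in range(50):
        system, x0 = make_planted_system(rng, 5, 8, 2)
        k = int(np.sum(x0 == 0))
        assert k > system.s
        seed = basis_pursuit(system)
        eps = float(np.linalg.norm(seed.x - x0))
        delta = delta_bound_prop1(seed, BoundInputs(eps=eps, k=k, s=system.s))
        sol = akron(system, seed, min(delta, system.n))
        assert sol.num_zeros >= k
        assert sol.residual <= 1e-8
        checked += 1
    assert checked == 50
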