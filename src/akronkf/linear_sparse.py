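"""Sparsest-solution solvers for under-determined linear systems.

An under-determined system ``Phi x = y`` with ``Phi`` of shape ``n x p``,
``p > n``, has an ``s = p - n`` dimensional affine solution set.  The
sparsest-solution (minimum l0-"norm") problem asks for the member of that
set with the most zero entries.  This module provides

* :func:`basis_pursuit` -- the convex l1 surrogate (min ``||x||_1`` subject
  to ``Phi x = y``), solved as a linear program;
* :func:`kron_exact` -- exact kernel reconstruction: because fixing ``s``
  correct zero positions reduces the system to a uniquely solvable ``n x n``
  one, the l0 optimum can be found by enumerating all ``C(p, s)`` zero-position
  sets (exponential in ``p``; practical only for small ``p``);
* :func:`akron` -- approximate kernel reconstruction: restrict the
  enumeration to the ``C(s + delta, s)`` zero sets drawn from the ``s + delta``
  smallest-magnitude entries of an l1 seed solution.  ``delta`` tunes the
  accuracy/compute trade-off from "trust the l1 support" (``delta = 0``) to
  full enumeration (``delta = n``);
* :func:`akron_noisy` -- the adaptive escalation rule for noisy systems
  (``||Phi x - y|| <= eps`` instead of equality);
* :func:`delta_bound_prop1` / :func:`delta_bound_prop2` -- a-priori upper
  bounds on the ``delta`` needed for the search to contain the l0 optimum,
  in terms of how close the l1 seed is to it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import linprog

__all__ = [
    "UnderdeterminedSystem",
    "SparseSolution",
    "BoundInputs",
    "SolverError",
    "basis_pursuit",
    "solve_with_zero_set",
    "kron_exact",
    "akron",
    "akron_noisy",
    "delta_bound_prop1",
    "delta_bound_prop2",
]

#: Default residual tolerance below which a candidate is considered to fit
#: the system exactly (noiseless data at double precision).
DEFAULT_FIT_TOL = 1e-9

#: Default relative tolerance below which a computed entry counts as zero.
DEFAULT_ZERO_TOL = 1e-8

#: Residual gap within which two candidates are treated as tied.
RESIDUAL_TIE_TOL = 1e-9

#: Refuse enumerations larger than this many zero-set combinations.
DEFAULT_MAX_COMBINATIONS = 1_000_000

#: Above this many unknowns, exact enumeration is refused outright.
DEFAULT_ENUMERATION_P_CAP = 20


class SolverError(RuntimeError):
    """Raised when the linear-programming solver fails or does not converge."""


@dataclass(frozen=True)
class UnderdeterminedSystem:
    """A full-rank under-determined linear system ``Phi x = y``.

    Parameters
    ----------
    phi:
        Sensing matrix of shape ``(n, p)`` with ``p > n >= 1``.  Must have
        full row rank ``n``; a rank-deficient matrix is rejected because the
        kernel-dimension bookkeeping (``s = p - n``) would be wrong.
    y:
        Observation vector of length ``n``.
    noise_eps:
        Noise threshold ``eps >= 0``.  Zero means the system is treated as
        noiseless (solutions must satisfy the constraint exactly); a positive
        value is the l2 "energy of the noise" used by :func:`akron_noisy`.
    """

    phi: NDArray[np.float64]
    y: NDArray[np.float64]
    noise_eps: float = 0.0

    def __post_init__(self) -> None:
        phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "y", y)
        n, p = phi.shape
        if not (p > n >= 1):
            raise ValueError(
                f"system must be under-determined with p > n >= 1, got n={n}, p={p}"
            )
        if y.shape != (n,):
            raise ValueError(f"y has length {y.shape[0]}, expected n={n}")
        if not np.all(np.isfinite(phi)) or not np.all(np.isfinite(y)):
            raise ValueError("phi and y must be finite")
        if self.noise_eps < 0:
            raise ValueError("noise_eps must be nonnegative")
        rank = np.linalg.matrix_rank(phi)
        if rank < n:
            raise ValueError(
                f"phi must have full row rank n={n}, numerical rank is {rank}"
            )

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    @property
    def p(self) -> int:
        return self.phi.shape[1]

    @property
    def s(self) -> int:
        """Kernel (null-space) dimension ``p - n``."""
        return self.p - self.n

    def residual(self, x: ArrayLike) -> float:
        """l2 residual ``||Phi x - y||_2`` of a candidate solution."""
        return float(np.linalg.norm(self.phi @ np.asarray(x, dtype=float) - self.y))


@dataclass(frozen=True)
class SparseSolution:
    """A candidate solution of an under-determined system.

    ``zero_set`` lists the indices that were *fixed* to exactly zero by the
    solver; ``num_zeros`` additionally counts entries that came out smaller
    than ``zero_tol`` (relative to ``max |x|``) in magnitude, so
    ``num_zeros >= len(zero_set)`` always holds.  ``converged`` is only
    meaningful for :func:`akron_noisy`, where ``False`` flags that no
    candidate reached the noise threshold and the minimal-residual one was
    returned instead.
    """

    x: NDArray[np.float64]
    zero_set: tuple[int, ...]
    residual: float
    num_zeros: int
    zero_tol: float = DEFAULT_ZERO_TOL
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float).ravel())
        object.__setattr__(self, "zero_set", tuple(sorted(int(j) for j in self.zero_set)))

    @property
    def l1(self) -> float:
        return float(np.abs(self.x).sum())

    def validate(self, system: UnderdeterminedSystem | None = None) -> None:
        """Check the container's own invariants; raise ``AssertionError`` if broken."""
        assert all(self.x[j] == 0.0 for j in self.zero_set), "zero_set entries must be exact zeros"
        assert self.num_zeros >= len(self.zero_set)
        if system is not None:
            assert abs(self.residual - system.residual(self.x)) <= 1e-10, (
                "stored residual disagrees with recomputation"
            )


@dataclass(frozen=True)
class BoundInputs:
    """Inputs to the a-priori delta bounds.

    ``eps`` bounds the l2 distance from the l1 seed to the l0 optimum
    ``x*``; ``eta`` bounds the nonzero magnitudes of ``x*`` from below;
    ``k`` is the number of zeros of ``x*``; ``s`` the kernel dimension.
    """

    eps: float
    eta: float | None = None
    k: int | None = None
    s: int | None = None

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")


def _zero_threshold(x: NDArray[np.float64], zero_tol: float) -> float:
    # zero_tol is interpreted relative to the largest magnitude so that the
    # notion of "zero" scales with the solution.
    m = float(np.max(np.abs(x))) if x.size else 0.0
    return zero_tol * m if m > 0 else zero_tol


def _make_solution(
    system: UnderdeterminedSystem,
    x: NDArray[np.float64],
    zero_set: Iterable[int],
    zero_tol: float,
    converged: bool = True,
) -> SparseSolution:
    x = np.asarray(x, dtype=float).copy()
    zero_set = tuple(sorted(int(j) for j in zero_set))
    x[list(zero_set)] = 0.0
    thr = _zero_threshold(x, zero_tol)
    num_zeros = int(np.count_nonzero(np.abs(x) <= thr))
    return SparseSolution(
        x=x,
        zero_set=zero_set,
        residual=system.residual(x),
        num_zeros=num_zeros,
        zero_tol=zero_tol,
        converged=converged,
    )


def _solve_zeros(
    system: UnderdeterminedSystem,
    zero_set: tuple[int, ...],
    zero_tol: float,
) -> SparseSolution:
    """Solve the system with the given entries fixed to zero.

    Deleting ``len(zero_set)`` columns leaves an ``n x (p - |zero_set|)``
    system solved by minimum-norm least squares (exact for a nonsingular
    square reduction, graceful for singular or over-zeroed ones).
    """
    p = system.p
    keep = [j for j in range(p) if j not in zero_set]
    x = np.zeros(p)
    if keep:
        sub = system.phi[:, keep]
        coef, *_ = np.linalg.lstsq(sub, system.y, rcond=None)
        x[keep] = coef
    return _make_solution(system, x, zero_set, zero_tol)


def solve_with_zero_set(
    system: UnderdeterminedSystem,
    zero_set: Sequence[int],
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> SparseSolution:
    """Solve ``Phi x = y`` with exactly ``s`` prescribed zero positions.

    If the ``s`` zero locations of an l0 optimum are known, deleting those
    columns leaves a square ``n x n`` system whose (unique, for a nonsingular
    reduction) solution is that optimum.  Singular reductions fall back to
    minimum-norm least squares and are scored by their residual rather than
    rejected, which keeps combinatorial searches total.
    """
    zs = tuple(sorted(int(j) for j in zero_set))
    if len(set(zs)) != len(zs):
        raise ValueError("zero_set contains duplicate indices")
    if len(zs) != system.s:
        raise ValueError(
            f"zero_set must have exactly s={system.s} indices, got {len(zs)}"
        )
    if zs and (zs[0] < 0 or zs[-1] >= system.p):
        raise ValueError("zero_set indices out of range")
    return _solve_zeros(system, zs, zero_tol)


def basis_pursuit(
    system: UnderdeterminedSystem,
    tol: float = DEFAULT_FIT_TOL,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> SparseSolution:
    """Minimum l1-norm solution of ``Phi x = y`` (basis pursuit).

    Solved as the standard linear program over the positive/negative split
    ``x = u - v``, ``u, v >= 0``: minimise ``sum(u) + sum(v)`` subject to
    ``Phi (u - v) = y``.  Entries whose magnitude falls below ``zero_tol``
    (relative to ``max |x|``) are clamped to exact zero and reported in
    ``zero_set``.

    Raises
    ------
    SolverError
        If the LP solver reports infeasibility (which for a full-rank
        ``Phi`` signals a numerical rank failure) or non-convergence; the
        solver status is included in the message.  Also raised when the
        equality constraints are violated by more than ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n, p = system.phi.shape
    c = np.ones(2 * p)
    a_eq = np.hstack([system.phi, -system.phi])
    res = linprog(
        c,
        A_eq=a_eq,
        b_eq=system.y,
        bounds=(0, None),
        method="highs",
        options={
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-9,
        },
    )
    if res.status != 0:
        raise SolverError(
            f"basis pursuit LP failed (status {res.status}: {res.message}); "
            "infeasibility for a full-rank system indicates numerical rank failure"
        )
    x = res.x[:p] - res.x[p:]
    violation = float(np.max(np.abs(system.phi @ x - system.y)))
    if violation > tol:
        raise SolverError(
            f"basis pursuit constraint violation {violation:.3e} exceeds tol {tol:.3e}"
        )
    thr = _zero_threshold(x, zero_tol)
    detected = tuple(int(j) for j in np.flatnonzero(np.abs(x) <= thr))
    return _make_solution(system, x, detected, zero_tol)


def _sparsify(
    system: UnderdeterminedSystem,
    sol: SparseSolution,
    fit_tol: float,
    zero_tol: float,
) -> SparseSolution:
    """Greedily extend a fitting solution's zero set while it keeps fitting.

    Repeatedly fixes the smallest-magnitude free entry to zero and re-solves;
    stops as soon as the refit residual exceeds ``fit_tol``.  This turns
    "entries that happen to come out tiny" into certified exact zeros and is
    what lets the search report solutions sparser than ``s`` zeros.
    """
    zeros = set(sol.zero_set)
    best = sol
    while True:
        free = [j for j in range(system.p) if j not in zeros]
        if not free:
            break
        j = min(free, key=lambda j: (abs(best.x[j]), j))
        cand = _solve_zeros(system, tuple(sorted(zeros | {j})), zero_tol)
        if cand.residual <= fit_tol:
            zeros.add(j)
            best = cand
        else:
            break
    return best


def _select(
    candidates: Sequence[SparseSolution],
    fit_tol: float,
) -> SparseSolution:
    """Pick the winning candidate.

    Candidates whose residual fits within ``fit_tol`` are ranked by the l0
    objective: most zeros first, then smallest l1 norm, then lexicographically
    smallest zero set (a deterministic tie-break).  If nothing fits, the
    minimal-residual candidate wins, with ties within ``RESIDUAL_TIE_TOL``
    broken by the same sparsity-first keys.
    """
    if not candidates:
        raise ValueError("no candidates to select from")

    def keys(c: SparseSolution) -> tuple:
        return (-c.num_zeros, c.l1, c.zero_set)

    fitting = [c for c in candidates if c.residual <= fit_tol]
    if fitting:
        return min(fitting, key=keys)
    rmin = min(c.residual for c in candidates)
    tied = [c for c in candidates if c.residual <= rmin + RESIDUAL_TIE_TOL]
    return min(tied, key=keys)


def kron_exact(
    system: UnderdeterminedSystem,
    tol: float = DEFAULT_FIT_TOL,
    zero_tol: float = DEFAULT_ZERO_TOL,
    p_cap: int = DEFAULT_ENUMERATION_P_CAP,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> SparseSolution:
    """Exact l0 solution by full enumeration of zero-position sets.

    Every one of the ``C(p, s)`` ways of fixing ``s`` entries to zero is
    re-solved; fitting candidates are greedily extended to even sparser ones
    while the residual stays within ``tol``, and the sparsest fitting
    solution wins (ties: smallest l1, then lexicographic zero set).

    The enumeration cost is exponential; systems with ``p > p_cap`` are
    refused with a pointer to :func:`akron`.
    """
    if system.p > p_cap:
        raise ValueError(
            f"p={system.p} exceeds the enumeration cap {p_cap}; "
            "use akron with a delta-neighborhood instead"
        )
    total = math.comb(system.p, system.s)
    if total > max_combinations:
        raise ValueError(
            f"C({system.p},{system.s}) = {total} combinations exceed the cap "
            f"{max_combinations}; use akron with a smaller delta"
        )
    candidates = []
    for zs in itertools.combinations(range(system.p), system.s):
        cand = _solve_zeros(system, zs, zero_tol)
        if cand.residual <= tol:
            cand = _sparsify(system, cand, tol, zero_tol)
        candidates.append(cand)
    return _select(candidates, tol)


def _seed_vector(l1_seed: SparseSolution | ArrayLike) -> NDArray[np.float64]:
    x = l1_seed.x if isinstance(l1_seed, SparseSolution) else np.asarray(l1_seed, dtype=float)
    return x.ravel()


def _neighborhood_pool(
    system: UnderdeterminedSystem,
    seed_x: NDArray[np.float64],
    delta: int,
) -> list[int]:
    """Indices of the ``s + delta`` smallest-magnitude seed entries.

    Magnitude ties are broken toward the lower index (stable sort).
    """
    if seed_x.shape != (system.p,):
        raise ValueError(f"seed has length {seed_x.size}, expected p={system.p}")
    order = np.argsort(np.abs(seed_x), kind="stable")
    return sorted(int(j) for j in order[: system.s + delta])


def akron(
    system: UnderdeterminedSystem,
    l1_seed: SparseSolution | ArrayLike,
    delta: int,
    fit_tol: float = DEFAULT_FIT_TOL,
    zero_tol: float = DEFAULT_ZERO_TOL,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> SparseSolution:
    """Approximate kernel reconstruction around an l1 seed.

    Takes the ``s + delta`` smallest-magnitude entries of the seed, re-solves
    the system for each of the ``C(s + delta, s)`` ways of fixing ``s`` of
    them to zero, and returns the winner under the l0 objective (see
    :func:`_select`).  ``delta = 0`` trusts the l1 support outright
    (one combination); ``delta = n`` enumerates every zero set that full
    kernel reconstruction would, and recovers its answer.

    ``fit_tol`` is the residual level at which a candidate counts as solving
    the system.  For data whose entries are themselves rounded (for example
    values transcribed from a printed table), set it to the rounding noise
    floor rather than machine precision.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta > system.n:
        raise ValueError(
            f"delta={delta} exceeds n={system.n}; delta=n already reproduces "
            "full kernel reconstruction"
        )
    total = math.comb(system.s + delta, system.s)
    if total > max_combinations:
        raise ValueError(
            f"C({system.s + delta},{system.s}) = {total} combinations exceed the "
            f"cap {max_combinations}; reduce delta"
        )
    seed_x = _seed_vector(l1_seed)
    pool = _neighborhood_pool(system, seed_x, delta)
    candidates = []
    for zs in itertools.combinations(pool, system.s):
        cand = _solve_zeros(system, zs, zero_tol)
        if cand.residual <= fit_tol:
            cand = _sparsify(system, cand, fit_tol, zero_tol)
        candidates.append(cand)
    return _select(candidates, fit_tol)


def akron_noisy(
    system: UnderdeterminedSystem,
    l1_seed: SparseSolution | ArrayLike,
    mode: str = "all",
    zero_tol: float = DEFAULT_ZERO_TOL,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> SparseSolution:
    """Adaptive delta escalation for noisy systems.

    Starting from the ``s`` smallest-magnitude seed entries, the candidate
    pool grows one element at a time (in ascending magnitude order).  At pool
    size ``s + delta`` the residual of the best candidate is compared with the
    noise energy ``system.noise_eps`` (an l2 threshold); the first pool size
    whose best candidate fits within it is accepted.  If even ``delta = n``
    fails, the overall minimal-residual candidate is returned flagged
    ``converged=False``.

    ``mode="all"`` evaluates every ``C(s + delta, s)`` zero set of the pool
    (consistent with the noiseless search); ``mode="nested"`` is the literal
    one-more-zero reading, fixing *all* ``s + delta`` pool entries to zero and
    scoring the over-zeroed least-squares fit.
    """
    if system.noise_eps <= 0:
        raise ValueError("noise_eps must be positive; use akron for noiseless systems")
    if mode not in ("all", "nested"):
        raise ValueError(f"unknown mode {mode!r}; expected 'all' or 'nested'")
    eps = system.noise_eps
    seed_x = _seed_vector(l1_seed)
    best_overall: SparseSolution | None = None
    for delta in range(system.n + 1):
        pool = _neighborhood_pool(system, seed_x, delta)
        if mode == "all":
            total = math.comb(system.s + delta, system.s)
            if total > max_combinations:
                raise ValueError(
                    f"C({system.s + delta},{system.s}) = {total} combinations exceed "
                    f"the cap {max_combinations}"
                )
            candidates = [
                _solve_zeros(system, zs, zero_tol)
                for zs in itertools.combinations(pool, system.s)
            ]
        else:
            candidates = [_solve_zeros(system, tuple(pool), zero_tol)]
        sel = _select(candidates, eps)
        if best_overall is None or sel.residual < best_overall.residual:
            best_overall = sel
        if sel.residual <= eps:
            return sel
    assert best_overall is not None
    return replace(best_overall, converged=False)


def delta_bound_prop1(
    l1_seed: SparseSolution | ArrayLike,
    b: BoundInputs,
) -> int:
    """Delta bound from counting small seed entries.

    If the l0 optimum has ``k > s`` zeros and the seed lies within l2
    distance ``eps`` of it, then at least ``s`` of the optimum's zero
    positions must carry seed magnitudes at most ``eps / sqrt(k - s + 1)``.
    With ``J`` the number of seed entries below that threshold, any
    ``delta <= J - s`` suffices for the search pool to contain a correct
    zero set; the returned value is ``max(J - s, 0)``.
    """
    if b.k is None or b.s is None:
        raise ValueError("BoundInputs.k and BoundInputs.s are required")
    if b.k <= b.s:
        raise ValueError(f"bound requires k > s, got k={b.k}, s={b.s}")
    x = _seed_vector(l1_seed)
    thr = b.eps / math.sqrt(b.k - b.s + 1)
    j_count = int(np.count_nonzero(np.abs(x) <= thr))
    return max(j_count - b.s, 0)


def delta_bound_prop2(b: BoundInputs) -> int:
    """Delta bound from a magnitude floor on the optimum's nonzeros.

    If every nonzero of the l0 optimum has magnitude at least ``eta`` and
    the seed is within l2 distance ``eps < eta`` of it, then
    ``delta = floor((eps / (eta - eps))^2)`` suffices; in particular
    ``eps < eta / 2`` gives ``delta = 0`` (the l1 support is already
    correct).
    """
    if b.eta is None:
        raise ValueError("BoundInputs.eta is required")
    if b.eps >= b.eta:
        raise ValueError(
            f"bound inapplicable: requires eps < eta, got eps={b.eps}, eta={b.eta}"
        )
    if b.eps < b.eta / 2:
        return 0
    return int(math.floor((b.eps / (b.eta - b.eps)) ** 2))
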