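"""Per-gene Kalman tracking of sparse, time-varying incoming-edge vectors.

The connectivity of a p-gene network at epoch k is a signed matrix ``A(k)``
whose row ``a_i(k)`` holds the incoming edges of gene i (positive =
activating, negative = repressing).  Each row evolves by a Gaussian random
walk, ``a_i(k+1) = a_i(k) + w_i(k)``, and is observed through the expression
data of epoch k: ``y_i(k) = X(k)^T a_i(k) + v_i(k)``, where ``X(k)`` is the
p x n_k expression matrix and ``y_i(k)`` the rate of change of gene i's
expression at the epoch's n_k samples.  With ``n_k < p`` the system is
under-determined, so the raw Kalman estimate is refined in two steps per
epoch: an l1 projection (soft-thresholding, the exact proximal solution of
the sparsity/tracking trade-off objective) followed by the delta-neighborhood
kernel-reconstruction search of :mod:`akronkf.linear_sparse`.  Rows are
independent, so the full matrix is assembled by tracking genes in parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from numpy.typing import ArrayLike, NDArray

from .linear_sparse import (
    DEFAULT_ZERO_TOL,
    SparseSolution,
    UnderdeterminedSystem,
    akron,
    akron_noisy,
)

__all__ = [
    "GeneState",
    "EpochData",
    "TrackerConfig",
    "TimeVaryingNetwork",
    "GeneTrackResult",
    "kf_predict",
    "kf_update",
    "lasso_project",
    "rts_smooth",
    "compute_derivatives",
    "track_gene",
    "track_network",
    "track_network_epochs",
]

#: Eigenvalue slack (relative to the trace) for the PSD check on covariances.
PSD_SLACK = 1e-10


@dataclass(frozen=True)
class GeneState:
    """Kalman state of one gene: incoming-edge mean ``a`` and covariance ``P``."""

    a: NDArray[np.float64]
    P: NDArray[np.float64]
    epoch_index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).ravel()
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "P", P)
        if P.shape != (a.size, a.size):
            raise ValueError(f"P must be {a.size}x{a.size}, got {P.shape}")

    def validate(self) -> None:
        """Check symmetry and positive semidefiniteness of ``P``."""
        assert np.allclose(self.P, self.P.T, atol=1e-8), "P must be symmetric"
        eig = np.linalg.eigvalsh(self.P)
        assert eig.min() >= -PSD_SLACK * max(np.trace(self.P), 1.0), "P must be PSD"


@dataclass(frozen=True)
class EpochData:
    """One epoch's observations: expression ``X`` (p x n_k) and rates ``Y`` (p x n_k)."""

    X: NDArray[np.float64]
    Y: NDArray[np.float64]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape != Y.shape:
            raise ValueError(f"X and Y must share shape, got {X.shape} vs {Y.shape}")
        if X.shape[1] < 1:
            raise ValueError("epoch must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class TrackerConfig:
    """Tuning knobs of the tracker.

    alpha:
        Trade-off of the l1 projection, in [0, 1].  0 keeps the raw Kalman
        estimate, values near 1 shrink everything to zero.  Default 0.2.
    delta:
        Neighborhood excess of the kernel-reconstruction search.  Default 1.
    q_scale, r_scale:
        Isotropic process / observation noise scales (``Q = q I``,
        ``R = r I``).
    p0_scale:
        Initial covariance scale; large = uninformative prior.
    smooth:
        Also run the fixed-interval (RTS) backward pass and re-apply the
        projection + search to the smoothed estimates.
    noise_eps:
        If positive, per-epoch refinement uses the adaptive noisy-case rule
        with this l2 noise threshold instead of a fixed delta.
    zero_tol:
        Relative magnitude below which an entry counts as zero.
    carry_refined:
        Carry the sparse refined estimate forward as the next epoch's prior
        mean (keeps sparsity persistent); ``False`` carries the raw Kalman
        estimate instead.
    fit_tol:
        Residual level at which a refinement candidate counts as solving the
        epoch system exactly.
    """

    alpha: float = 0.2
    delta: int = 1
    q_scale: float = 1e-2
    r_scale: float = 1e-1
    p0_scale: float = 1e2
    smooth: bool = False
    noise_eps: float = 0.0
    zero_tol: float = DEFAULT_ZERO_TOL
    carry_refined: bool = True
    fit_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        for name in ("q_scale", "r_scale", "p0_scale", "zero_tol", "fit_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class TimeVaryingNetwork:
    """A sequence of p x p signed connectivity matrices, one per epoch."""

    A: tuple[NDArray[np.float64], ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        A = tuple(np.asarray(a, dtype=float) for a in self.A)
        names = tuple(str(g) for g in self.gene_names)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "gene_names", names)
        p = len(names)
        for k, a in enumerate(A):
            if a.shape != (p, p):
                raise ValueError(f"A[{k}] has shape {a.shape}, expected ({p}, {p})")

    @property
    def n_epochs(self) -> int:
        return len(self.A)

    @property
    def p(self) -> int:
        return len(self.gene_names)


def kf_predict(state: GeneState, q_scale: float) -> GeneState:
    """Time update under the random-walk model: mean unchanged, ``P += q I``."""
    if q_scale < 0:
        raise ValueError("q_scale must be nonnegative")
    P = state.P + q_scale * np.eye(state.a.size)
    P = 0.5 * (P + P.T)
    return GeneState(state.a, P, state.epoch_index)


def kf_update(
    state: GeneState,
    X: ArrayLike,
    y: ArrayLike,
    r_scale: float,
) -> GeneState:
    """Measurement update with observation matrix ``H = X^T`` and ``R = r I``.

    All ``n_k`` samples of the epoch enter a single stacked update.  The gain
    is obtained from a linear solve against the innovation covariance (never
    an explicit inverse) and the covariance uses the Joseph form, which keeps
    ``P`` symmetric PSD even with a nearly singular innovation covariance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = state.a.size
    if X.shape[0] != p:
        raise ValueError(f"X must have {p} rows, got {X.shape[0]}")
    if y.shape[0] != X.shape[1]:
        raise ValueError(f"y has length {y.size}, expected {X.shape[1]}")
    H = X.T  # (n_k, p)
    n_k = H.shape[0]
    S = H @ state.P @ H.T + r_scale * np.eye(n_k)
    S = 0.5 * (S + S.T)
    try:
        # K = P H^T S^{-1}; with S symmetric, K^T = S^{-1} H P.
        K = np.linalg.solve(S, H @ state.P).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "innovation covariance is numerically singular; "
            "increase r_scale to regularize the update"
        ) from exc
    innovation = y - H @ state.a
    a_new = state.a + K @ innovation
    ikh = np.eye(p) - K @ H
    P_new = ikh @ state.P @ ikh.T + r_scale * (K @ K.T)
    P_new = 0.5 * (P_new + P_new.T)
    return GeneState(a_new, P_new, state.epoch_index)


def lasso_project(a: ArrayLike, alpha: float) -> NDArray[np.float64]:
    """Exact minimizer of ``(1 - alpha) ||a0 - a||_2^2 + alpha ||a||_1``.

    The objective is separable, so the minimizer is elementwise
    soft-thresholding of the input with threshold
    ``lambda = alpha / (2 (1 - alpha))``.  ``alpha = 0`` returns the input
    unchanged; ``alpha = 1`` makes the objective ignore the data term, so the
    zero vector is returned with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 1.0:
        warnings.warn(
            "alpha=1 makes the projection objective degenerate; returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(a)
    lam = alpha / (2.0 * (1.0 - alpha))
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def rts_smooth(
    filtered: Sequence[GeneState],
    predicted: Sequence[GeneState],
) -> list[GeneState]:
    """Fixed-interval (Rauch-Tung-Striebel) smoother with identity transition.

    ``filtered[k]`` is the posterior at epoch k and ``predicted[k]`` the prior
    (so ``predicted[k + 1]`` is the one-step prediction from epoch k).  The
    backward pass refines each filtered state using all later observations;
    the last smoothed state equals the last filtered state.
    """
    if len(filtered) != len(predicted):
        raise ValueError(
            f"filtered and predicted sequences must align, got "
            f"{len(filtered)} vs {len(predicted)}"
        )
    if not filtered:
        raise ValueError("need at least one state")
    T = len(filtered)
    smoothed: list[GeneState] = [filtered[-1]]
    for k in range(T - 2, -1, -1):
        f, pr_next, sm_next = filtered[k], predicted[k + 1], smoothed[0]
        # G = P_f P_pred^{-1}; P_pred symmetric, so G = solve(P_pred, P_f)^T.
        G = np.linalg.solve(pr_next.P, f.P).T
        a = f.a + G @ (sm_next.a - pr_next.a)
        P = f.P + G @ (sm_next.P - pr_next.P) @ G.T
        P = 0.5 * (P + P.T)
        smoothed.insert(0, GeneState(a, P, f.epoch_index))
    return smoothed


def compute_derivatives(
    expression: ArrayLike,
    sample_times: ArrayLike,
    partition: Sequence[tuple[int, int]] | None = None,
) -> NDArray[np.float64]:
    """Per-gene rate of change of expression by finite differences.

    Central differences at interior samples, one-sided at the boundaries.
    When an epoch ``partition`` (0-based half-open ``[start, stop)`` ranges)
    is supplied, differences never cross epoch boundaries: each epoch is
    differentiated independently, so a single-sample jump between stages does
    not contaminate either stage's rates.
    """
    E = np.atleast_2d(np.asarray(expression, dtype=float))
    t = np.asarray(sample_times, dtype=float).ravel()
    if E.shape[1] != t.size:
        raise ValueError(f"expression has {E.shape[1]} samples but {t.size} times given")
    if t.size < 2:
        raise ValueError("need at least two samples to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing (no duplicates)")
    segments = [(0, t.size)] if partition is None else [tuple(seg) for seg in partition]
    out = np.empty_like(E)
    for start, stop in segments:
        if stop - start < 2:
            raise ValueError(
                f"epoch [{start}, {stop}) has fewer than two samples; "
                "cannot estimate rates within it"
            )
        out[:, start:stop] = np.gradient(E[:, start:stop], t[start:stop], axis=1)
    return out


@dataclass(frozen=True)
class GeneTrackResult:
    """Per-epoch estimates of one gene's incoming-edge vector, by stage.

    ``kf`` is the raw Kalman posterior mean, ``lasso`` its l1 projection,
    ``akron`` the kernel-reconstruction refinement (the tracker's primary
    output).  The ``*_smooth`` stages repeat the projection/refinement on the
    RTS-smoothed states and are empty when smoothing was not requested.
    ``converged`` flags, per epoch, whether the noisy-case escalation reached
    the noise threshold (always True in noiseless mode).
    """

    kf: tuple[NDArray[np.float64], ...]
    lasso: tuple[NDArray[np.float64], ...]
    akron: tuple[NDArray[np.float64], ...]
    kf_smooth: tuple[NDArray[np.float64], ...] = ()
    lasso_smooth: tuple[NDArray[np.float64], ...] = ()
    akron_smooth: tuple[NDArray[np.float64], ...] = ()
    converged: tuple[bool, ...] = ()
    residuals: tuple[float, ...] = ()

    @property
    def estimates(self) -> tuple[NDArray[np.float64], ...]:
        """Primary output: the refined sparse estimate per epoch."""
        return self.akron


def _refine(
    X: NDArray[np.float64],
    y: NDArray[np.float64],
    projected: NDArray[np.float64],
    config: TrackerConfig,
) -> SparseSolution | None:
    """Sparse refinement of a projected estimate for one epoch's system.

    Returns ``None`` when the epoch is not under-sampled (``n_k >= p``), in
    which case there is no kernel to search and the projection stands.
    """
    p, n_k = X.shape
    if n_k >= p:
        return None
    system = UnderdeterminedSystem(X.T, y, noise_eps=config.noise_eps)
    if config.noise_eps > 0:
        return akron_noisy(system, projected, zero_tol=config.zero_tol)
    return akron(
        system,
        projected,
        min(config.delta, system.n),
        fit_tol=config.fit_tol,
        zero_tol=config.zero_tol,
    )


def track_gene(
    epochs: Sequence[tuple[ArrayLike, ArrayLike]],
    config: TrackerConfig,
) -> GeneTrackResult:
    """Track one gene's incoming-edge vector across epochs.

    Each epoch applies predict -> stacked measurement update -> l1 projection
    -> kernel-reconstruction refinement.  The refined sparse vector is the
    epoch's output and (by default) the prior mean carried into the next
    epoch, while the covariance is carried from the standard update.  With
    ``config.smooth``, an RTS backward pass runs over the pre-projection
    filtered states and the projection + refinement are re-applied to the
    smoothed estimates.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    first_X = np.atleast_2d(np.asarray(epochs[0][0], dtype=float))
    p = first_X.shape[0]
    state = GeneState(np.zeros(p), config.p0_scale * np.eye(p), 0)

    kf_list: list[NDArray[np.float64]] = []
    lasso_list: list[NDArray[np.float64]] = []
    akron_list: list[NDArray[np.float64]] = []
    converged: list[bool] = []
    residuals: list[float] = []
    filtered: list[GeneState] = []
    predicted: list[GeneState] = []

    for k, (X, y) in enumerate(epochs):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        prior = kf_predict(state, config.q_scale) if k > 0 else state
        predicted.append(prior)
        filt = kf_update(prior, X, y, config.r_scale)
        filtered.append(filt)
        kf_list.append(filt.a)

        projected = lasso_project(filt.a, config.alpha)
        lasso_list.append(projected)

        sol = _refine(X, y, projected, config)
        if sol is None:
            refined, ok, res = projected, True, float(np.linalg.norm(X.T @ projected - y))
        else:
            refined, ok, res = sol.x, sol.converged, sol.residual
        akron_list.append(refined)
        converged.append(ok)
        residuals.append(res)

        carry = refined if config.carry_refined else filt.a
        state = GeneState(carry, filt.P, k + 1)

    kf_s: list[NDArray[np.float64]] = []
    lasso_s: list[NDArray[np.float64]] = []
    akron_s: list[NDArray[np.float64]] = []
    if config.smooth:
        smoothed = rts_smooth(filtered, predicted)
        for (X, y), sm in zip(epochs, smoothed):
            X = np.atleast_2d(np.asarray(X, dtype=float))
            y = np.asarray(y, dtype=float).ravel()
            kf_s.append(sm.a)
            proj = lasso_project(sm.a, config.alpha)
            lasso_s.append(proj)
            sol = _refine(X, y, proj, config)
            akron_s.append(proj if sol is None else sol.x)

    return GeneTrackResult(
        kf=tuple(kf_list),
        lasso=tuple(lasso_list),
        akron=tuple(akron_list),
        kf_smooth=tuple(kf_s),
        lasso_smooth=tuple(lasso_s),
        akron_smooth=tuple(akron_s),
        converged=tuple(converged),
        residuals=tuple(residuals),
    )


def _assemble(
    results: Sequence[GeneTrackResult],
    stage: str,
    gene_names: Sequence[str],
    n_epochs: int,
) -> TimeVaryingNetwork:
    p = len(results)
    mats = []
    for k in range(n_epochs):
        A = np.vstack([getattr(results[i], stage)[k] for i in range(p)])
        mats.append(A)
    return TimeVaryingNetwork(tuple(mats), tuple(gene_names))


def track_network_epochs(
    epochs: Sequence[EpochData],
    config: TrackerConfig,
    gene_names: Sequence[str] | None = None,
    n_jobs: int = 1,
) -> dict[str, TimeVaryingNetwork]:
    """Track every gene over pre-sliced epoch data and assemble networks.

    Rows are independent, so genes are processed in parallel (deterministic:
    the result does not depend on execution order).  Returns one network per
    method stage: ``"kf"`` (raw Kalman), ``"lasso_kf"`` (l1-projected) and
    ``"akron_kf"`` (refined), plus ``*_smooth`` variants when requested.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    p = epochs[0].X.shape[0]
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(p)]
    if len(gene_names) != p:
        raise ValueError(f"{len(gene_names)} gene names for {p} genes")

    def one_gene(i: int) -> GeneTrackResult:
        return track_gene([(e.X, e.Y[i]) for e in epochs], config)

    if n_jobs == 1:
        results = [one_gene(i) for i in range(p)]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one_gene)(i) for i in range(p))

    stages = ["kf", "lasso_kf", "akron_kf"]
    stage_attr = {"kf": "kf", "lasso_kf": "lasso", "akron_kf": "akron"}
    if config.smooth:
        stages += ["kf_smooth", "lasso_kf_smooth", "akron_kf_smooth"]
        stage_attr.update(
            kf_smooth="kf_smooth",
            lasso_kf_smooth="lasso_smooth",
            akron_kf_smooth="akron_smooth",
        )
    return {
        st: _assemble(results, stage_attr[st], gene_names, len(epochs)) for st in stages
    }


def _check_partition(partition: Sequence[tuple[int, int]], m: int) -> None:
    covered = np.zeros(m, dtype=bool)
    for start, stop in partition:
        if stop <= start:
            raise ValueError(f"empty epoch [{start}, {stop})")
        if start < 0 or stop > m:
            raise ValueError(f"epoch [{start}, {stop}) out of range for {m} samples")
        if covered[start:stop].any():
            raise ValueError("epoch partition overlaps")
        covered[start:stop] = True
    if not covered.all():
        raise ValueError("epoch partition does not cover all samples")


def track_network(
    expression: ArrayLike,
    epoch_partition: Sequence[tuple[int, int]],
    config: TrackerConfig,
    sample_times: ArrayLike | None = None,
    gene_names: Sequence[str] | None = None,
    n_jobs: int = 1,
) -> dict[str, TimeVaryingNetwork]:
    """Infer time-varying networks from a genes x samples expression matrix.

    Expression rates are estimated by per-epoch finite differences (sample
    times default to ``0, 1, 2, ...``), the time axis is sliced by the epoch
    partition (0-based half-open ranges that must cover all samples
    disjointly), and each gene's incoming-edge vector is tracked
    independently across epochs.
    """
    E = np.atleast_2d(np.asarray(expression, dtype=float))
    p, m = E.shape
    if sample_times is None:
        sample_times = np.arange(m, dtype=float)
    partition = [(int(a), int(b)) for a, b in epoch_partition]
    _check_partition(partition, m)
    rates = compute_derivatives(E, sample_times, partition)
    epochs = [EpochData(E[:, a:b], rates[:, a:b]) for a, b in partition]
    return track_network_epochs(epochs, config, gene_names=gene_names, n_jobs=n_jobs)
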