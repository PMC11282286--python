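"""Unconstrained NMF demixing of raw fingerprint videos.

The video is reshaped to a pixels × frames matrix M and factorized as
M ≈ W·H with W, H ≥ 0 and no regularization, by minimizing the squared
Frobenius loss ½‖M − WH‖²_F. Columns of W are spatial fingerprints and rows
of H the corresponding time traces. Initialization is deterministic NNDSVD;
the primary solver is cyclic coordinate descent (HALS: each factor column/
row gets an exact nonnegatively-clipped least-squares update); a classical
multiplicative-update solver with provably non-increasing loss is kept as an
internal oracle. Excess rank produces replica fingerprints, which
``rank_scan`` exploits to estimate the true source count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .camera import VideoStack

__all__ = [
    "NMFConfig",
    "DemixResult",
    "reshape_video",
    "unreshape_matrix",
    "bin_pixels",
    "nndsvd_init",
    "nmf_fit",
    "demix_video",
    "rank_scan",
]


@dataclass(frozen=True)
class NMFConfig:
    """Solver configuration; defaults follow standard raw-video demixing
    practice (NNDSVD init, coordinate descent, max_iter 3000, seed 0, no
    regularization)."""

    rank: int = 2
    max_iter: int = 3000
    init: str = "nndsvd"
    solver: str = "cd"
    seed: int = 0
    tol: float = 1e-4
    alpha_W: float = 0.0
    alpha_H: float = 0.0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.init not in ("nndsvd", "random"):
            raise ValueError("init must be 'nndsvd' or 'random'")
        if self.solver not in ("cd", "mu"):
            raise ValueError("solver must be 'cd' (coordinate descent) or 'mu'")
        if self.alpha_W or self.alpha_H:
            raise NotImplementedError("regularized NMF is out of scope; keep alphas at 0")


@dataclass
class DemixResult:
    """NMF factors plus fit diagnostics.

    From :func:`nmf_fit`, ``spatial_components`` is (rank, pixels);
    :func:`demix_video` reshapes it to (rank, X, Y) images, max-normalizes
    each component to 1 and folds the scale into ``temporal_components``
    (rank, T), leaving the product reconstruction unchanged.
    """

    spatial_components: np.ndarray
    temporal_components: np.ndarray
    rank: int
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    config: NMFConfig | None = None

    @property
    def n_frames(self) -> int:
        return self.temporal_components.shape[1]

    def spatial_matrix(self) -> np.ndarray:
        """(pixels, rank) matrix view of the spatial components."""
        k = self.spatial_components.shape[0]
        return self.spatial_components.reshape(k, -1).T


def reshape_video(video: VideoStack | np.ndarray) -> np.ndarray:
    """Reshape a (T, X, Y) video into a (pixels, frames) float matrix.

    Column t is frame t flattened in row-major order; the exact inverse is
    :func:`unreshape_matrix` given the frame shape.
    """
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a nonempty (T, X, Y) video")
    T = frames.shape[0]
    return frames.reshape(T, -1).T.astype(float)


def unreshape_matrix(matrix: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`reshape_video`."""
    matrix = np.asarray(matrix)
    return matrix.T.reshape(-1, *frame_shape)


def bin_pixels(video: VideoStack, factor: int) -> VideoStack:
    """Spatially bin each frame by ``factor``, averaging factor×factor blocks.

    Averaging preserves the intensity scale. If ``factor`` does not divide a
    dimension, trailing rows/columns are cropped (with a warning).
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return video
    frames = np.asarray(video.frames, dtype=float)
    T, X, Y = frames.shape
    nx, ny = X // factor, Y // factor
    if nx == 0 or ny == 0:
        raise ValueError(f"bin factor {factor} exceeds frame size {X}x{Y}")
    if X % factor or Y % factor:
        warnings.warn(
            f"bin factor {factor} does not divide {X}x{Y}; cropping to {nx*factor}x{ny*factor}",
            stacklevel=2,
        )
        frames = frames[:, : nx * factor, : ny * factor]
    binned = frames.reshape(T, nx, factor, ny, factor).mean(axis=(2, 4))
    mask = None
    if video.saturation_mask is not None:
        m = video.saturation_mask[:, : nx * factor, : ny * factor]
        mask = m.reshape(T, nx, factor, ny, factor).any(axis=(2, 4))
    return VideoStack(
        frames=binned,
        bit_depth=None,  # averaged counts are no longer integers
        frame_rate=video.frame_rate,
        saturation_mask=mask,
    )


def nndsvd_init(
    matrix: np.ndarray, rank: int, svd_seed: int = 0, variant: str = "plain"
) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative Double Singular Value Decomposition.

    The leading singular triplet is nonnegative (Perron–Frobenius) and is
    kept directly; every subsequent singular pair is split into its positive
    and negative parts, and the part carrying more energy is retained and
    rescaled to preserve the singular value. The default "plain" variant
    leaves zeros as zeros (fully deterministic); variant "mean" fills zeros
    with the matrix mean (useful for multiplicative updates, which cannot
    leave the zero set).
    """
    if variant not in ("plain", "mean"):
        raise ValueError("variant must be 'plain' or 'mean'")
    M = np.asarray(matrix, dtype=float)
    if np.any(M < 0):
        raise ValueError("NNDSVD requires a nonnegative matrix")
    if not 1 <= rank <= min(M.shape):
        raise ValueError(f"rank must be in [1, {min(M.shape)}]")
    U, S, Vt = randomized_svd(M, n_components=rank, random_state=svd_seed)
    W = np.zeros((M.shape[0], rank))
    H = np.zeros((rank, M.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, rank):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        xpn, ypn = np.linalg.norm(xp), np.linalg.norm(yp)
        xnn, ynn = np.linalg.norm(xn), np.linalg.norm(yn)
        mp, mn = xpn * ypn, xnn * ynn
        if mp >= mn:
            u = xp / xpn if xpn > 0 else xp
            v = yp / ypn if ypn > 0 else yp
            sigma = mp
        else:
            u = xn / xnn if xnn > 0 else xn
            v = yn / ynn if ynn > 0 else yn
            sigma = mn
        W[:, j] = np.sqrt(S[j] * sigma) * u
        H[j, :] = np.sqrt(S[j] * sigma) * v
    if variant == "mean":
        fill = M.mean()
        W[W == 0] = fill
        H[H == 0] = fill
    return W, H


def _loss(norm_M2: float, M_Ht: np.ndarray, W: np.ndarray, HHt: np.ndarray) -> float:
    """½‖M − WH‖²_F via the trace expansion (no T×pixels temporary)."""
    cross = float(np.einsum("ik,ik->", W, M_Ht))
    quad = float(np.einsum("ik,kl,il->", W, HHt, W))
    return 0.5 * (norm_M2 - 2.0 * cross + quad)


def _hals_update(F: np.ndarray, G: np.ndarray, MGt: np.ndarray) -> None:
    """In-place HALS pass over the columns of F for ½‖M − F G‖²."""
    GGt = G @ G.T
    k = F.shape[1]
    for j in range(k):
        denom = GGt[j, j]
        if denom <= np.finfo(float).eps:
            continue
        grad = MGt[:, j] - F @ GGt[:, j]
        F[:, j] = np.maximum(F[:, j] + grad / denom, 0.0)


def nmf_fit(matrix: np.ndarray, config: NMFConfig) -> DemixResult:
    """Minimize ½‖M − WH‖²_F over W, H ≥ 0.

    Coordinate descent (``solver='cd'``) performs cyclic HALS block updates,
    W first then H; the multiplicative-update solver (``'mu'``) applies the
    classical Lee–Seung rules whose loss is monotonically non-increasing.
    Iteration stops at ``max_iter`` or when the relative per-iteration loss
    decrease falls below ``tol``. The per-iteration loss is recorded in
    ``loss_history`` (squared-Frobenius residuals, halved).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2D matrix")
    if np.any(np.isnan(M)):
        raise ValueError("input matrix contains NaN")
    if np.any(M < 0):
        raise ValueError("NMF requires a nonnegative matrix")
    if config.rank > min(M.shape):
        raise ValueError(f"rank {config.rank} exceeds min(matrix shape) = {min(M.shape)}")

    if config.init == "nndsvd":
        W, H = nndsvd_init(M, config.rank, svd_seed=0)
    else:
        rng = np.random.default_rng(config.seed)
        scale = math.sqrt(M.mean() / config.rank) if M.size else 1.0
        W = scale * np.abs(rng.standard_normal((M.shape[0], config.rank)))
        H = scale * np.abs(rng.standard_normal((config.rank, M.shape[1])))

    norm_M2 = float(np.einsum("ij,ij->", M, M))
    eps = np.finfo(float).eps
    losses: list[float] = []
    converged = False

    for _ in range(config.max_iter):
        if config.solver == "cd":
            MHt = M @ H.T
            _hals_update(W, H, MHt)
            WtM = W.T @ M
            Ht = H.T
            _hals_update(Ht, W.T, WtM.T)
            H = Ht.T
        else:  # multiplicative updates
            WtM = W.T @ M
            WtW = W.T @ W
            H *= WtM / np.maximum(WtW @ H, eps)
            MHt = M @ H.T
            HHt = H @ H.T
            W *= MHt / np.maximum(W @ HHt, eps)
        HHt = H @ H.T
        MHt = M @ H.T
        loss = _loss(norm_M2, MHt, W, HHt)
        losses.append(loss)
        if len(losses) > 1 and config.tol > 0:
            prev = losses[-2]
            if prev - loss <= config.tol * max(prev, eps):
                converged = True
                break

    return DemixResult(
        spatial_components=W.T.copy(),  # (rank, pixels); demix_video reshapes to images
        temporal_components=H.copy(),
        rank=config.rank,
        loss_history=np.asarray(losses),
        converged=converged,
        config=config,
    )


def _normalize_and_order(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalize spatial components, fold scale into H, order by
    decreasing temporal energy (ties by first nonzero pixel index)."""
    K = W.shape[0]
    W = W.copy()
    H = H.copy()
    for k in range(K):
        peak = W[k].max()
        if peak > 0:
            W[k] /= peak
            H[k] *= peak
    energy = (H**2).sum(axis=1)
    first_px = np.array(
        [int(np.argmax(W[k].ravel() > 0)) if W[k].any() else W[k].size for k in range(K)]
    )
    order = np.lexsort((first_px, -energy))
    return W[order], H[order]


def demix_video(
    video: VideoStack,
    config: NMFConfig,
    bin_factor: int = 1,
) -> DemixResult:
    """Demix a raw video: optional pixel binning, reshape, NMF.

    NMF is applied directly to the (binned) raw counts with no other
    pre-processing. The returned spatial components are reshaped to images
    and max-normalized to 1, with the scale folded into the temporal
    components (the product WH is unchanged); components are ordered by
    decreasing temporal energy.
    """
    binned = bin_pixels(video, bin_factor)
    matrix = reshape_video(binned)
    result = nmf_fit(matrix, config)
    shape = binned.frame_shape
    W = result.spatial_components.reshape(result.rank, -1)
    W, H = _normalize_and_order(W, result.temporal_components)
    result.spatial_components = W.reshape(result.rank, *shape)
    result.temporal_components = H
    return result


#: replica merging: spatial Pearson correlation above this is "the same source"
REPLICA_THRESHOLD = 0.9
#: components below this fraction of the strongest temporal energy are dropped
ENERGY_FLOOR = 0.01


def _unique_component_count(
    result: DemixResult, replica_threshold: float, energy_floor: float
) -> int:
    """Number of unique components after replica merging and energy gating.

    Replicas of one source can share its fingerprint (spatial correlation)
    or, when excess rank splits a fingerprint into spatially disjoint
    halves, its singular time trace (temporal correlation); a pair exceeding
    the threshold in either view is merged.
    """
    W = result.spatial_components.reshape(result.rank, -1)
    H = result.temporal_components
    energy = (H**2).sum(axis=1)
    if energy.max() <= 0:
        return 0
    keep = np.nonzero(energy >= energy_floor * energy.max())[0]
    if keep.size == 0:
        return 0
    Wk = W[keep].astype(float)
    Hk = H[keep].astype(float)
    valid = (Wk.std(axis=1) > 0) & (Hk.std(axis=1) > 0)
    Wk, Hk = Wk[valid], Hk[valid]
    n = Wk.shape[0]
    if n == 0:
        return 0
    corr_s = np.atleast_2d(np.corrcoef(Wk))
    corr_t = np.atleast_2d(np.corrcoef(Hk))
    # union-find style merge of replica pairs
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if corr_s[i, j] > replica_threshold or corr_t[i, j] > replica_threshold:
                parent[find(j)] = find(i)
    return len({find(i) for i in range(n)})


def rank_scan(
    video: VideoStack,
    rank_range,
    replica_threshold: float = REPLICA_THRESHOLD,
    energy_floor: float = ENERGY_FLOOR,
    bin_factor: int = 1,
    max_iter: int = 3000,
    tol: float = 1e-4,
) -> tuple[dict[int, DemixResult], int]:
    """Fit NMF over a range of ranks and estimate the source count.

    Above the true source count, extra components are replicas of existing
    fingerprints (or near-silent), so the unique-component count plateaus;
    the estimate is the most frequent plateau value, ties broken toward the
    value observed at the largest ranks.
    """
    ranks = [int(r) for r in rank_range]
    if not ranks:
        raise ValueError("rank_range must be nonempty")
    results: dict[int, DemixResult] = {}
    counts: dict[int, int] = {}
    for r in ranks:
        res = demix_video(video, NMFConfig(rank=r, max_iter=max_iter, tol=tol), bin_factor)
        results[r] = res
        counts[r] = _unique_component_count(res, replica_threshold, energy_floor)
    values = [counts[r] for r in sorted(ranks)]
    best, best_score = values[-1], -1.0
    for v in set(values):
        # frequency, then recency (how late in the scan the value appears)
        score = values.count(v) + 0.5 * (max(i for i, x in enumerate(values) if x == v) / len(values))
        if score > best_score:
            best, best_score = v, score
    return results, int(best)
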