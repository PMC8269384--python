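"""PCA on single spectral blocks and consensus PCA across blocks.

Consensus PCA (CPCA) analyzes two or more row-aligned data blocks at once.
Each centered block is scaled by an inverse root-mean-square factor that
equalizes the blocks' total sums of squares (normalized so the average
block keeps its magnitude — with a single block the scaling is exactly 1);
the global model is an ordinary PCA of the column-concatenated scaled
super-matrix.  Per component, the block loading is the global loading
restricted to a block's columns renormalized to unit length, the block
scores are the scaled block matrix projected on that loading, and a block's
contribution is the squared norm of its global-loading segment — how much
of the consensus direction lives in that block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DesignError
from .spectra_io import SpectraSet

__all__ = ["PCAModel", "CPCAModel", "fit_pca", "fit_cpca"]


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # (k, p), orthonormal rows
    scores: np.ndarray  # (n, k)
    explained_variance_pct: np.ndarray  # (k,), of total variance

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings + self.mean


@dataclass
class CPCAModel:
    block_labels: list[str]
    block_weights: np.ndarray
    mean: np.ndarray  # concatenated-column mean (of scaled blocks)
    global_scores: np.ndarray
    global_loadings: np.ndarray
    block_scores: dict[str, np.ndarray]
    block_loadings: dict[str, np.ndarray]
    #: (k, n_blocks) percentage of each global loading's squared norm per block
    block_contrib_pct: np.ndarray
    explained_variance_pct: np.ndarray


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: largest-|loading| element positive."""
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def _pca(X: np.ndarray, n_components: int):
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise DesignError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    expl = 100.0 * (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].copy()
    scores = scores.copy()
    _fix_signs(loadings, scores)
    return mean, loadings, scores, expl


def fit_pca(sset: SpectraSet | np.ndarray, n_components: int) -> PCAModel:
    """PCA of a mean-centered spectral matrix via SVD.

    Explained variances are percentages of the total variance; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    X = sset.matrix if isinstance(sset, SpectraSet) else np.asarray(sset, dtype=float)
    mean, loadings, scores, expl = _pca(X, n_components)
    return PCAModel(mean, loadings, scores, expl)


def fit_cpca(
    blocks: list[SpectraSet],
    n_components: int,
    labels: list[str] | None = None,
) -> CPCAModel:
    """Consensus PCA of row-aligned blocks (see module docstring).

    Blocks must have identical sample ordering — typically both blocks after
    technical-replicate averaging.  Results are invariant to block ordering
    and, up to a common scale on the scores, to multiplying any block's
    intensities by a constant.
    """
    if not blocks:
        raise AlignmentError("no blocks given")
    labels = labels or [str(b.meta["block"].iloc[0]) for b in blocks]
    n = blocks[0].n_samples
    ref_ids = blocks[0].bio_ids().tolist()
    for b, lab in zip(blocks[1:], labels[1:]):
        if b.n_samples != n:
            raise AlignmentError(
                f"block {lab!r} has {b.n_samples} rows, expected {n}"
            )
        ids = b.bio_ids().tolist()
        if ids != ref_ids:
            first = next(i for i, (x, y) in enumerate(zip(ref_ids, ids)) if x != y)
            raise AlignmentError(
                f"blocks row-misaligned at row {first}: "
                f"{ref_ids[first]!r} vs {ids[first]!r}"
            )

    centered = [b.matrix - b.matrix.mean(axis=0) for b in blocks]
    ss = np.array([float((Xc**2).sum()) for Xc in centered])
    if np.any(ss == 0):
        raise DesignError("a block has zero total sum of squares")
    # equal-SS weighting, normalized so the average block keeps its scale
    weights = np.sqrt(ss.mean() / ss)
    scaled = [w * Xc for w, Xc in zip(weights, centered)]
    X = np.hstack(scaled)

    mean = np.zeros(X.shape[1])
    _, loadings, scores, expl = _pca(X, n_components)

    edges = np.cumsum([0] + [b.n_points for b in blocks])
    block_loadings: dict[str, np.ndarray] = {}
    block_scores: dict[str, np.ndarray] = {}
    contrib = np.empty((n_components, len(blocks)))
    for bi, lab in enumerate(labels):
        seg = loadings[:, edges[bi]:edges[bi + 1]]
        norms = np.linalg.norm(seg, axis=1)
        contrib[:, bi] = 100.0 * norms**2
        with np.errstate(invalid="ignore", divide="ignore"):
            bl = np.where(norms[:, None] > 0, seg / norms[:, None], 0.0)
        block_loadings[lab] = bl
        block_scores[lab] = scaled[bi] @ bl.T
    return CPCAModel(
        block_labels=list(labels),
        block_weights=weights,
        mean=mean,
        global_scores=scores,
        global_loadings=loadings,
        block_scores=block_scores,
        block_loadings=block_loadings,
        block_contrib_pct=contrib,
        explained_variance_pct=expl,
    )
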