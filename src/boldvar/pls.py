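"""Partial least squares correlation (PLSC) for two-block brain-behavior data.

Two model families are implemented:

* **Mean-centered (group-comparison) PLS** decomposes the matrix of
  within-group column means expressed as deviations from the grand mean.
  Its latent variables are group contrasts over elements (voxels or
  behavioral variables).

* **Behavioral PLS** decomposes the matrix of within-group Pearson
  correlations between each element column and each behavioral variable,
  stacked group-major.  Its latent variables are brain-behavior
  correlation patterns.

Inference uses permutation tests on the singular values and stratified
bootstrap resampling of subjects within group, with orthogonal Procrustes
alignment of the resampled singular vectors to the point estimate so that
axis reflections and rotations do not inflate the bootstrap standard
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes


class PLSError(ValueError):
    pass


# ---------------------------------------------------------------------------
# data containers


@dataclass
class GroupedDataBlock:
    """Subjects-by-elements data with a two-level group label per subject."""

    X: np.ndarray  # (n_subjects, n_elements)
    group: np.ndarray  # (n_subjects,) labels, exactly two levels
    element_ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.group = np.asarray(self.group)
        if self.X.ndim != 2:
            raise PLSError("X must be 2-D (subjects x elements)")
        if self.group.shape[0] != self.X.shape[0]:
            raise PLSError("group labels must match number of subjects")
        if not np.all(np.isfinite(self.X)):
            raise PLSError("X contains non-finite values")
        levels, counts = np.unique(self.group, return_counts=True)
        if len(levels) < 2:
            raise PLSError("need two groups; got a single level")
        if len(levels) > 2:
            raise PLSError(f"more than two group levels: {list(levels)}")
        if counts.min() < 2:
            raise PLSError("each group needs at least 2 subjects")

    @property
    def levels(self) -> np.ndarray:
        """Group levels in order of first appearance (stable row ordering)."""
        _, idx = np.unique(self.group, return_index=True)
        return self.group[np.sort(idx)]


@dataclass
class BehaviorBlock:
    """Subjects-by-behaviors data aligned row-wise with a GroupedDataBlock."""

    Y: np.ndarray
    behavior_names: list | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if not np.all(np.isfinite(self.Y)):
            raise PLSError("Y contains non-finite values")


@dataclass
class LatentDecomposition:
    """SVD of the PLS cross-block matrix.

    ``V @ diag(S) @ U.T`` reconstructs the decomposed matrix: ``V`` holds the
    design/behavior saliences (one row per row of the input matrix), ``U``
    the element saliences (one row per element column).
    """

    U: np.ndarray  # (n_elements, n_lv) element saliences
    S: np.ndarray  # (n_lv,) singular values, non-increasing
    V: np.ndarray  # (n_rows, n_lv) design / behavior saliences
    covariance_fraction: np.ndarray
    model_kind: str  # {"mean_centered", "behavioral"}
    row_labels: list | None = None

    @property
    def n_lv(self) -> int:
        return len(self.S)

    def reconstruct(self) -> np.ndarray:
        return self.V @ np.diag(self.S) @ self.U.T


@dataclass
class ResamplingResult:
    permutation_p: np.ndarray  # per LV
    bootstrap_se_u: np.ndarray  # (n_elements, n_lv)
    bootstrap_se_v: np.ndarray  # (n_rows, n_lv)
    bootstrap_ratio: np.ndarray  # U / SE(U), +-inf sentinel where SE ~ 0
    unstable_se: np.ndarray  # bool mask where SE(U) < tolerance
    ci_low: np.ndarray  # (n_rows, n_lv) percentile CI of V saliences
    ci_high: np.ndarray
    n_permutations: int
    n_bootstraps: int
    seed: int | None
    ci_level: float = 0.95
    bootstrap_ratio_v: np.ndarray | None = None


@dataclass
class BrainScores:
    scores: np.ndarray  # (n_subjects, n_lv)
    group: np.ndarray


@dataclass
class PLSResult:
    """Bundle of decomposition, resampling inference and brain scores."""

    decomposition: LatentDecomposition
    resampling: ResamplingResult
    brain_scores: BrainScores | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model matrices


def group_mean_center(block: GroupedDataBlock) -> np.ndarray:
    """Within-group column means deviated from the grand column mean.

    Returns the (n_groups x n_elements) matrix M_dev whose SVD yields the
    group-comparison latent variables.  With equal group sizes its rows sum
    to zero columnwise.
    """
    grand = block.X.mean(axis=0)
    rows = [block.X[block.group == g].mean(axis=0) - grand for g in block.levels]
    return np.vstack(rows)


def _zscore_cols(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (A - mu) / safe, sd


def stack_correlations(block: GroupedDataBlock, behavior: BehaviorBlock,
                       strict: bool = True) -> np.ndarray:
    """Within-group element-behavior Pearson correlations, stacked group-major.

    Row ordering is group-major then behavior: all behaviors of the first
    group, then all behaviors of the second.  Elements with zero variance
    within a group carry no signal there and get correlation 0 (with a
    warning) so that voxel indexing stays stable.
    """
    if behavior.Y.shape[0] != block.X.shape[0]:
        raise PLSError("behavior block and data block must share subject order")
    rows = []
    for g in block.levels:
        sel = block.group == g
        Xg, sdx = _zscore_cols(block.X[sel])
        Yg, sdy = _zscore_cols(behavior.Y[sel])
        if np.any(sdy == 0):
            if strict:
                raise PLSError(f"zero-variance behavior within group {g!r}")
            Yg[:, sdy == 0] = 0.0  # degenerate resample: carries no signal
        n = sel.sum()
        R = Yg.T @ Xg / n
        if np.any(sdx == 0):
            warnings.warn(
                f"{int((sdx == 0).sum())} zero-variance element(s) in group {g!r}; "
                "correlations set to 0",
                stacklevel=2,
            )
            R[:, sdx == 0] = 0.0
        rows.append(R)
    return np.vstack(rows)


def svd_lv(M: np.ndarray, model_kind: str = "behavioral",
           row_labels: list | None = None) -> LatentDecomposition:
    """Thin SVD of the cross-block matrix with a deterministic sign convention.

    For each latent variable the design/behavior salience entry of largest
    magnitude is made positive; element saliences are flipped along with it
    so the reconstruction is unchanged.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise PLSError("cannot decompose a matrix with non-finite entries")
    W, S, Zt = np.linalg.svd(M, full_matrices=False)
    U = Zt.T  # element saliences
    V = W  # design / behavior saliences
    for k in range(len(S)):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    total = float(np.sum(S**2))
    frac = S**2 / total if total > 0 else np.zeros_like(S)
    return LatentDecomposition(U=U, S=S, V=V, covariance_fraction=frac,
                               model_kind=model_kind, row_labels=row_labels)


def _build_matrix(X: np.ndarray, block: GroupedDataBlock,
                  behavior: BehaviorBlock | None) -> np.ndarray:
    """Rebuild the model matrix for (possibly permuted/resampled) data."""
    b = GroupedDataBlock.__new__(GroupedDataBlock)
    b.X = X
    b.group = block.group
    b.element_ids = block.element_ids
    if behavior is None:
        return group_mean_center(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stack_correlations(b, behavior, strict=False)


# ---------------------------------------------------------------------------
# resampling inference


def permutation_test(block: GroupedDataBlock, behavior: BehaviorBlock | None,
                     observed_S: np.ndarray, n_perm: int = 1000,
                     seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Permutation p-value per latent variable.

    Subject rows of X are shuffled relative to the group labels (and to the
    behavior rows for the behavioral model), the model matrix is rebuilt and
    decomposed, and same-index singular values are compared.  The add-one
    convention p = (1 + #{S_perm >= S_obs}) / (1 + n_perm) avoids zero
    p-values at finite permutation counts.
    """
    if n_perm < 1:
        raise PLSError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = block.X.shape[0]
    count = np.zeros(len(observed_S))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        M = _build_matrix(block.X[perm], block, behavior)
        Sp = np.linalg.svd(M, compute_uv=False)
        k = min(len(Sp), len(observed_S))
        count[:k] += Sp[:k] >= observed_S[:k]
    return (1.0 + count) / (1.0 + n_perm)


def bootstrap_saliences(block: GroupedDataBlock, behavior: BehaviorBlock | None,
                        decomp: LatentDecomposition, n_boot: int = 1000,
                        seed: int | np.random.Generator | None = None,
                        ci_level: float = 0.95, procrustes: bool = True,
                        se_tol: float = 1e-12):
    """Stratified bootstrap of the singular vectors.

    Subjects are resampled with replacement within their own group, the
    model is rebuilt and decomposed, and the resampled singular vectors are
    aligned to the originals by a single orthogonal Procrustes rotation of
    the stacked [U_b; V_b] onto the stacked originals (the thin SVD makes
    one of the two blocks square orthogonal on its own, which would align
    perfectly and erase all bootstrap variability).  Standard errors are
    bootstrap SDs; bootstrap ratios divide the original element saliences by
    their SE, with an infinite sentinel (flagged, never a silent division)
    where the SE collapses below ``se_tol``.  Percentile confidence
    intervals are formed on the design/behavior saliences.
    """
    if n_boot < 2:
        raise PLSError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    idx_by_group = [np.flatnonzero(block.group == g) for g in block.levels]
    n_lv = decomp.n_lv
    Us = np.empty((n_boot, *decomp.U.shape))
    Vs = np.empty((n_boot, *decomp.V.shape))
    for b in range(n_boot):
        take = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                               for ix in idx_by_group])
        Xb = block.X[take]
        bb = GroupedDataBlock.__new__(GroupedDataBlock)
        bb.X = Xb
        bb.group = np.concatenate([block.group[ix] for ix in idx_by_group])
        bb.element_ids = block.element_ids
        Yb = None
        if behavior is not None:
            Yb = BehaviorBlock.__new__(BehaviorBlock)
            Yb.Y = behavior.Y[take]
            Yb.behavior_names = behavior.behavior_names
        M = _build_matrix(Xb, bb, Yb)
        d = svd_lv(M, decomp.model_kind)
        Ub, Vb = d.U[:, :n_lv], d.V[:, :n_lv]
        if procrustes:
            Q, _ = orthogonal_procrustes(np.vstack([Ub, Vb]),
                                         np.vstack([decomp.U, decomp.V]))
            Ub = Ub @ Q
            Vb = Vb @ Q
        Us[b] = Ub
        Vs[b] = Vb
    se_u = Us.std(axis=0, ddof=1)
    se_v = Vs.std(axis=0, ddof=1)
    unstable = se_u < se_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(unstable, np.sign(decomp.U) * np.inf, decomp.U / np.where(unstable, 1.0, se_u))
        unstable_v = se_v < se_tol
        bsr_v = np.where(unstable_v, np.sign(decomp.V) * np.inf,
                         decomp.V / np.where(unstable_v, 1.0, se_v))
    if np.any(unstable):
        warnings.warn(f"{int(unstable.sum())} bootstrap SE(s) below {se_tol}; "
                      "bootstrap ratios reported as +-inf", stacklevel=2)
    alpha = (1.0 - ci_level) / 2.0
    ci_low = np.percentile(Vs, 100 * alpha, axis=0)
    ci_high = np.percentile(Vs, 100 * (1 - alpha), axis=0)
    return se_u, se_v, bsr, bsr_v, unstable, ci_low, ci_high


def brain_scores(block: GroupedDataBlock, decomp: LatentDecomposition) -> BrainScores:
    """Project each subject onto the element saliences: scores = X @ U.

    X is used exactly as analyzed by the model; no additional centering is
    applied here.
    """
    if block.X.shape[1] != decomp.U.shape[0]:
        raise PLSError(
            f"element count mismatch: X has {block.X.shape[1]} columns, "
            f"U has {decomp.U.shape[0]} rows")
    return BrainScores(scores=block.X @ decomp.U, group=block.group.copy())


# ---------------------------------------------------------------------------
# high-level model wrappers


def _row_labels(levels, behavior: BehaviorBlock | None):
    if behavior is None:
        return [str(g) for g in levels]
    names = behavior.behavior_names or [f"b{j}" for j in range(behavior.Y.shape[1])]
    return [f"{g}:{b}" for g in levels for b in names]


def mean_centered_pls(block: GroupedDataBlock, n_perm: int = 1000,
                      n_boot: int = 1000, seed: int | None = None,
                      ci_level: float = 0.95, procrustes: bool = True) -> PLSResult:
    """Group-comparison PLS with permutation and bootstrap inference."""
    rng = np.random.default_rng(seed)
    M = group_mean_center(block)
    decomp = svd_lv(M, "mean_centered", _row_labels(block.levels, None))
    p = permutation_test(block, None, decomp.S, n_perm, rng)
    se_u, se_v, bsr, bsr_v, unstable, lo, hi = bootstrap_saliences(
        block, None, decomp, n_boot, rng, ci_level, procrustes)
    res = ResamplingResult(p, se_u, se_v, bsr, unstable, lo, hi,
                           n_perm, n_boot, seed, ci_level, bsr_v)
    scores = brain_scores(block, decomp)
    return PLSResult(decomp, res, scores)


def behavioral_pls(block: GroupedDataBlock, behavior: BehaviorBlock,
                   n_perm: int = 1000, n_boot: int = 1000,
                   seed: int | None = None, ci_level: float = 0.95,
                   procrustes: bool = True) -> PLSResult:
    """Behavioral PLS on stacked within-group correlations.

    Brain scores are computed from the within-group z-scored element data
    (the representation the correlation model analyzes).
    """
    for g in np.unique(block.group):
        if np.any(behavior.Y[block.group == g].std(axis=0) == 0):
            raise PLSError(f"zero-variance behavior within group {g!r}")
    rng = np.random.default_rng(seed)
    M = stack_correlations(block, behavior)
    decomp = svd_lv(M, "behavioral", _row_labels(block.levels, behavior))
    p = permutation_test(block, behavior, decomp.S, n_perm, rng)
    se_u, se_v, bsr, bsr_v, unstable, lo, hi = bootstrap_saliences(
        block, behavior, decomp, n_boot, rng, ci_level, procrustes)
    res = ResamplingResult(p, se_u, se_v, bsr, unstable, lo, hi,
                           n_perm, n_boot, seed, ci_level, bsr_v)
    Xz = np.empty_like(block.X)
    for g in block.levels:
        sel = block.group == g
        Xz[sel], _ = _zscore_cols(block.X[sel])
    zblock = GroupedDataBlock(Xz, block.group, block.element_ids)
    scores = brain_scores(zblock, decomp)
    return PLSResult(decomp, res, scores)
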