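"""Reduction of a 14-test neuropsychological battery to factor scores.

Pipeline: orient all tests so higher = better, transform significantly
skewed columns (square root, falling back to log10; negatively skewed
columns are reflected first), run PCA on the correlation matrix, pick the
number of components at the scree elbow, check near-orthogonality with an
oblique (oblimin) rotation, and finish with a varimax rotation and
regression-method factor scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class FactorError(ValueError):
    pass


#: Canonical subtest names of the battery, in fixed column order.
TEST_NAMES = [
    "RCFT immediate recall",
    "RCFT delayed recall",
    "VOSP silhouettes",
    "VOSP progressive silhouettes",
    "WASI block design",
    "TMT A",
    "TMT B",
    "Digit span forward",
    "Digit span backward",
    "WMS immediate recall",
    "WMS delayed recall",
    "WASI matrix reasoning",
    "WASI vocabulary",
    "WASI similarity",
]

#: Timed tests where a lower raw score means better performance.
LOWER_BETTER = {"TMT A", "TMT B"}

FACTOR_NAMES = ["visuospatial", "control_speed", "memory", "intelligence"]

#: Reference varimax loading pattern of the battery on its four factors
#: (visuospatial, cognitive control/speed, memory, intelligence).  Used as
#: the generative default for synthetic batteries and as a recovery target.
REFERENCE_LOADINGS = np.array([
    [0.87, -0.03, 0.06, 0.13],
    [0.84, -0.01, 0.08, 0.24],
    [0.58, 0.13, 0.00, 0.23],
    [0.69, 0.23, -0.09, 0.20],
    [0.53, 0.16, 0.37, 0.53],
    [0.46, 0.54, 0.11, -0.14],
    [0.41, 0.69, 0.30, 0.18],
    [-0.31, 0.72, -0.13, 0.18],
    [0.08, 0.79, 0.21, 0.08],
    [-0.08, 0.20, 0.85, 0.28],
    [0.09, 0.05, 0.88, -0.02],
    [0.36, 0.60, 0.06, 0.42],
    [0.24, 0.19, 0.15, 0.83],
    [0.24, 0.08, 0.05, 0.80],
])


# ---------------------------------------------------------------------------
# containers


@dataclass
class BatteryMatrix:
    scores: pd.DataFrame  # subjects x tests
    direction: dict  # test name -> "higher_better" | "lower_better"

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            bad = self.scores.index[self.scores.isna().any(axis=1)].tolist()
            raise FactorError(f"battery rows with missing entries: {bad}")
        for t in self.scores.columns:
            self.direction.setdefault(t, "higher_better")


@dataclass
class ColumnTransform:
    """One column's recorded transform, re-applicable bit-for-bit."""

    kind: str  # none | sqrt | log10 | reflect+sqrt | reflect+log10
    shift: float = 0.0  # added before sqrt/log
    reflect_base: float = 0.0  # column max+min used for reflection
    skew_p_before: float = float("nan")
    skew_p_after: float = float("nan")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        reflected = self.kind.startswith("reflect")
        if reflected:
            x = self.reflect_base - x
        if self.kind.endswith("sqrt"):
            y = np.sqrt(x + self.shift)
        elif self.kind.endswith("log10"):
            y = np.log10(x + self.shift)
        else:
            return x
        # a reflected transform is order-reversing; negate so the column
        # keeps its higher-is-better orientation
        return -y if reflected else y


@dataclass
class TransformRecord:
    per_test: dict = field(default_factory=dict)  # test name -> ColumnTransform


@dataclass
class FactorSolution:
    n_factors: int
    loadings: np.ndarray  # tests x factors
    factor_scores: np.ndarray  # subjects x factors, mean 0 per factor
    variance_proportions: np.ndarray
    factor_correlations: np.ndarray
    rotation: str  # {"none", "oblique", "varimax"}
    test_names: list = field(default_factory=list)
    factor_names: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# orientation and transforms


def orient_scores(battery: BatteryMatrix) -> BatteryMatrix:
    """Reflect lower-is-better columns so higher scores always mean better.

    Reflection uses (max + min) - x, which keeps the column in its original
    positive range while exactly reversing the rank order.
    """
    out = battery.scores.copy()
    direction = {}
    for t in out.columns:
        if battery.direction.get(t) == "lower_better":
            col = out[t].to_numpy(dtype=float)
            out[t] = (col.max() + col.min()) - col
        direction[t] = "higher_better"
    return BatteryMatrix(out, direction)


def _skew_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float("nan")
    return float(stats.skewtest(x).pvalue)


def transform_if_skewed(battery: BatteryMatrix, alpha: float = 0.05
                        ) -> tuple[BatteryMatrix, TransformRecord]:
    """Square-root (falling back to log10) transform of significantly
    skewed columns.

    Skewness is tested with D'Agostino's test.  Positively skewed columns
    are shifted to be non-negative and square-rooted; if still skewed the
    (shifted) column is log10-transformed instead.  Negative skew is
    handled by reflecting the column first.  Constant columns are left
    untouched with a warning.  Every choice is recorded so the transform
    can be replayed exactly on new data.
    """
    out = battery.scores.copy()
    record = TransformRecord()
    for t in out.columns:
        x = out[t].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"column {t!r} is constant; skewness undefined, "
                          "no transform", stacklevel=2)
            record.per_test[t] = ColumnTransform("none")
            continue
        p0 = _skew_p(x)
        if p0 >= alpha:
            record.per_test[t] = ColumnTransform("none", skew_p_before=p0)
            continue
        negative = stats.skew(x) < 0
        prefix = "reflect+" if negative else ""
        base = float(x.max() + x.min()) if negative else 0.0
        work = base - x if negative else x
        shift_sqrt = float(max(0.0, -work.min()))
        shift_log = float(-work.min() + 1.0)
        # try sqrt first, fall back to log10; keep a transform only if it
        # actually improves the skew over the untransformed column
        candidates = [ColumnTransform(prefix + "sqrt", shift_sqrt, base, p0),
                      ColumnTransform(prefix + "log10", shift_log, base, p0)]
        chosen = ColumnTransform("none", skew_p_before=p0, skew_p_after=p0)
        y = x
        for cand in candidates:
            yc = cand.apply(x)
            if not np.all(np.isfinite(yc)):
                raise FactorError(
                    f"non-finite values after {cand.kind} transform of {t!r}")
            pc = _skew_p(yc)
            cand.skew_p_after = pc
            if not np.isnan(pc) and pc > chosen.skew_p_after:
                chosen, y = cand, yc
            if not np.isnan(pc) and pc >= alpha:
                break  # sqrt already resolved the skew
        record.per_test[t] = chosen
        out[t] = y
    return BatteryMatrix(out, dict(battery.direction)), record


# ---------------------------------------------------------------------------
# component count


def scree_select(eigenvalues: np.ndarray) -> int:
    """Number of components before the scree-plot elbow.

    The elbow is operationalized as the interior eigenvalue lying furthest
    below the chord joining the first and last eigenvalues; the components
    before it are retained.  Ties break toward fewer components.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if e.size < 3:
        raise FactorError("need at least 3 eigenvalues for a scree decision")
    if np.any(e <= 0) or np.any(np.diff(e) > 1e-10):
        raise FactorError("eigenvalues must be positive and non-increasing")
    k = np.arange(e.size)
    chord = e[0] + (e[-1] - e[0]) * k / (e.size - 1)
    below = chord - e
    elbow = int(np.argmax(below[1:-1])) + 1  # argmax takes the first maximum
    return elbow


# ---------------------------------------------------------------------------
# rotations


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (SVD-based iteration), Kaiser row-normalized by default.

    Returns (rotated loadings, rotation matrix).
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k == 1:
        return A.copy(), np.eye(1)
    if kaiser_normalize:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        An = A / h[:, None]
    else:
        h = None
        An = A
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = An @ R
        u, s, vt = np.linalg.svd(
            An.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    L = An @ R
    if h is not None:
        L = L * h[:, None]
    return L, R


def _quartimin_grad(L: np.ndarray) -> tuple[float, np.ndarray]:
    k = L.shape[1]
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    G = L * (L2 @ N)
    f = float((L2 * (L2 @ N)).sum()) / 4.0
    return f, G


def oblimin(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-6
            ) -> tuple[np.ndarray, np.ndarray]:
    """Direct quartimin (oblimin, gamma = 0) rotation by gradient projection.

    Returns (pattern loadings, factor correlation matrix Phi).
    """
    A = np.asarray(loadings, dtype=float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.eye(1)
    T = np.eye(k)
    L = A @ np.linalg.inv(T).T
    f, Gq = _quartimin_grad(L)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.diag(T.T @ G))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(40):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            L = A @ np.linalg.inv(X).T
            f_new, Gq = _quartimin_grad(L)
            if f_new < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = X
        f = f_new
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi


# ---------------------------------------------------------------------------
# extraction


def extract_and_rotate(battery: BatteryMatrix, n_factors: int,
                       rotation: str = "varimax",
                       kaiser_normalize: bool = True) -> FactorSolution:
    """Correlation-matrix PCA with the requested rotation and regression
    (Thurstone) factor scores.

    The loadings sign convention makes each factor's largest-magnitude
    loading positive, so solutions are stable across seeds and runs.
    """
    X = battery.scores.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 * n_factors:
        raise FactorError("need at least 2 subjects per extracted factor")
    R = np.corrcoef(X, rowvar=False)
    Rabs = np.abs(R - np.eye(p))
    if Rabs.max() > 0.999:
        # duplicated / collinear tests make the solution meaningless
        i, j = np.unravel_index(np.argmax(Rabs), Rabs.shape)
        names = list(battery.scores.columns)
        raise FactorError("singular correlation matrix; collinear "
                          f"columns: {names[i]!r}, {names[j]!r}")
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[n_factors - 1] < 1e-10:
        raise FactorError(f"correlation matrix supports fewer than "
                          f"{n_factors} components")
    A = V[:, :n_factors] * np.sqrt(w[:n_factors])

    Phi = np.eye(n_factors)
    if rotation == "varimax":
        L, _ = varimax(A, kaiser_normalize=kaiser_normalize)
    elif rotation == "oblique":
        L, Phi = oblimin(A)
    elif rotation == "none":
        L = A.copy()
    else:
        raise FactorError(f"unknown rotation {rotation!r}")

    # sign convention: largest |loading| per factor is positive
    flip = np.ones(n_factors)
    for k in range(n_factors):
        j = np.argmax(np.abs(L[:, k]))
        if L[j, k] < 0:
            flip[k] = -1.0
    L = L * flip
    Phi = Phi * np.outer(flip, flip)

    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    # pseudo-inverse tolerates the rank deficiency of small-n batteries
    Rinv = np.linalg.pinv(R, rcond=1e-10, hermitian=True)
    structure = L @ Phi  # equals L when orthogonal
    scores = Z @ Rinv @ structure
    var_prop = (structure * L).sum(axis=0) / p

    return FactorSolution(
        n_factors=n_factors, loadings=L, factor_scores=scores,
        variance_proportions=var_prop, factor_correlations=Phi,
        rotation=rotation, test_names=list(battery.scores.columns),
        factor_names=FACTOR_NAMES[:n_factors] if p == len(TEST_NAMES) else
        [f"factor{k + 1}" for k in range(n_factors)])


def oblique_orthogonality_check(solution: FactorSolution,
                                threshold: float = 0.32) -> str:
    """Decide whether an orthogonal rotation is appropriate.

    If no off-diagonal factor correlation of the oblique solution exceeds
    the threshold in magnitude (< ~10% shared variance), the solution is
    nearly orthogonal and varimax is used.
    """
    Phi = solution.factor_correlations
    off = np.abs(Phi - np.diag(np.diag(Phi)))
    return "use_orthogonal" if off.max() <= threshold else "keep_oblique"


def factor_pipeline(scores: pd.DataFrame, direction: dict | None = None,
                    n_factors: int | None = None,
                    orthogonality_threshold: float = 0.32):
    """Full battery reduction: orient, transform, scree, oblique check, rotate.

    Returns (FactorSolution, TransformRecord, scree eigenvalues).  If the
    oblique factor correlations exceed the orthogonality threshold the
    oblique solution itself is returned instead of the varimax one.
    """
    direction = dict(direction or {t: "lower_better" if t in LOWER_BETTER
                                   else "higher_better" for t in scores.columns})
    battery = BatteryMatrix(scores, direction)
    battery = orient_scores(battery)
    battery, record = transform_if_skewed(battery)
    X = battery.scores.to_numpy(dtype=float)
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    eig = eig[eig > 1e-8]  # null eigenvalues (n < p) carry no scree information
    if n_factors is None:
        n_factors = min(scree_select(eig), X.shape[0] // 2)
    oblique = extract_and_rotate(battery, n_factors, rotation="oblique")
    decision = oblique_orthogonality_check(oblique, orthogonality_threshold)
    if decision == "use_orthogonal":
        solution = extract_and_rotate(battery, n_factors, rotation="varimax")
    else:
        solution = oblique
    return solution, record, eig


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-factor Tucker congruence between two loading matrices.

    Columns of B are greedily matched to columns of A by absolute
    congruence; returns the matched |phi| per factor of A.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    C = np.abs(A.T @ B) / np.outer(np.linalg.norm(A, axis=0),
                                   np.linalg.norm(B, axis=0))
    out = np.empty(A.shape[1])
    used: set = set()
    for i in np.argsort(-C.max(axis=1)):  # most confident matches first
        j_order = np.argsort(-C[i])
        j = next(j for j in j_order if j not in used)
        used.add(j)
        out[i] = C[i, j]
    return out
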