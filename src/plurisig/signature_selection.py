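"""Step 2: L1-penalized logistic feature selection over resampled gene sets.

Known pluripotency genes (the positive class) are paired with an equal
number of randomly drawn non-pluripotency genes; an L1-penalized
("lasso") logistic regression is fit to the Z-scored promoter features
of each balanced set, with the penalty weight chosen by inner
cross-validation on held-out binomial deviance.  The procedure repeats
over many resampled negative sets and the per-column selection
frequencies and coefficient signs are aggregated into a signature.

The solver is a glmnet-style iteratively reweighted least squares with
inner coordinate descent and warm starts along a descending lambda
path, compiled with numba.  The objective is

    (1/n) * sum_i log(1 + exp(-t_i * (x_i . w + b))) + lambda * ||w||_1

with t in {-1, +1} and an unpenalized intercept.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .peak_io import FeatureColumn, FeatureMatrix

logger = logging.getLogger(__name__)

SCOPES = ("epigenetic", "protein_binding", "combined", "combined_expression")

#: Objective decrease between outer reweighting steps below which a
#: lambda is declared converged.
OBJECTIVE_TOL = 1e-7
#: Max coefficient change below which an inner CD pass is converged.
INNER_TOL = 1e-6
MAX_OUTER = 100
MAX_INNER = 1000

#: Default lambda path: log-spaced points from just above lambda_max
#: (where no feature enters) down to lambda_max * LAMBDA_MIN_RATIO.
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-2

#: Default inner CV folds for choosing lambda.
DEFAULT_INNER_FOLDS = 5


# ---------------------------------------------------------------------------
# Resample plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResamplePlan:
    """Balanced positive/negative gene sets for every resample."""

    positives: frozenset[str]
    n_resamples: int
    master_seed: int
    negative_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if len(self.negative_sets) != self.n_resamples:
            raise ValueError("negative_sets length must equal n_resamples")
        for i, neg in enumerate(self.negative_sets):
            if len(neg) != len(self.positives):
                raise ValueError(f"resample {i}: negative set size != |positives|")
            if neg & self.positives:
                raise ValueError(f"resample {i}: negatives overlap positives")


def make_resample_plan(
    positives: set[str],
    universe: set[str],
    n_resamples: int = 500,
    master_seed: int = 0,
) -> ResamplePlan:
    """Draw ``n_resamples`` negative sets of size |positives| without
    replacement from ``universe - positives``; resample *r* uses the seed
    sequence ``(master_seed, r)`` so any resample is reproducible in
    isolation."""
    if not positives:
        raise ValueError("positives must be nonempty")
    pool = sorted(universe - set(positives))
    if len(pool) < len(positives):
        raise ValueError(
            f"cannot draw {len(positives)} negatives from "
            f"{len(pool)} non-positive genes"
        )
    negative_sets = []
    for r in range(n_resamples):
        rng = np.random.default_rng(np.random.SeedSequence((master_seed, r)))
        idx = rng.choice(len(pool), size=len(positives), replace=False)
        negative_sets.append(frozenset(pool[i] for i in idx))
    return ResamplePlan(
        positives=frozenset(positives),
        n_resamples=n_resamples,
        master_seed=master_seed,
        negative_sets=tuple(negative_sets),
    )


# ---------------------------------------------------------------------------
# Numba lasso-logistic path solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _logistic_objective(f, t, w, lam, n):
    obj = lam * np.abs(w).sum()
    for i in range(n):
        z = -t[i] * f[i]
        obj += (np.log1p(np.exp(z)) if z < 35.0 else z) / n
    return obj


@njit(cache=True)
def _wls_cd_sweep(X, v, r, w, b_arr, lam, n, p, sx2, active_only, active):
    """One coordinate-descent pass on the weighted least-squares surrogate."""
    maxd = 0.0
    num = 0.0
    den = 0.0
    for i in range(n):
        num += v[i] * r[i]
        den += v[i]
    db = num / den
    if db != 0.0:
        b_arr[0] += db
        for i in range(n):
            r[i] -= db
        if abs(db) > maxd:
            maxd = abs(db)
    for j in range(p):
        if active_only and not active[j]:
            continue
        den_j = sx2[j]
        if den_j <= 0.0:
            continue
        num = 0.0
        for i in range(n):
            num += v[i] * X[i, j] * r[i]
        u = num / n + (den_j / n) * w[j]
        wj = 0.0
        if u > lam:
            wj = (u - lam) / (den_j / n)
        elif u < -lam:
            wj = (u + lam) / (den_j / n)
        d = wj - w[j]
        if d != 0.0:
            w[j] = wj
            active[j] = True
            for i in range(n):
                r[i] -= X[i, j] * d
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd


@njit(cache=True)
def _lasso_logistic_path(X, y, lams, tol, max_outer, inner_tol, max_inner):
    """Warm-started coefficient path over a descending lambda grid.

    Returns (W [n_lambda x p], b [n_lambda], status [n_lambda]) where
    status 1 flags a lambda that did not converge within the caps.
    """
    n, p = X.shape
    t = 2.0 * y - 1.0
    nl = lams.shape[0]
    W = np.zeros((nl, p))
    B = np.zeros(nl)
    status = np.zeros(nl, np.int64)
    w = np.zeros(p)
    b_arr = np.zeros(1)
    f = np.zeros(n)
    v = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    sx2 = np.empty(p)
    active = np.zeros(p, np.bool_)
    for k in range(nl):
        lam = lams[k]
        obj = _logistic_objective(f, t, w, lam, n)
        converged = False
        for _outer in range(max_outer):
            # quadratic (IRLS) approximation around the current fit
            for i in range(n):
                fi = f[i]
                pi = 1.0 / (1.0 + np.exp(-fi)) if fi > -35.0 else np.exp(fi)
                vi = pi * (1.0 - pi)
                if vi < 1e-5:
                    vi = 1e-5
                v[i] = vi
                z[i] = fi + (y[i] - pi) / vi
                r[i] = z[i] - fi
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += v[i] * X[i, j] * X[i, j]
                sx2[j] = s
                active[j] = w[j] != 0.0
            _wls_cd_sweep(X, v, r, w, b_arr, lam, n, p, sx2, False, active)
            for _inner in range(max_inner):
                maxd = _wls_cd_sweep(X, v, r, w, b_arr, lam, n, p, sx2, True, active)
                if maxd < inner_tol:
                    maxd2 = _wls_cd_sweep(X, v, r, w, b_arr, lam, n, p, sx2,
                                          False, active)
                    if maxd2 < inner_tol:
                        break
            for i in range(n):
                f[i] = z[i] - r[i]
            newobj = _logistic_objective(f, t, w, lam, n)
            if obj - newobj < tol:
                converged = True
                obj = newobj
                break
            obj = newobj
        if not converged:
            status[k] = 1
        W[k] = w
        B[k] = b_arr[0]
    return W, B, status


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which the all-zero coefficient vector is optimal."""
    n = len(y)
    p0 = y.mean()  # intercept-only fitted probability
    return float(np.max(np.abs(X.T @ (y - p0))) / n)


def make_lambda_grid(X: np.ndarray, y: np.ndarray,
                     n_lambda: int = N_LAMBDA,
                     min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Descending log-spaced grid from just above lambda_max downwards."""
    lmax = lambda_max(X, y) * (1.0 + 1e-3)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def solve_lasso_path(X: np.ndarray, y: np.ndarray,
                     lambda_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the penalized path; hard error if any lambda fails to converge."""
    X = np.asfortranarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    lams = np.ascontiguousarray(lambda_grid, dtype=float)
    if np.any(np.diff(lams) > 0):
        raise ValueError("lambda_grid must be non-increasing")
    if np.any(lams < 0):
        raise ValueError("lambda_grid must be non-negative")
    W, B, status = _lasso_logistic_path(
        X, y, lams, OBJECTIVE_TOL, MAX_OUTER, INNER_TOL, MAX_INNER
    )
    if status.any():
        bad = lams[np.flatnonzero(status)[0]]
        raise RuntimeError(f"lasso path failed to converge at lambda={bad:g}")
    return W, B


def _binomial_deviance(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays of held-out samples for stratified folds."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


# ---------------------------------------------------------------------------
# LassoFit / fit_lasso_logistic
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """A lasso-logistic fit at the CV-chosen penalty."""

    lam: float
    coefficients: dict[FeatureColumn, float]
    intercept: float
    selected: frozenset[FeatureColumn]
    cv_deviance_path: dict[float, float]

    def __post_init__(self) -> None:
        nz = frozenset(c for c, v in self.coefficients.items() if v != 0.0)
        if nz != self.selected:
            raise ValueError("selected must be the nonzero-coefficient columns")


def fit_lasso_logistic(
    matrix: FeatureMatrix,
    labels: dict[str, int],
    lambda_grid: np.ndarray | None = None,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    cv_seed: int = 0,
) -> LassoFit:
    """CV-tuned L1 logistic regression on one balanced resample.

    ``labels`` maps the resample's training genes (positives 1,
    negatives 0) to classes; all other matrix rows are ignored.  The
    penalty is chosen to minimize mean held-out binomial deviance over
    stratified inner folds, then the model is refit on all training
    rows at that penalty.
    """
    if not matrix.normalized:
        raise ValueError("matrix must be Z-score normalized before fitting")
    genes = sorted(labels)
    rows = matrix.gene_indices(genes)
    X = matrix.values[rows]
    y = np.array([labels[g] for g in genes], dtype=float)
    if y.min() == y.max():
        raise ValueError("labels must contain both classes")
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be nonempty")

    rng = np.random.default_rng(np.random.SeedSequence((cv_seed, 0x1a550)))
    deviance = np.zeros(lambda_grid.size)
    if inner_folds > 1:
        folds = _stratified_folds(y, inner_folds, rng)
        for held_out in folds:
            train = np.setdiff1d(np.arange(len(y)), held_out)
            W, B = solve_lasso_path(X[train], y[train], lambda_grid)
            eta = X[held_out] @ W.T + B  # held-out x lambda
            prob = 1.0 / (1.0 + np.exp(-eta))
            for k in range(lambda_grid.size):
                deviance[k] += _binomial_deviance(prob[:, k], y[held_out])
        deviance /= len(folds)
        best = int(np.argmin(deviance))
    else:
        best = lambda_grid.size - 1
    W, B = solve_lasso_path(X, y, lambda_grid)
    coef = {c: float(W[best, j]) for j, c in enumerate(matrix.columns)}
    return LassoFit(
        lam=float(lambda_grid[best]),
        coefficients=coef,
        intercept=float(B[best]),
        selected=frozenset(c for c, v in coef.items() if v != 0.0),
        cv_deviance_path={float(l): float(d)
                          for l, d in zip(lambda_grid, deviance)},
    )


# ---------------------------------------------------------------------------
# Signature aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureEntry:
    dataset_id: str
    feature_type: str
    selection_frequency: float
    sign: str  # '+' enriched at positives, '-' depleted
    median_coefficient: float


@dataclass
class Signature:
    """Aggregated selected features for one scope (the per-scope signature)."""

    scope: str
    entries: list[SignatureEntry]
    n_resamples: int

    @property
    def columns(self) -> list[tuple[str, str]]:
        return [(e.dataset_id, e.feature_type) for e in self.entries]

    def column_mask(self, matrix: FeatureMatrix) -> np.ndarray:
        keys = set(self.columns)
        return np.array([(c.dataset_id, c.feature_type) in keys
                         for c in matrix.columns])


def select_signature(
    matrix: FeatureMatrix,
    plan: ResamplePlan,
    scope: str = "combined",
    frequency_threshold: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    inner_folds: int = DEFAULT_INNER_FOLDS,
) -> Signature:
    """Aggregate per-resample lasso selections into a scope signature.

    Entries are the columns selected (nonzero coefficient) in at least
    ``frequency_threshold`` of resamples, with the sign of the median
    nonzero coefficient; entries whose median nonzero coefficient is
    exactly 0 are excluded.  Sorted by descending frequency, then column
    order.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    sub = matrix.select_columns(matrix.scope_mask(scope))
    if sub.n_columns == 0:
        raise ValueError(f"matrix has no columns in scope {scope!r}")
    n_sel = np.zeros(sub.n_columns, dtype=int)
    coefs: list[list[float]] = [[] for _ in range(sub.n_columns)]
    for negatives in plan.negative_sets:
        labels = {g: 1 for g in plan.positives}
        labels.update({g: 0 for g in negatives})
        # seed from the negative-set content, so aggregation does not
        # depend on the order resamples are listed in
        fit = fit_lasso_logistic(
            sub, labels, lambda_grid=lambda_grid, inner_folds=inner_folds,
            cv_seed=_derive_seed(plan.master_seed,
                                 "cv:" + ",".join(sorted(negatives))),
        )
        for j, col in enumerate(sub.columns):
            v = fit.coefficients[col]
            if v != 0.0:
                n_sel[j] += 1
                coefs[j].append(v)
    entries = []
    for j, col in enumerate(sub.columns):
        freq = float(n_sel[j] / plan.n_resamples)
        if freq < frequency_threshold or not coefs[j]:
            continue
        med = float(np.median(coefs[j]))
        if med == 0.0:
            continue
        entries.append(
            SignatureEntry(
                dataset_id=col.dataset_id,
                feature_type=col.feature_type,
                selection_frequency=freq,
                sign="+" if med > 0 else "-",
                median_coefficient=med,
            )
        )
    order = {(c.dataset_id, c.feature_type): j for j, c in enumerate(sub.columns)}
    entries.sort(key=lambda e: (-e.selection_frequency,
                                order[(e.dataset_id, e.feature_type)]))
    return Signature(scope=scope, entries=entries, n_resamples=plan.n_resamples)


def _derive_seed(master_seed: int, tag: str) -> int:
    return (master_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def write_signature(signature: Signature, path) -> None:
    """Signature TSV: dataset_id, feature_type, frequency, sign, median_coefficient."""
    with open(path, "w") as fh:
        fh.write("dataset_id\tfeature_type\tfrequency\tsign\tmedian_coefficient\n")
        for e in signature.entries:
            fh.write(
                f"{e.dataset_id}\t{e.feature_type}\t{e.selection_frequency!r}"
                f"\t{e.sign}\t{e.median_coefficient!r}\n"
            )


def read_signature(path, scope: str = "combined",
                   n_resamples: int = 0) -> Signature:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["dataset_id", "feature_type", "frequency", "sign",
                    "median_coefficient"]
        if header != expected:
            raise ValueError(f"{path}: unexpected signature header {header}")
        for line in fh:
            if not line.strip():
                continue
            ds, ft, freq, sign, med = line.rstrip("\n").split("\t")
            entries.append(SignatureEntry(ds, ft, float(freq), sign, float(med)))
    return Signature(scope=scope, entries=entries, n_resamples=n_resamples)
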