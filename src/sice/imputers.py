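"""Univariate imputation kernels.

Each kernel fills the masked entries of one target column given complete
predictor columns, the elementary step a chained-equations engine repeats.
Six model-based methods are provided — predictive mean matching (``pmm``),
Bayesian linear regression (``blr``), binary logistic regression
(``logreg``), polytomous/multinomial logistic regression (``polyreg``),
linear discriminant analysis (``lda``) and a classification/regression tree
with leaf sampling (``cart``) — plus the single-imputation baselines
``mean``, ``median``, ``mode`` and ``random`` (random observed sample).

All stochastic kernels draw imputations rather than taking an argmax
(Bernoulli / categorical draws at the fitted probabilities, donor sampling
for PMM, leaf sampling for CART): repeated calls must produce *distinct*
plausible values, which is what gives the downstream pooling of several
imputations something to average over.

Categorical predictors enter fits as reference-level dummy codes, ordinal
predictors as integer ranks; the target column is never encoded outside the
kernel that imputes it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .tabular import MISSING, DataTable, VariableSpec

__all__ = [
    "ImputationTask",
    "RegressionDraw",
    "CartImputer",
    "draw_blr",
    "impute_pmm",
    "impute_blr",
    "impute_logreg",
    "impute_polyreg",
    "impute_lda",
    "impute_cart",
    "impute_baseline",
    "apply_method",
    "METHOD_NAMES",
    "method_compatible",
    "encode_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6
DEFAULT_DONORS = 5
DEFAULT_MIN_LEAF = 5
LDA_SHRINKAGE = 1e-4


@dataclass
class ImputationTask:
    """One imputation problem: fill ``mask`` rows of ``target`` from ``predictors``.

    Fitting uses the rows that are neither masked nor missing in the target;
    predictor columns must be complete on every row involved.
    """

    table: DataTable
    target: str
    predictors: list[str]
    mask: np.ndarray  # boolean, length n_rows: rows to impute
    rng: np.random.Generator

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("mask selects no rows: nothing to impute")
        col = self.table.column(self.target)
        self.fit_rows = [
            r for r in range(self.table.n_rows)
            if not self.mask[r] and col[r] is not MISSING
        ]
        self.impute_rows = [int(r) for r in np.flatnonzero(self.mask)]
        if not self.fit_rows:
            raise ValueError(f"column {self.target!r} has no observed values to fit on")
        for p in self.predictors:
            pcol = self.table.column(p)
            for r in self.fit_rows + self.impute_rows:
                if pcol[r] is MISSING:
                    raise ValueError(
                        f"predictor {p!r} is missing at row {r + 1}; kernels "
                        "require complete predictors"
                    )

    @property
    def target_spec(self) -> VariableSpec:
        return self.table.spec(self.target)

    def observed_values(self) -> list[Any]:
        col = self.table.column(self.target)
        return [col[r] for r in self.fit_rows]


def encode_matrix(
    table: DataTable, columns: Sequence[str], rows: Sequence[int], intercept: bool = False
) -> np.ndarray:
    """Numeric design matrix: dummies for binary/nominal, ranks for ordinal."""
    blocks: list[np.ndarray] = []
    if intercept:
        blocks.append(np.ones((len(rows), 1)))
    for name in columns:
        spec = table.spec(name)
        col = table.column(name)
        vals = [col[r] for r in rows]
        if spec.vartype == "numeric":
            blocks.append(np.asarray(vals, dtype=float)[:, None])
        elif spec.vartype == "ordinal":
            ranks = [spec.levels.index(v) for v in vals]
            blocks.append(np.asarray(ranks, dtype=float)[:, None])
        else:  # binary / nominal: reference-level dummies
            dummies = np.zeros((len(rows), len(spec.levels) - 1))
            for i, v in enumerate(vals):
                j = spec.levels.index(v)
                if j > 0:
                    dummies[i, j - 1] = 1.0
            blocks.append(dummies)
    if not blocks:
        return np.ones((len(rows), 1))  # intercept-only design
    return np.hstack(blocks)


def _numeric_target(task: ImputationTask) -> tuple[np.ndarray, bool]:
    """Observed target as floats; ordinal targets become integer ranks."""
    spec = task.target_spec
    obs = task.observed_values()
    if spec.vartype == "numeric":
        return np.asarray(obs, dtype=float), False
    if spec.vartype in ("ordinal", "binary"):
        return np.asarray([spec.levels.index(v) for v in obs], dtype=float), True
    raise ValueError(
        f"column {task.target!r} is {spec.vartype}; this kernel needs a "
        "numeric, ordinal or binary target"
    )


def _rank_to_level(spec: VariableSpec, value: float) -> str:
    rank = int(np.clip(round(value), 0, len(spec.levels) - 1))
    return spec.levels[rank]


# --------------------------------------------------------------------------
# Bayesian linear regression draw (shared by PMM and BLR)
# --------------------------------------------------------------------------

@dataclass
class RegressionDraw:
    """Least-squares fit plus one posterior draw of (coefficients, variance).

    ``b`` is the (ridge-regularised) least-squares solution; ``sigma2_star``
    is drawn from the scaled inverse-chi-square posterior of the residual
    variance under the standard noninformative prior, and ``b_star`` from
    Normal(b, sigma2_star * (X'X + ridge*I)^-1).  An exact fit (zero
    residuals) collapses the posterior: ``sigma2_star = 0`` and
    ``b_star = b``.
    """

    b: np.ndarray
    b_star: np.ndarray
    sigma2_star: float


def draw_blr(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RegressionDraw:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 rows to fit a regression, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    xtx = X.T @ X
    xty = X.T @ y

    def _solve(r: float) -> tuple[np.ndarray, np.ndarray]:
        A = xtx + r * np.eye(p)
        Ainv = np.linalg.inv(A)
        return Ainv @ xty, Ainv

    try:
        b, Ainv = _solve(ridge)
        if not np.all(np.isfinite(b)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        logger.warning(
            "singular X'X with ridge=%g; refitting with ridge=%g", ridge, DEFAULT_RIDGE
        )
        b, Ainv = _solve(DEFAULT_RIDGE)

    resid = y - X @ b
    rss = float(resid @ resid)
    scale = max(1.0, float(y @ y))
    if rss <= 1e-12 * scale:  # exact fit: degenerate posterior
        return RegressionDraw(b=b, b_star=b.copy(), sigma2_star=0.0)
    df = max(n - p, 1)
    sigma2_star = rss / float(rng.chisquare(df))
    Ainv = (Ainv + Ainv.T) / 2.0
    try:
        L = np.linalg.cholesky(Ainv)
    except np.linalg.LinAlgError:
        # numerically semi-definite: symmetrise via eigendecomposition
        w, V = np.linalg.eigh(Ainv)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    b_star = b + math.sqrt(sigma2_star) * (L @ rng.standard_normal(p))
    return RegressionDraw(b=b, b_star=b_star, sigma2_star=sigma2_star)


# --------------------------------------------------------------------------
# PMM and BLR kernels
# --------------------------------------------------------------------------

def impute_pmm(
    task: ImputationTask,
    donors: int = DEFAULT_DONORS,
    ridge: float = DEFAULT_RIDGE,
) -> list[Any]:
    """Predictive mean matching.

    Fits a linear regression of the target on the predictors, takes one
    posterior draw of the coefficients, predicts observed rows with the
    least-squares coefficients and missing rows with the drawn ones, and
    imputes each missing row with the observed target value of one of the
    ``donors`` rows whose predictions lie closest — so every imputation is a
    genuinely observed value.
    """
    y, is_ordinal = _numeric_target(task)
    if len(task.fit_rows) < donors:
        raise ValueError(
            f"donor pool of {donors} exceeds the {len(task.fit_rows)} observed rows"
        )
    X_obs = encode_matrix(task.table, task.predictors, task.fit_rows, intercept=True)
    X_mis = encode_matrix(task.table, task.predictors, task.impute_rows, intercept=True)
    draw = draw_blr(X_obs, y, ridge=ridge, rng=task.rng)
    pred_obs = X_obs @ draw.b
    pred_mis = X_mis @ draw.b_star
    observed = task.observed_values()
    out: list[Any] = []
    for pm in pred_mis:
        dist = np.abs(pred_obs - pm)
        pool = np.argsort(dist, kind="stable")[:donors]
        pick = pool[int(task.rng.integers(donors))]
        out.append(observed[int(pick)])
    return out


def impute_blr(task: ImputationTask, ridge: float = DEFAULT_RIDGE) -> list[Any]:
    """Bayesian linear regression: impute with draws from the posterior
    predictive distribution (coefficient draw plus fresh Gaussian noise)."""
    y, is_ordinal = _numeric_target(task)
    X_obs = encode_matrix(task.table, task.predictors, task.fit_rows, intercept=True)
    X_mis = encode_matrix(task.table, task.predictors, task.impute_rows, intercept=True)
    draw = draw_blr(X_obs, y, ridge=ridge, rng=task.rng)
    noise = math.sqrt(draw.sigma2_star) * task.rng.standard_normal(len(task.impute_rows))
    values = X_mis @ draw.b_star + noise
    spec = task.target_spec
    if is_ordinal:
        return [_rank_to_level(spec, v) for v in values]
    return [float(v) for v in values]


# --------------------------------------------------------------------------
# Categorical kernels: logistic, polytomous, LDA
# --------------------------------------------------------------------------

def _draw_labels(
    levels: Sequence[str], proba: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """One categorical draw per row from its probability vector."""
    proba = np.clip(np.asarray(proba, dtype=float), 0.0, None)
    proba = proba / proba.sum(axis=1, keepdims=True)
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(proba))
    idx = (u[:, None] > cum).sum(axis=1)
    return [levels[int(i)] for i in idx]


def _single_class_fallback(task: ImputationTask, classes: list[str]) -> list[str] | None:
    if len(classes) == 1:
        logger.warning(
            "column %r: only one class %r observed; imputing it everywhere",
            task.target, classes[0],
        )
        return [classes[0]] * len(task.impute_rows)
    return None


def _observed_classes(task: ImputationTask) -> list[str]:
    seen = set(task.observed_values())
    return [lv for lv in task.target_spec.levels if lv in seen]


def _logistic_impute(task: ImputationTask) -> list[str]:
    classes = _observed_classes(task)
    fallback = _single_class_fallback(task, classes)
    if fallback is not None:
        return fallback
    X_obs = encode_matrix(task.table, task.predictors, task.fit_rows)
    X_mis = encode_matrix(task.table, task.predictors, task.impute_rows)
    model = LogisticRegression(C=1.0 / DEFAULT_RIDGE, max_iter=2000)
    model.fit(X_obs, task.observed_values())
    proba = model.predict_proba(X_mis)
    return _draw_labels(list(model.classes_), proba, task.rng)


def impute_logreg(task: ImputationTask) -> list[str]:
    """Binary logistic regression; labels drawn Bernoulli at the fitted
    probabilities (a tiny ridge keeps separated data finite)."""
    if task.target_spec.vartype != "binary":
        raise ValueError(f"logreg requires a binary target, got {task.target_spec.vartype}")
    return _logistic_impute(task)


def impute_polyreg(task: ImputationTask) -> list[str]:
    """Multinomial (polytomous) logistic regression; labels drawn from the
    fitted per-row category distribution."""
    if not task.target_spec.is_categorical:
        raise ValueError("polyreg requires a categorical target")
    return _logistic_impute(task)


def impute_lda(task: ImputationTask) -> list[str]:
    """Linear discriminant analysis; labels drawn from class posteriors.

    Classes observed fewer than twice are dropped from the discriminant
    (logged); a singular within-class scatter triggers shrinkage
    regularisation toward the identity, and if even that fails the class
    prior frequencies are used.
    """
    if not task.target_spec.is_categorical:
        raise ValueError("lda requires a categorical target")
    observed = task.observed_values()
    counts: dict[str, int] = {}
    for v in observed:
        counts[v] = counts.get(v, 0) + 1
    keep = [lv for lv in task.target_spec.levels if counts.get(lv, 0) >= 2]
    dropped = [lv for lv in counts if lv not in keep]
    if dropped:
        logger.warning("column %r: classes %s have < 2 rows; dropped from LDA",
                       task.target, dropped)
    rows = [r for r, v in zip(task.fit_rows, observed) if v in keep]
    labels = [v for v in observed if v in keep]
    fallback = _single_class_fallback(task, keep or list(counts))
    if fallback is not None:
        return fallback
    X_obs = encode_matrix(task.table, task.predictors, rows)
    X_mis = encode_matrix(task.table, task.predictors, task.impute_rows)
    for shrinkage in (None, LDA_SHRINKAGE):
        try:
            model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
            model.fit(X_obs, labels)
            proba = model.predict_proba(X_mis)
            if not np.all(np.isfinite(proba)):
                raise np.linalg.LinAlgError("non-finite posteriors")
            if shrinkage is not None:
                logger.warning(
                    "column %r: singular within-class scatter; LDA refit with "
                    "shrinkage %g", task.target, LDA_SHRINKAGE,
                )
            return _draw_labels(list(model.classes_), proba, task.rng)
        except (np.linalg.LinAlgError, ValueError):
            continue
    logger.warning("column %r: LDA unfittable; drawing from class priors", task.target)
    priors = np.asarray([counts.get(lv, 0) for lv in keep], dtype=float)
    proba = np.tile(priors / priors.sum(), (len(task.impute_rows), 1))
    return _draw_labels(keep, proba, task.rng)


# --------------------------------------------------------------------------
# CART kernel
# --------------------------------------------------------------------------

@dataclass
class CartImputer:
    """A fitted tree plus, per leaf, the observed target values that reached it."""

    tree: DecisionTreeClassifier | DecisionTreeRegressor
    leaf_values: dict[int, list[Any]] = field(default_factory=dict)

    def sample(self, X: np.ndarray, rng: np.random.Generator) -> list[Any]:
        leaves = self.tree.apply(X)
        out = []
        for leaf in leaves:
            pool = self.leaf_values[int(leaf)]
            out.append(pool[int(rng.integers(len(pool)))])
        return out


def fit_cart(task: ImputationTask, min_leaf: int = DEFAULT_MIN_LEAF) -> CartImputer:
    """Grow the greedy binary tree: deviance (squared-error) reduction for a
    numeric target, Gini reduction for a categorical one; leaves stop at
    ``min_leaf`` observed rows."""
    spec = task.target_spec
    X_obs = encode_matrix(task.table, task.predictors, task.fit_rows)
    observed = task.observed_values()
    seed = int(task.rng.integers(2**31 - 1))
    if spec.vartype == "numeric":
        tree = DecisionTreeRegressor(
            criterion="squared_error", min_samples_leaf=min_leaf, random_state=seed
        )
        tree.fit(X_obs, np.asarray(observed, dtype=float))
    else:
        tree = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_leaf, random_state=seed
        )
        tree.fit(X_obs, observed)
    leaf_values: dict[int, list[Any]] = {}
    for leaf, value in zip(tree.apply(X_obs), observed):
        leaf_values.setdefault(int(leaf), []).append(value)
    return CartImputer(tree=tree, leaf_values=leaf_values)


def impute_cart(task: ImputationTask, min_leaf: int = DEFAULT_MIN_LEAF) -> list[Any]:
    """Tree imputation: route each missing row to its leaf and draw uniformly
    from the *observed* target values in that leaf (leaf sampling keeps the
    imputation stochastic; a constant target yields a single-leaf tree and a
    constant imputation)."""
    model = fit_cart(task, min_leaf=min_leaf)
    X_mis = encode_matrix(task.table, task.predictors, task.impute_rows)
    return model.sample(X_mis, task.rng)


# --------------------------------------------------------------------------
# Single-imputation baselines
# --------------------------------------------------------------------------

def impute_baseline(task: ImputationTask, kind: str) -> list[Any]:
    """``mean`` / ``median`` (numeric target), ``mode`` (categorical; ties
    broken by higher observed count then schema level order), or ``random``
    (independent uniform draws from the observed values)."""
    observed = task.observed_values()
    n = len(task.impute_rows)
    spec = task.target_spec
    if kind in ("mean", "median"):
        if spec.vartype != "numeric":
            raise ValueError(f"{kind} imputation requires a numeric target")
        vals = np.asarray(observed, dtype=float)
        stat = float(np.mean(vals) if kind == "mean" else np.median(vals))
        return [stat] * n
    if kind == "mode":
        if not spec.is_categorical:
            raise ValueError("mode imputation requires a categorical target")
        counts = {lv: 0 for lv in spec.levels}
        for v in observed:
            counts[v] += 1
        best = max(spec.levels, key=lambda lv: (counts[lv], -spec.levels.index(lv)))
        return [best] * n
    if kind in ("random", "random_sample"):
        idx = task.rng.integers(len(observed), size=n)
        return [observed[int(i)] for i in idx]
    raise ValueError(f"unknown baseline kind {kind!r}")


# --------------------------------------------------------------------------
# Method registry (names accepted by config / CLI / engine)
# --------------------------------------------------------------------------

_METHODS = {
    "pmm": impute_pmm,
    "blr": impute_blr,
    "logreg": impute_logreg,
    "polyreg": impute_polyreg,
    "lda": impute_lda,
    "cart": impute_cart,
    "mean": lambda task: impute_baseline(task, "mean"),
    "median": lambda task: impute_baseline(task, "median"),
    "mode": lambda task: impute_baseline(task, "mode"),
    "random": lambda task: impute_baseline(task, "random"),
}

METHOD_NAMES = tuple(_METHODS)

_COMPAT = {
    "pmm": ("numeric", "ordinal", "binary"),
    "blr": ("numeric", "ordinal"),
    "logreg": ("binary",),
    "polyreg": ("binary", "nominal", "ordinal"),
    "lda": ("binary", "nominal", "ordinal"),
    "cart": ("binary", "nominal", "ordinal", "numeric"),
    "mean": ("numeric",),
    "median": ("numeric",),
    "mode": ("binary", "nominal", "ordinal"),
    "random": ("binary", "nominal", "ordinal", "numeric"),
}


def method_compatible(method: str, vartype: str) -> bool:
    if method not in _COMPAT:
        raise ValueError(f"unknown method {method!r}; known: {sorted(_COMPAT)}")
    return vartype in _COMPAT[method]


def apply_method(method: str, task: ImputationTask) -> list[Any]:
    """Dispatch a method name to its kernel (the engine's single entry point)."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; known: {sorted(_METHODS)}")
    if not method_compatible(method, task.target_spec.vartype):
        raise ValueError(
            f"method {method!r} is incompatible with {task.target_spec.vartype} "
            f"column {task.target!r}"
        )
    return _METHODS[method](task)
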