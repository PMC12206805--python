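"""Spectral preprocessing, PLS machinery, CARS and SPA wavelength selection,
and the classical classifiers (PLS-DA, RBF-SVM) with grid search.

Multi-class handling throughout is the standard PLS2 extension: class labels
become one-hot responses, a single PLS2 model regresses all six columns, and
variable importance is the row L2 norm of the p x K coefficient matrix.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo PLS fits;
an exponentially decreasing function (EDF) enforces the retained-variable
count ``ceil(r_i * p)`` with ``r_i = a * exp(-k*i)``, ``a = (p/2)^(1/(N-1))``
and ``k = ln(p/2)/(N-1)``, so run 1 keeps all p variables and run N keeps 2;
adaptive reweighted sampling (weighted draws with replacement) can only
shrink a run's subset further.  The subset with the lowest RMSECV wins.

SPA (successive projections algorithm) grows, from every starting column, a
chain of minimally collinear variables by orthogonal projection norms, scores
every (chain, size) by multiple linear regression RMSEP on a validation
split, and optionally shrinks the winning size by an F-test (alpha = 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cube_io import WavelengthAxis

__all__ = [
    "SpectraTable",
    "SelectionResult",
    "CarsConfig",
    "snv",
    "one_hot",
    "pls2_fit",
    "PLSModel",
    "rmsecv_kfold",
    "cars_select",
    "spa_select",
    "train_plsda",
    "train_svm_rbf",
    "PLSDAClassifier",
    "SVMClassifier",
]


@dataclass
class SpectraTable:
    """n x p matrix of mean spectra with wavelength axis and labels (1..6)."""

    X: np.ndarray
    axis: WavelengthAxis
    y: np.ndarray
    fold: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.axis):
            raise ValueError("X column count must equal axis length")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows and y length differ")
        if np.isnan(self.X).any():
            raise ValueError("X contains NaN")
        if self.X.shape[0] < np.unique(self.y).size:
            raise ValueError("need at least one spectrum per class")

    @property
    def n_classes(self) -> int:
        return int(self.y.max())


@dataclass
class SelectionResult:
    """Selected band indices/wavelengths plus diagnostic traces."""

    selected_indices: np.ndarray
    selected_nm: np.ndarray
    criterion_curve: np.ndarray      # RMSECV per run (CARS) / best RMSEP per size (SPA)
    trace: dict
    method: str
    seed: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("selected indices must be distinct")
        self.selected_indices = idx
        self.selected_nm = np.asarray(self.selected_nm, dtype=np.float64)


@dataclass
class CarsConfig:
    n_runs: int = 50
    mc_fraction: float = 0.8
    max_pls_components: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.mc_fraction < 1:
            raise ValueError("mc_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Preprocessing and PLS machinery
# ---------------------------------------------------------------------------

def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each spectrum centered and scaled to unit
    sample standard deviation (n-1 denominator).  Removes multiplicative
    scatter and additive baseline effects."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 1e-12)
    if bad.size:
        raise ValueError(f"constant spectrum at row index {bad[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def one_hot(y: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    K = n_classes or int(y.max())
    Y = np.zeros((y.size, K))
    Y[np.arange(y.size), y - 1] = 1.0
    return Y


@dataclass
class PLSModel:
    """Fitted PLS2 model: predict(X) = X @ B + intercept."""

    B: np.ndarray           # p x K coefficient matrix
    intercept: np.ndarray   # K
    ncomp: int
    _sk: PLSRegression | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.B + self.intercept

    def variable_weights(self) -> np.ndarray:
        """Row L2 norms of B, normalized to sum 1 (CARS importance)."""
        w = np.linalg.norm(self.B, axis=1)
        s = w.sum()
        return w / s if s > 0 else np.full(w.size, 1.0 / w.size)


def pls2_fit(X: np.ndarray, Y: np.ndarray, ncomp: int) -> PLSModel:
    """NIPALS PLS2 on (internally centered) X against one-hot responses Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    n, p = X.shape
    if not 1 <= ncomp <= min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NIPALS convergence chatter on degenerate Y
        sk = PLSRegression(n_components=ncomp, scale=False).fit(X, Y)
    B = sk.coef_.T  # sklearn stores (K, p)
    # fold the internal X-centering into the intercept: y = x B + (y_mean - x_mean B)
    intercept = np.asarray(sk.intercept_).ravel() - sk._x_mean @ B
    return PLSModel(B=B, intercept=intercept, ncomp=ncomp, _sk=sk)


def rmsecv_kfold(
    X: np.ndarray, Y: np.ndarray, ncomp: int, folds: int = 5, seed: int = 0
) -> float:
    """Pooled K-fold RMSECV of PLS2, folds stratified by class (argmax of Y)."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = Y.argmax(axis=1)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        warnings.warn("stratification impossible for some class; folds may mix")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_sum, n_entries = 0.0, 0
    for tr, te in skf.split(X, labels):
        nc = min(ncomp, tr.size - 1, X.shape[1])
        model = pls2_fit(X[tr], Y[tr], nc)
        resid = Y[te] - model.predict(X[te])
        sq_sum += float((resid ** 2).sum())
        n_entries += resid.size
    return float(np.sqrt(sq_sum / n_entries))


def _pick_ncomp(X, Y, max_ncomp, folds, seed):
    """Component count with the lowest full-matrix RMSECV (tie -> smaller)."""
    upper = min(max_ncomp, X.shape[0] - 1 - X.shape[0] // folds, X.shape[1])
    best_nc, best = 1, np.inf
    for nc in range(1, max(upper, 1) + 1):
        r = rmsecv_kfold(X, Y, nc, folds, seed)
        if r < best - 1e-12:
            best, best_nc = r, nc
    return best_nc


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def edf_ratio(i: int, p: int, n_runs: int) -> float:
    """Keep-ratio r_i = a*exp(-k*i): r_1 = 1 and ceil(r_N * p) = 2."""
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * i))


def cars_select(table: SpectraTable, config: CarsConfig | None = None) -> SelectionResult:
    """Competitive adaptive reweighted sampling on one-hot PLS2.

    Per run: Monte-Carlo calibration draw, PLS2 fit on the current variable
    set, EDF-enforced reduction to the top-weight variables, adaptive
    reweighted sampling (weighted draws with replacement; the retained set is
    every variable drawn at least once), and RMSECV of the retained set.
    Returns the subset with minimum RMSECV plus the full trace.
    """
    config = config or CarsConfig()
    X, y = table.X, table.y
    n, p = X.shape
    if p < 10:
        raise ValueError("CARS needs at least 10 variables")
    Y = one_hot(y)
    rng = np.random.default_rng(config.seed)
    ncomp = _pick_ncomp(X, Y, config.max_pls_components, config.cv_folds, config.seed)

    current = np.arange(p)
    subsets, sizes, rmsecv = [], [], []
    n_cal = int(np.ceil(config.mc_fraction * n))
    for i in range(1, config.n_runs + 1):
        cal = rng.choice(n, size=n_cal, replace=False)
        nc = min(ncomp, current.size, n_cal - 1)
        model = pls2_fit(X[np.ix_(cal, current)], Y[cal], nc)
        w = model.variable_weights()
        # EDF: enforced reduction to the top ceil(r_i * p) variables
        n_keep = min(int(np.ceil(edf_ratio(i, p, config.n_runs) * p)), current.size)
        top = np.argsort(-w, kind="stable")[:n_keep]
        kept = current[np.sort(top)]
        w_kept = w[np.sort(top)]
        # ARS: n_keep weighted draws with replacement; retained = drawn at least once
        probs = w_kept / w_kept.sum() if w_kept.sum() > 0 else None
        drawn = rng.choice(kept.size, size=n_keep, replace=True, p=probs)
        retained = kept[np.unique(drawn)]
        subsets.append(retained)
        sizes.append(retained.size)
        if retained.size < max(2, min(ncomp, 2)):
            rmsecv.append(np.inf)
        else:
            nc_r = min(ncomp, retained.size, n - 1)
            rmsecv.append(
                rmsecv_kfold(X[:, retained], Y, nc_r, config.cv_folds, config.seed)
            )
        current = retained if retained.size >= 2 else current
    rmsecv = np.asarray(rmsecv)
    best = int(np.argmin(rmsecv))
    sel = np.sort(subsets[best])
    return SelectionResult(
        selected_indices=sel,
        selected_nm=table.axis.values[sel],
        criterion_curve=rmsecv,
        trace={
            "subset_sizes": np.asarray(sizes),
            "edf_sizes": np.array(
                [int(np.ceil(edf_ratio(i, p, config.n_runs) * p))
                 for i in range(1, config.n_runs + 1)]
            ),
            "best_run": best,
            "ncomp": ncomp,
        },
        method="cars",
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(
    Xn: np.ndarray, start: int, max_vars: int, norms0: np.ndarray | None = None
) -> list[int]:
    """Projection chain from one starting column: each step appends the
    column with the largest norm in the orthogonal complement of the span of
    the chosen ones.  Truncates on numerically zero projections.

    Projected squared norms are maintained incrementally (one Q-row times X
    product per step) instead of deflating the whole matrix.
    """
    n, p = Xn.shape
    if norms0 is None:
        norms0 = np.einsum("ij,ij->j", Xn, Xn)
    chain = [start]
    if norms0[start] <= 1e-24:
        return chain
    Q = np.empty((max_vars, n))
    Q[0] = Xn[:, start] / np.sqrt(norms0[start])
    norms2 = norms0.copy()
    for t in range(1, max_vars):
        g = Q[t - 1] @ Xn
        norms2 -= g * g
        np.maximum(norms2, 0.0, out=norms2)
        norms2[chain] = -1.0
        j = int(np.argmax(norms2))
        if norms2[j] <= 1e-20 + 1e-14 * norms0[j]:
            break
        # orthonormalize the chosen column against the chain
        coeffs = Q[:t] @ Xn[:, j]
        u = Xn[:, j] - Q[:t].T @ coeffs
        nu = np.linalg.norm(u)
        if nu <= 1e-12:
            break
        chain.append(j)
        Q[t] = u / nu
    return chain


def _prefix_rmsep(X_tr, Y_tr, X_va, Y_va, chain):
    """RMSEP of intercept-MLR for every prefix size of the chain.

    One incremental QR factorization of the growing training design shares
    the work across prefixes: appending a column costs one projection, and
    each prefix's coefficients come from a small triangular solve.  Columns
    that are numerically dependent on the prefix get zero coefficients
    (the fit is unchanged).
    """
    n_tr = X_tr.shape[0]
    m_max = len(chain)
    K = Y_tr.shape[1]
    n_cols = m_max + 1  # intercept + chain columns
    A_va = np.column_stack([np.ones(X_va.shape[0]), X_va[:, chain]])
    Q = np.empty((n_tr, n_cols))
    Rcoef = np.zeros((n_cols, n_cols))  # row = basis vector, col = design col
    G = np.empty((n_cols, K))           # Q^T Y for each basis vector
    indep: list[int] = []               # design-column index per basis vector
    rank = 0
    rmseps = np.empty(m_max)
    for j in range(n_cols):
        a = np.ones(n_tr) if j == 0 else X_tr[:, chain[j - 1]].astype(np.float64)
        if rank:
            r = Q[:, :rank].T @ a
            u = a - Q[:, :rank] @ r
            Rcoef[:rank, j] = r
        else:
            u = a
        rho = float(np.linalg.norm(u))
        if rho > 1e-10 * max(1.0, np.linalg.norm(a)):
            Q[:, rank] = u / rho
            Rcoef[rank, j] = rho
            G[rank] = Q[:, rank] @ Y_tr
            indep.append(j)
            rank += 1
        if j >= 1:
            cols = indep[:rank]
            R_sub = Rcoef[np.ix_(range(rank), cols)]
            beta = solve_triangular(R_sub, G[:rank])
            resid = Y_va - A_va[:, cols] @ beta
            rmseps[j - 1] = np.sqrt((resid ** 2).mean())
    return rmseps


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    axis: WavelengthAxis,
    max_vars: int = 30,
    f_alpha: float = 0.25,
) -> SelectionResult:
    """Successive projections algorithm with MLR/RMSEP chain scoring.

    Ties on RMSEP across starting columns resolve to the lowest start index;
    the final size may shrink to the smallest m whose RMSEP is not
    significantly above the minimum (F-test on squared-error ratio,
    alpha = ``f_alpha``).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    n_tr, p = X_train.shape
    if max_vars > min(n_tr - 1, p):
        raise ValueError(f"max_vars must be <= min(n_train - 1, p) = {min(n_tr - 1, p)}")
    K = int(max(y_train.max(), y_val.max()))
    Y_tr = one_hot(y_train, K)
    Y_va = one_hot(y_val, K)
    # center columns for the projection geometry (standard SPA practice)
    mu = X_train.mean(axis=0)
    Xn = X_train - mu

    best = (np.inf, -1, -1)  # (rmsep, start, m)
    per_size_best = np.full(max_vars, np.inf)
    chains = {}
    norms0 = np.einsum("ij,ij->j", Xn, Xn)
    for start in range(p):
        chain = _spa_chain(Xn, start, max_vars, norms0)
        chains[start] = chain
        rmseps = _prefix_rmsep(X_train, Y_tr, X_val, Y_va, chain)
        np.minimum(per_size_best[: rmseps.size], rmseps, out=per_size_best[: rmseps.size])
        m_local = int(np.argmin(rmseps))
        cand = (float(rmseps[m_local]), start, m_local + 1)
        if cand[0] < best[0] - 1e-15:
            best = cand
    rmsep_min, start, m_best = best
    chain = chains[start]
    rmseps = _prefix_rmsep(X_train, Y_tr, X_val, Y_va, chain)
    # F-test size reduction: smallest m not significantly worse than the minimum
    dof = Y_va.size
    f_crit = stats.f.ppf(1 - f_alpha, dof, dof)
    for m in range(1, m_best + 1):
        if (rmseps[m - 1] / rmsep_min) ** 2 <= f_crit:
            m_best = m
            break
    sel = np.sort(np.asarray(chain[:m_best], dtype=int))
    return SelectionResult(
        selected_indices=sel,
        selected_nm=axis.values[sel],
        criterion_curve=per_size_best,
        trace={"start": start, "chain": np.asarray(chain), "rmsep_at_selected":
               float(rmseps[m_best - 1]), "rmsep_min": rmsep_min},
        method="spa",
        seed=None,
    )


# ---------------------------------------------------------------------------
# Classical classifiers with grid search
# ---------------------------------------------------------------------------

@dataclass
class PLSDAClassifier:
    """PLS-DA: one-hot PLS2 with argmax decision; ncomp by validation grid."""

    model: PLSModel
    ncomp: int
    val_accuracy: float
    grid: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X).argmax(axis=1) + 1

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def train_plsda(
    table_train: SpectraTable, table_val: SpectraTable, ncomp_grid=range(1, 21)
) -> PLSDAClassifier:
    """Grid-search the PLS component count on validation accuracy
    (ties -> smaller ncomp); refit retained model on the training set."""
    K = max(table_train.n_classes, table_val.n_classes)
    Y_tr = one_hot(table_train.y, K)
    limit = min(table_train.X.shape[0] - 1, table_train.X.shape[1])
    accs = {}
    best_nc, best_acc = None, -1.0
    for nc in ncomp_grid:
        if nc > limit:
            continue
        model = pls2_fit(table_train.X, Y_tr, nc)
        pred = model.predict(table_val.X).argmax(axis=1) + 1
        acc = float((pred == table_val.y).mean())
        accs[nc] = acc
        if acc > best_acc + 1e-12:  # strict improvement keeps the smaller ncomp on ties
            best_acc, best_nc = acc, nc
    if best_nc is None:
        raise ValueError("ncomp grid entirely outside rank limits")
    model = pls2_fit(table_train.X, Y_tr, best_nc)
    return PLSDAClassifier(model=model, ncomp=best_nc, val_accuracy=best_acc, grid=accs)


@dataclass
class SVMClassifier:
    """RBF-kernel SVM (one-vs-one); (C, gamma) by validation grid search."""

    svc: SVC
    C: float
    gamma: float
    val_accuracy: float
    grid: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        # one-vs-rest-style votes for ROC purposes
        return self.svc.decision_function(X)


def train_svm_rbf(
    table_train: SpectraTable,
    table_val: SpectraTable,
    C_grid=None,
    gamma_grid=None,
) -> SVMClassifier:
    """RBF-SVM grid search on validation accuracy.

    Default grids C = 2^{-5..15 step 2}, gamma = 2^{-15..3 step 2}; ties
    resolve to smaller C, then smaller gamma.  Expects SNV-preprocessed
    spectra.
    """
    C_grid = C_grid if C_grid is not None else [2.0 ** e for e in range(-5, 16, 2)]
    gamma_grid = (
        gamma_grid if gamma_grid is not None else [2.0 ** e for e in range(-15, 4, 2)]
    )
    best = None
    accs = {}
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            svc = SVC(C=C, gamma=gamma, kernel="rbf", random_state=0)
            svc.fit(table_train.X, table_train.y)
            acc = float((svc.predict(table_val.X) == table_val.y).mean())
            accs[(C, gamma)] = acc
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma, svc)
    acc, C, gamma, svc = best
    return SVMClassifier(svc=svc, C=C, gamma=gamma, val_accuracy=acc, grid=accs)
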