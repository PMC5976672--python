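"""L1-penalised multinomial classification with stability selection.

The classifier is glmnet-style lasso multinomial logistic regression in the
symmetric (all-class) parameterisation: the objective is

    (1/N) * multinomial negative log-likelihood + lambda * sum_j |theta_j|

summed over penalised columns and all classes, solved by a partial-Newton
outer loop (per-class quadratic approximation) with cyclic coordinate
descent and soft-thresholding inside. Centre-of-origin indicator columns
are never penalised: the study design always adjusts for centre, so it must
not be selected away. Feature columns are standardised to mean 0 / variance
1 on the training split only.

The stability protocol: split off a 1/10 test set, tune lambda by 10-fold
cross-validated multinomial deviance on the remaining 9/10, refit, record
test accuracy (overall and per class) and which features carry a nonzero
coefficient in any class; repeat R times (150 in the original protocol)
and aggregate per-feature selection frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .datamodel import Block, OmicsMatrix, SampleSheet, Scale, ValidationError

_PMIN = 1e-5


# ---------------------------------------------------------------------------
# feature space
# ---------------------------------------------------------------------------

@dataclass
class FeatureSpace:
    """Samples-by-columns design for the classifier.

    ``penalty_mask`` marks which columns are lasso-penalised (the omics
    features); centre indicators are unpenalised.
    """

    block: Block
    matrix: np.ndarray            # n_samples x n_columns
    column_ids: list[str]
    penalty_mask: np.ndarray      # bool per column
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.penalty_mask = np.asarray(self.penalty_mask, dtype=bool)
        n, p = self.matrix.shape
        if len(self.column_ids) != p or len(self.penalty_mask) != p:
            raise ValidationError("column ids / penalty mask must match matrix")
        if len(self.sample_ids) != n:
            raise ValidationError("sample ids must match matrix rows")

    @property
    def feature_ids(self) -> list[str]:
        return [c for c, pen in zip(self.column_ids, self.penalty_mask) if pen]


def build_feature_space(sheet: SampleSheet,
                        mirna_cpm: OmicsMatrix | None = None,
                        protein_log: OmicsMatrix | None = None) -> FeatureSpace:
    """Assemble the design: ln(CPM+1) miRNA columns and/or protein log
    abundances, plus unpenalised centre indicator columns (ref = first)."""
    blocks = []
    ids: list[str] = []
    if mirna_cpm is not None:
        if mirna_cpm.scale is not Scale.CPM:
            raise ValidationError("miRNA block must be CPM scale")
        m = mirna_cpm.reorder_samples(list(sheet.sample_ids))
        blocks.append(np.log1p(m.values).T)
        ids.extend(m.feature_ids)
    if protein_log is not None:
        if protein_log.scale is not Scale.LOG_ABUNDANCE:
            raise ValidationError("protein block must be log_abundance scale")
        pmat = protein_log.reorder_samples(list(sheet.sample_ids))
        blocks.append(pmat.values.T)
        ids.extend(pmat.feature_ids)
    if not blocks:
        raise ValidationError("need at least one omics block")
    x = np.hstack(blocks)
    mask = [True] * x.shape[1]
    centre_levels = sorted(set(sheet.centre))
    for lv in centre_levels[1:]:
        x = np.hstack([x, np.array([[1.0 if c == lv else 0.0]
                                    for c in sheet.centre])])
        ids.append(f"centre[{lv}]")
        mask.append(False)
    if mirna_cpm is not None and protein_log is not None:
        block = Block.COMBINED
    elif mirna_cpm is not None:
        block = Block.MIRNA
    else:
        block = Block.PROTEIN
    return FeatureSpace(block, x, ids, np.array(mask), list(sheet.sample_ids))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@njit(cache=False)
def _softmax_col(eta, k, out):
    n, K = eta.shape
    for i in range(n):
        m = eta[i, 0]
        for kk in range(1, K):
            if eta[i, kk] > m:
                m = eta[i, kk]
        s = 0.0
        for kk in range(K):
            s += np.exp(eta[i, kk] - m)
        out[i] = np.exp(eta[i, k] - m) / s


@njit(cache=False)
def _cd_class(Xs, w, r, beta_k, b0k, penal, lam_n, active_only, active, tol,
              max_sweeps):
    """Coordinate descent on one class's coefficients given IRLS weights.

    Updates beta_k / the residual r in place; returns (new intercept,
    max coefficient change seen)."""
    n, p = Xs.shape
    dmax_total = 0.0
    for _ in range(max_sweeps):
        dmax = 0.0
        # intercept (never penalised)
        num = 0.0
        den = 0.0
        for i in range(n):
            num += w[i] * r[i]
            den += w[i]
        db = num / den
        b0k += db
        for i in range(n):
            r[i] -= db
        if abs(db) > dmax:
            dmax = abs(db)
        for j in range(p):
            if active_only and not active[j]:
                continue
            bj = beta_k[j]
            num = 0.0
            den = 0.0
            for i in range(n):
                xij = Xs[i, j]
                wi = w[i]
                num += wi * xij * r[i]
                den += wi * xij * xij
            if den <= 1e-12:
                continue
            num += bj * den
            if penal[j]:
                if num > lam_n:
                    new = (num - lam_n) / den
                elif num < -lam_n:
                    new = (num + lam_n) / den
                else:
                    new = 0.0
            else:
                new = num / den
            d = new - bj
            if d != 0.0:
                beta_k[j] = new
                active[j] = new != 0.0 or not penal[j]
                for i in range(n):
                    r[i] -= d * Xs[i, j]
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        if dmax > dmax_total:
            dmax_total = dmax
        if dmax < tol:
            break
    return b0k, dmax_total


@njit(cache=False)
def _recenter(beta, b0, penal):
    """Remove the softmax-invariant shift directions: mean-centre the
    intercepts and every unpenalised column's coefficients across classes."""
    K = b0.shape[0]
    p = beta.shape[0]
    m = 0.0
    for k in range(K):
        m += b0[k]
    m /= K
    for k in range(K):
        b0[k] -= m
    for j in range(p):
        if not penal[j]:
            mj = 0.0
            for k in range(K):
                mj += beta[j, k]
            mj /= K
            for k in range(K):
                beta[j, k] -= mj


@njit(cache=False)
def _fit_lambda(Xs, Y, penal, lam, beta, b0, tol, max_outer):
    """Partial-Newton / coordinate-descent fit at one lambda (warm start in
    beta, b0). Returns (n_outer, converged flag).

    Convergence is judged on the identifiability-centred coefficients:
    shifts along softmax-invariant directions (intercepts, unpenalised
    columns) are removed each outer iteration before comparing."""
    n, p = Xs.shape
    K = Y.shape[1]
    _recenter(beta, b0, penal)
    eta = np.empty((n, K))
    for i in range(n):
        for k in range(K):
            s = b0[k]
            for j in range(p):
                if beta[j, k] != 0.0:
                    s += Xs[i, j] * beta[j, k]
            eta[i, k] = s
    pk = np.empty(n)
    r = np.empty(n)
    w = np.empty(n)
    active = np.empty(p, dtype=np.bool_)
    beta_prev = beta.copy()
    b0_prev = b0.copy()
    lam_n = lam * n
    obj_prev = np.inf
    for outer in range(max_outer):
        for k in range(K):
            _softmax_col(eta, k, pk)
            for i in range(n):
                # fitted probabilities outside [PMIN, 1-PMIN] are snapped to
                # 0/1 with a floor weight: a perfectly fitted point then has
                # zero working residual, so separation cannot diverge
                pik = pk[i]
                if pik < _PMIN:
                    pik = 0.0
                    w[i] = _PMIN
                elif pik > 1.0 - _PMIN:
                    pik = 1.0
                    w[i] = _PMIN
                else:
                    w[i] = pik * (1.0 - pik)
                r[i] = (Y[i, k] - pik) / w[i]
            for j in range(p):
                active[j] = beta[j, k] != 0.0 or not penal[j]
            # one full sweep to find the active set, then active-set sweeps,
            # then a full sweep to catch violations
            b0[k], _ = _cd_class(Xs, w, r, beta[:, k], b0[k], penal, lam_n,
                                 False, active, tol, 1)
            b0[k], _ = _cd_class(Xs, w, r, beta[:, k], b0[k], penal, lam_n,
                                 True, active, tol, 50)
            b0[k], _ = _cd_class(Xs, w, r, beta[:, k], b0[k], penal, lam_n,
                                 False, active, tol, 1)
            b0[k], _ = _cd_class(Xs, w, r, beta[:, k], b0[k], penal, lam_n,
                                 True, active, tol, 50)
            for i in range(n):
                s = b0[k]
                for j in range(p):
                    if beta[j, k] != 0.0:
                        s += Xs[i, j] * beta[j, k]
                eta[i, k] = s
        _recenter(beta, b0, penal)
        # eta must track the centred parameters
        for i in range(n):
            for k in range(K):
                s = b0[k]
                for j in range(p):
                    if beta[j, k] != 0.0:
                        s += Xs[i, j] * beta[j, k]
                eta[i, k] = s
        dmax = 0.0
        for k in range(K):
            d = abs(b0[k] - b0_prev[k])
            if d > dmax:
                dmax = d
            for j in range(p):
                d = abs(beta[j, k] - beta_prev[j, k])
                if d > dmax:
                    dmax = d
        if dmax < tol:
            return outer + 1, True, dmax
        # penalised objective; a flat objective under oscillating weights
        # (points crossing the probability snap boundary) is also converged
        obj = 0.0
        for i in range(n):
            m = eta[i, 0]
            for k in range(1, K):
                if eta[i, k] > m:
                    m = eta[i, k]
            s = 0.0
            ey = 0.0
            for k in range(K):
                s += np.exp(eta[i, k] - m)
                if Y[i, k] == 1.0:
                    ey = eta[i, k]
            obj -= ey - m - np.log(s)
        obj /= n
        for j in range(p):
            if penal[j]:
                for k in range(K):
                    obj += lam * abs(beta[j, k])
        if abs(obj_prev - obj) < 1e-8 * (abs(obj) + 1.0):
            return outer + 1, True, dmax
        obj_prev = obj
        for k in range(K):
            b0_prev[k] = b0[k]
            for j in range(p):
                beta_prev[j, k] = beta[j, k]
    # report the final oscillation amplitude so the caller can judge
    dmax = 0.0
    for k in range(K):
        d = abs(b0[k] - b0_prev[k])
        if d > dmax:
            dmax = d
        for j in range(p):
            d = abs(beta[j, k] - beta_prev[j, k])
            if d > dmax:
                dmax = d
    return max_outer, False, dmax


@dataclass
class LassoMultinomialFit:
    """One lasso-multinomial solution (coefficients on the standardised scale)."""

    classes: list[str]
    column_ids: list[str]
    penalty_mask: np.ndarray
    intercepts: np.ndarray        # K
    coefficients: np.ndarray      # p x K, standardised-column scale
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    lam: float
    converged: bool

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.scaler_mean) / self.scaler_sd
        eta = self.intercepts + Xs @ self.coefficients
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(self.classes)[self.predict_proba(X).argmax(axis=1)]

    def selected_features(self, tol: float = 0.0) -> list[str]:
        """Penalised columns with a nonzero coefficient in any class."""
        nz = np.abs(self.coefficients).max(axis=1) > tol
        return [c for c, pen, f in zip(self.column_ids, self.penalty_mask, nz)
                if pen and f]


def _standardize(X: np.ndarray, mask: np.ndarray):
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    mean[mask] = X[:, mask].mean(axis=0)
    s = X[:, mask].std(axis=0, ddof=0)
    s[s == 0] = 1.0  # constant columns can never be selected anyway
    sd[mask] = s
    return (X - mean) / sd, mean, sd


def _one_hot(labels, classes) -> np.ndarray:
    idx = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def _normalise_identifiability(b0, beta, penal):
    """Mean-centre across classes the intercept and unpenalised columns
    (softmax-invariant shifts) so solutions are deterministic."""
    b0 -= b0.mean()
    free = ~penal
    if free.any():
        beta[free, :] -= beta[free, :].mean(axis=1, keepdims=True)


def lambda_max(Xs: np.ndarray, Y: np.ndarray, penal: np.ndarray,
               b0: np.ndarray, beta_free: np.ndarray) -> float:
    """Smallest lambda zeroing all penalised coefficients (KKT at the null
    model, which includes intercepts and unpenalised columns)."""
    n = Xs.shape[0]
    eta = b0 + Xs @ beta_free
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    G = Xs[:, penal].T @ (Y - P) / n
    return float(np.abs(G).max())


def fit_lasso_multinomial(space: FeatureSpace, labels, lam: float,
                          classes: list[str] | None = None,
                          warm: LassoMultinomialFit | None = None,
                          tol: float = 1e-4,
                          max_outer: int = 100) -> LassoMultinomialFit:
    """Fit at one lambda. Columns are standardised internally on the data
    given (so pass the training split only)."""
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    labels = list(labels)
    if classes is None:
        classes = sorted(set(labels))
    if len(set(labels)) < 2:
        raise ValidationError("need >= 2 classes in the training data")
    X = space.matrix
    penal = space.penalty_mask
    n, p = X.shape
    if lam == 0 and np.sum(penal) >= n:
        raise ValidationError("lambda = 0 requires p < n on penalised columns")
    Xs, mean, sd = _standardize(X, penal)
    Y = _one_hot(labels, classes)
    K = len(classes)
    if warm is not None:
        beta = warm.coefficients.copy()
        b0 = warm.intercepts.copy()
    else:
        beta = np.zeros((p, K))
        freq = np.clip(Y.mean(axis=0), 1e-12, None)
        b0 = np.log(freq) - np.log(freq).mean()
    n_outer, converged, dmax = _fit_lambda(Xs, Y, penal, lam, beta, b0, tol,
                                           max_outer)
    if not converged and dmax > 100 * tol:
        # a genuine failure to make progress, not a weight-snap limit cycle
        raise RuntimeError(
            f"coordinate descent did not converge at lambda={lam:g} "
            f"after {max_outer} outer iterations (last max coefficient "
            f"change {dmax:.2e})"
        )
    # exact zeros for coefficients at/below the KKT boundary noise floor
    beta[np.abs(beta) < 1e-12] = 0.0
    _normalise_identifiability(b0, beta, penal)
    return LassoMultinomialFit(list(classes), list(space.column_ids),
                               penal.copy(), b0, beta, mean, sd, lam, True)


def multinomial_gradient(fit: LassoMultinomialFit, space: FeatureSpace,
                         labels) -> np.ndarray:
    """(1/N) X_std^T (P - Y): the KKT gradient on the standardised scale."""
    Xs = (space.matrix - fit.scaler_mean) / fit.scaler_sd
    Y = _one_hot(list(labels), fit.classes)
    P = fit.predict_proba(space.matrix)
    return Xs.T @ (P - Y) / Xs.shape[0]


# ---------------------------------------------------------------------------
# cross-validated lambda path
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    lambda_grid: np.ndarray
    coefficients: np.ndarray       # n_lambda x p x K (full-data fits)
    intercepts: np.ndarray         # n_lambda x K
    cv_deviance: np.ndarray        # mean CV multinomial deviance per lambda
    lambda_selected: float
    selected_index: int
    fits: list = field(default_factory=list, repr=False)

    @property
    def selected_fit(self) -> LassoMultinomialFit:
        return self.fits[self.selected_index]


def _path_grid(space, labels, classes, n_lambda, eps) -> np.ndarray:
    Xs, _, _ = _standardize(space.matrix, space.penalty_mask)
    Y = _one_hot(list(labels), classes)
    # null model: intercepts + unpenalised columns only
    null = fit_lasso_multinomial(space, labels, lam=1e30, classes=classes)
    lmax = lambda_max(Xs, Y, space.penalty_mask, null.intercepts,
                      null.coefficients)
    return np.geomspace(lmax, eps * lmax, n_lambda)


def _fit_path(space, labels, classes, grid) -> list[LassoMultinomialFit]:
    fits = []
    warm = None
    for lam in grid:
        warm = fit_lasso_multinomial(space, labels, lam, classes=classes,
                                     warm=warm)
        fits.append(warm)
    return fits


def _subspace(space: FeatureSpace, rows: np.ndarray) -> FeatureSpace:
    return FeatureSpace(space.block, space.matrix[rows],
                        list(space.column_ids), space.penalty_mask.copy(),
                        [space.sample_ids[i] for i in rows])


def multinomial_deviance(fit: LassoMultinomialFit, X: np.ndarray,
                         labels) -> float:
    """-2 * mean log-probability of the true class."""
    P = fit.predict_proba(X)
    idx = {c: k for k, c in enumerate(fit.classes)}
    ll = np.log(np.clip(P[np.arange(len(labels)),
                          [idx[la] for la in labels]], 1e-12, None))
    return float(-2.0 * ll.mean())


def tune_lambda_cv(space: FeatureSpace, labels, n_folds: int = 10,
                   n_lambda: int = 100, eps: float = 0.01,
                   seed: int = 0) -> LassoPath:
    """Pick lambda minimising 10-fold cross-validated multinomial deviance.

    Folds are stratified by class; the grid runs log-spaced from the
    data-derived lambda_max down to eps * lambda_max; fold fits reuse the
    full-data grid (glmnet convention) and warm-start down the path.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    n = len(labels)
    if n < n_folds:
        raise ValidationError(f"need n >= {n_folds} samples for CV")
    grid = _path_grid(space, labels, classes, n_lambda, eps)
    y = np.array(labels)
    dev = np.zeros((n_folds, len(grid)))
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed + attempt)
        folds = list(skf.split(np.zeros(n), y))
        if all(len(set(y[tr])) == len(classes) for tr, _ in folds):
            break
    else:
        raise ValidationError(
            "could not stratify CV folds with every class in each training set"
        )
    for f, (tr, va) in enumerate(folds):
        sub = _subspace(space, tr)
        fits = _fit_path(sub, y[tr], classes, grid)
        for gi, fit in enumerate(fits):
            dev[f, gi] = multinomial_deviance(fit, space.matrix[va], y[va])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    full_fits = _fit_path(space, labels, classes, grid)
    coefs = np.stack([f.coefficients for f in full_fits])
    icpts = np.stack([f.intercepts for f in full_fits])
    return LassoPath(grid, coefs, icpts, mean_dev, float(grid[best]), best,
                     full_fits)


# ---------------------------------------------------------------------------
# resampling protocol
# ---------------------------------------------------------------------------

@dataclass
class SelectionProfile:
    """Aggregate of the R-replicate resampling protocol."""

    feature_ids: list[str]
    counts: np.ndarray            # selections per feature over R replicates
    frequencies: np.ndarray
    mean_abs_coef: np.ndarray     # mean |coefficient| when selected (tie-break)
    overall_accuracy: np.ndarray  # per replicate
    per_class_accuracy: pd.DataFrame  # R x K, NaN when class absent from test
    R: int

    def summary(self) -> pd.DataFrame:
        rows = [{"label": "all",
                 "accuracy": float(np.mean(self.overall_accuracy)),
                 "std": float(np.std(self.overall_accuracy, ddof=1))}]
        for cls in self.per_class_accuracy.columns:
            acc = self.per_class_accuracy[cls].dropna()
            rows.append({"label": cls, "accuracy": float(acc.mean()),
                         "std": float(acc.std(ddof=1))})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "count": self.counts.astype(int),
            "frequency": self.frequencies,
            "mean_abs_coef": self.mean_abs_coef,
        }).sort_values(["frequency", "mean_abs_coef", "feature_id"],
                       ascending=[False, False, True]).reset_index(drop=True)


def resample_evaluate(space: FeatureSpace, labels, R: int = 150,
                      test_fraction: float = 0.1, seed: int = 0,
                      n_folds: int = 10, n_lambda: int = 100,
                      stratify: bool = False) -> SelectionProfile:
    """The replicated split / tune / refit / score protocol.

    Each replicate holds out ``test_fraction`` of the samples, tunes
    lambda by ``n_folds``-fold CV on the rest, refits there, and records
    test accuracy plus the features with any nonzero coefficient.

    Test splits are simple random draws by default. Stratified splits are
    available (``stratify=True``) but bias the protocol's permutation null
    below chance: with near-balanced classes the training majority is
    systematically the class under-represented in the stratified test set,
    so a no-signal model scores ~1/(test size) instead of ~1/K. CV folds
    within the training set are always stratified, which a valid
    multinomial fit needs at this sample size.
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    labels = np.array(list(labels))
    classes = sorted(set(labels))
    feats = space.feature_ids
    fidx = {f: i for i, f in enumerate(feats)}
    pen_rows = np.flatnonzero(space.penalty_mask)
    counts = np.zeros(len(feats))
    coef_sum = np.zeros(len(feats))
    overall = np.zeros(R)
    per_class = np.full((R, len(classes)), np.nan)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=R)
    n = len(labels)
    for rep in range(R):
        rs = int(rep_seeds[rep])
        if stratify:
            sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                         random_state=rs)
            tr, te = next(sss.split(np.zeros(n), labels))
        else:
            perm = np.random.default_rng(rs).permutation(n)
            n_test = max(1, int(round(test_fraction * n)))
            te, tr = perm[:n_test], perm[n_test:]
            if len(set(labels[tr])) < 2:
                raise ValidationError("training split lost all but one class")
        path = tune_lambda_cv(_subspace(space, tr), labels[tr],
                              n_folds=n_folds, n_lambda=n_lambda, seed=rs)
        fit = path.selected_fit
        pred = fit.predict(space.matrix[te])
        truth = labels[te]
        overall[rep] = float(np.mean(pred == truth))
        for k, cls in enumerate(classes):
            m = truth == cls
            if m.any():
                per_class[rep, k] = float(np.mean(pred[m] == truth[m]))
        sel = fit.selected_features()
        abs_coef = np.abs(fit.coefficients[pen_rows]).mean(axis=1)
        for f in sel:
            counts[fidx[f]] += 1
        coef_sum += abs_coef * (np.abs(fit.coefficients[pen_rows]).max(axis=1)
                                > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs = np.where(counts > 0, coef_sum / counts, 0.0)
    return SelectionProfile(
        feature_ids=list(feats),
        counts=counts,
        frequencies=counts / R,
        mean_abs_coef=mean_abs,
        overall_accuracy=overall,
        per_class_accuracy=pd.DataFrame(per_class, columns=classes),
        R=R,
    )


def top_predictors(profile: SelectionProfile, k: int = 20) -> list[str]:
    """Top-k features by selection frequency; ties broken by mean absolute
    coefficient, then lexicographic id."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    ranked = profile.to_frame()
    ever = ranked[ranked["count"] > 0]
    if k > len(ranked):
        import warnings
        warnings.warn(f"k={k} exceeds feature count {len(ranked)}; "
                      "returning all ever-selected features", stacklevel=2)
        return list(ever["feature_id"])
    # never-selected features are not predictors, whatever k says
    return list(ever["feature_id"].head(k))
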