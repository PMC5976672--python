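"""Per-feature differential expression for the two omics blocks.

miRNA counts: negative-binomial GLM with log link,
log mu = intercept + status + centre + log-library-size offset, count
variance mu * (1 + phi * mu). Coefficients are fit by IRLS at fixed phi;
the feature-specific dispersion phi is estimated by maximising the
Cox-Reid adjusted profile likelihood (the adjustment corrects the downward
bias of the plain profile MLE at small n). Significance of the status term
is a likelihood-ratio test against the reduced model without status, fit at
the full model's dispersion so the models are properly nested; the
statistic is referred to chi-square with df = #status levels - 1.

Protein log abundances: per-protein multinomial logistic regression of
class membership on centre and the protein value (reference class
"control"); dropping the protein term gives an LRT with df = K - 1.

Multiple testing: Storey q-values with the pi0 smoother (BH available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .datamodel import OmicsMatrix, SampleSheet, Scale, ValidationError

_LN2 = np.log(2.0)
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix(sheet: SampleSheet, include_status: bool = True,
                  extra: np.ndarray | None = None):
    """Intercept + status indicators (ref = first level) + centre indicators
    (ref = alphabetically first) + optional extra column.

    Returns (X, column_names).
    """
    n = len(sheet)
    cols = [np.ones(n)]
    names = ["intercept"]
    if include_status:
        for lv in sheet.status_levels[1:]:
            cols.append(np.array([1.0 if s == lv else 0.0
                                  for s in sheet.status]))
            names.append(f"status[{lv}]")
    centre_levels = sorted(set(sheet.centre))
    for lv in centre_levels[1:]:
        cols.append(np.array([1.0 if c == lv else 0.0 for c in sheet.centre]))
        names.append(f"centre[{lv}]")
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
        names.append("extra")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# negative-binomial GLM
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    coefficients: dict[str, float]
    dispersion: float
    log_likelihood: float
    converged: bool
    column_names: list[str] = field(default_factory=list)
    beta: np.ndarray | None = None


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood in the mean/dispersion parameterisation."""
    mu = np.clip(mu, 1e-12, None)
    if phi < 1e-8:  # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / phi
    return float(np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - inv * np.log1p(phi * mu)
    ))


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
          max_iter: int = 60, tol: float = 1e-9):
    """IRLS for the NB log-link GLM at fixed dispersion.

    Returns (beta, loglik, converged, W) with W the final IRLS weights.
    """
    n, q = X.shape
    # start from an intercept matching the offset-adjusted mean
    beta = np.zeros(q)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-12))
    ll_old = -np.inf
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, nb_loglik(y, mu, phi), False, w
        step = 1.0
        ll_new = -np.inf
        for _ in range(8):  # halve until the likelihood does not decrease
            cand = beta + step * (beta_new - beta)
            mu_c = np.exp(np.clip(X @ cand + offset, -_ETA_CLIP, _ETA_CLIP))
            ll_new = nb_loglik(y, mu_c, phi)
            if ll_new >= ll_old - 1e-12:
                beta = cand
                break
            step *= 0.5
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + phi * mu)
    return beta, nb_loglik(y, mu, phi), converged, w


def _cox_reid_apl(y, X, offset, phi) -> float:
    """Cox-Reid adjusted profile log-likelihood of phi."""
    beta, ll, _, w = _irls(y, X, offset, phi)
    xtwx = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def estimate_dispersion(y: np.ndarray, X: np.ndarray,
                        offset: np.ndarray) -> float:
    """Maximise the Cox-Reid APL over log-dispersion (bounded search)."""
    res = optimize.minimize_scalar(
        lambda t: -_cox_reid_apl(y, X, offset, np.exp(t)),
        bounds=(np.log(1e-6), np.log(30.0)), method="bounded",
        options={"xatol": 0.02},
    )
    phi = float(np.exp(res.x))
    # the boundary is effectively Poisson
    return 0.0 if phi < 2e-6 else phi


def fit_nb_glm(counts_row: np.ndarray, sheet: SampleSheet,
               offsets: np.ndarray, include_status: bool = True,
               dispersion: float | None = None) -> NBFit:
    """Fit the NB GLM for one feature; estimates phi by Cox-Reid APL unless given."""
    y = np.asarray(counts_row, dtype=float)
    if y.max() <= 0:
        raise ValidationError("feature has no positive counts")
    X, names = design_matrix(sheet, include_status=include_status)
    if dispersion is None:
        dispersion = estimate_dispersion(y, X, offsets)
    beta, ll, converged, _ = _irls(y, X, offsets, dispersion)
    return NBFit(dict(zip(names, beta)), dispersion, ll, converged, names, beta)


def lrt_status(full: NBFit, reduced: NBFit,
               df: int = 2) -> tuple[float, int, float]:
    """LRT of the status term: 2 * (ll_full - ll_reduced), chi-square df."""
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        # nested models cannot do this; flag by NaN p rather than lie
        return 0.0, df, float("nan")
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# multinomial logistic model for proteins
# ---------------------------------------------------------------------------

@dataclass
class MultinomFit:
    coefficients: np.ndarray   # (K-1, q), reference class fixed at zero
    log_likelihood: float
    converged: bool
    classes: list[str] = field(default_factory=list)
    column_names: list[str] = field(default_factory=list)


def _multinom_nll_grad(theta, X, Y, ridge=0.0):
    """Reference-coded multinomial NLL and gradient.

    theta flattens a (K-1, q) matrix; class 0 is the reference with eta=0.
    """
    n, q = X.shape
    km1 = Y.shape[1] - 1
    B = theta.reshape(km1, q)
    eta = np.column_stack([np.zeros(n), X @ B.T])       # n x K
    lse = logsumexp(eta, axis=1)
    ll = float(np.sum(eta[Y.astype(bool)]) - lse.sum())
    P = np.exp(eta - lse[:, None])
    G = (P[:, 1:] - Y[:, 1:]).T @ X                     # (K-1, q)
    nll = -ll + 0.5 * ridge * float(theta @ theta)
    return nll, G.ravel() + ridge * theta


def fit_multinomial(X: np.ndarray, labels: list[str], classes: list[str],
                    ridge: float = 0.0) -> MultinomFit:
    """Maximum-likelihood multinomial logit (reference = classes[0])."""
    n, q = X.shape
    K = len(classes)
    idx = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((n, K))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    x0 = np.zeros((K - 1) * q)
    res = optimize.minimize(_multinom_nll_grad, x0, args=(X, Y, ridge),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})
    converged = bool(res.success)
    if not converged and ridge == 0.0:
        # quasi-separation: stabilise with a tiny ridge and flag it
        res = optimize.minimize(_multinom_nll_grad, res.x, args=(X, Y, 1e-6),
                                jac=True, method="L-BFGS-B",
                                options={"maxiter": 1000})
    ll = -_multinom_nll_grad(res.x, X, Y, 0.0)[0]
    return MultinomFit(res.x.reshape(K - 1, q), ll, converged, list(classes))


def predict_multinomial(fit: MultinomFit, X: np.ndarray) -> np.ndarray:
    """Class probabilities (softmax over the reference-coded linear predictors)."""
    n = X.shape[0]
    eta = np.column_stack([np.zeros(n), X @ fit.coefficients.T])
    return np.exp(eta - logsumexp(eta, axis=1)[:, None])


def fit_protein_multinomial(protein_row: np.ndarray, sheet: SampleSheet,
                            include_protein: bool = True) -> MultinomFit:
    """Class ~ centre (+ protein log abundance) multinomial fit for one protein."""
    classes = [lv for lv in sheet.status_levels if lv in set(sheet.status)]
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes for the multinomial model")
    extra = np.asarray(protein_row, dtype=float) if include_protein else None
    X, names = design_matrix(sheet, include_status=False, extra=extra)
    fit = fit_multinomial(X, sheet.status, classes)
    fit.column_names = names
    return fit


def lrt_protein(full: MultinomFit,
                reduced: MultinomFit) -> tuple[float, int, float]:
    """LRT for the protein term: df = K - 1 (one coefficient per non-reference class)."""
    df = len(full.classes) - 1
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def estimate_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """Storey q-values (pi0 by the cubic smoother) or Benjamini-Hochberg.

    q-values are monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values given")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        lambdas = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        if m < 100:
            # too few tests for the smoother to be stable
            pi0 = 1.0
        else:
            coef = np.polynomial.polynomial.polyfit(lambdas, pi0_lam, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def log2_fold_changes(fit_or_means) -> dict[str, float]:
    """Per-contrast log2 fold-changes.

    Accepts either an NBFit (status coefficients on the natural-log scale)
    or a mapping {status level: natural-log-scale group mean}.
    """
    if isinstance(fit_or_means, NBFit):
        gd = fit_or_means.coefficients.get("status[GD]", 0.0)
        go = fit_or_means.coefficients.get("status[GO]", 0.0)
    else:
        means = dict(fit_or_means)
        ref = means.get("control", 0.0)
        gd = means.get("GD", ref) - ref
        go = means.get("GO", ref) - ref
    return {
        "log2fc_GD_vs_control": gd / _LN2,
        "log2fc_GO_vs_control": go / _LN2,
        "log2fc_GO_vs_GD": (go - gd) / _LN2,
    }


# ---------------------------------------------------------------------------
# block-level drivers
# ---------------------------------------------------------------------------

def run_de_mirna(counts: OmicsMatrix, sheet: SampleSheet,
                 lib_sizes: np.ndarray | None = None,
                 qvalue_method: str = "storey") -> pd.DataFrame:
    """NB-GLM LRT for every miRNA in a filtered raw-count matrix.

    Returns a DataFrame (feature_id, lrt_statistic, df, p_value, q_value,
    log2fc per contrast, dispersion, converged) sorted by q-value.
    Non-converged or degenerate features carry NaN p and are excluded from
    the q-value calibration.
    """
    if counts.scale is not Scale.RAW_COUNTS:
        raise ValidationError("DE models raw filtered counts")
    sheet.require_classes(2)
    mat = counts.reorder_samples(list(sheet.sample_ids))
    if lib_sizes is None:
        lib_sizes = mat.values.sum(axis=0)
    offsets = np.log(np.asarray(lib_sizes, dtype=float))
    rows = []
    for i, fid in enumerate(mat.feature_ids):
        y = mat.values[i]
        if y.max() <= 0:
            rows.append(_na_row(fid))
            continue
        full = fit_nb_glm(y, sheet, offsets)
        reduced = fit_nb_glm(y, sheet, offsets, include_status=False,
                             dispersion=full.dispersion)
        stat, df, p = lrt_status(full, reduced)
        ok = full.converged and reduced.converged and np.isfinite(p)
        row = {"feature_id": fid, "lrt_statistic": stat, "df": df,
               "p_value": p if ok else np.nan, "dispersion": full.dispersion,
               "converged": ok}
        row.update(log2_fold_changes(full))
        rows.append(row)
    return _finalise(pd.DataFrame(rows), qvalue_method)


def run_de_protein(log_abund: OmicsMatrix, sheet: SampleSheet,
                   qvalue_method: str = "storey") -> pd.DataFrame:
    """Multinomial-logit LRT for every protein in a filtered log-abundance matrix."""
    if log_abund.scale is not Scale.LOG_ABUNDANCE:
        raise ValidationError("protein DE models log abundances")
    sheet.require_classes(2)
    mat = log_abund.reorder_samples(list(sheet.sample_ids))
    status = np.array(sheet.status)
    rows = []
    for i, fid in enumerate(mat.feature_ids):
        x = mat.values[i]
        if np.ptp(x) == 0:
            rows.append(_na_row(fid))
            continue
        full = fit_protein_multinomial(x, sheet)
        reduced = fit_protein_multinomial(x, sheet, include_protein=False)
        stat, df, p = lrt_protein(full, reduced)
        means = {lv: float(x[status == lv].mean())
                 for lv in sheet.status_levels if np.any(status == lv)}
        row = {"feature_id": fid, "lrt_statistic": stat, "df": df,
               "p_value": p, "dispersion": np.nan,
               "converged": full.converged and reduced.converged}
        row.update(log2_fold_changes(means))
        rows.append(row)
    return _finalise(pd.DataFrame(rows), qvalue_method)


def _na_row(fid: str) -> dict:
    out = {"feature_id": fid, "lrt_statistic": np.nan, "df": 2,
           "p_value": np.nan, "dispersion": np.nan, "converged": False}
    out.update({k: np.nan for k in ("log2fc_GD_vs_control",
                                    "log2fc_GO_vs_control",
                                    "log2fc_GO_vs_GD")})
    return out


def _finalise(df: pd.DataFrame, qvalue_method: str) -> pd.DataFrame:
    ok = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = estimate_qvalues(df.loc[ok, "p_value"].to_numpy(),
                                            method=qvalue_method)
    df = df.assign(q_value=q)
    return df.sort_values(["q_value", "p_value", "feature_id"],
                          na_position="last").reset_index(drop=True)
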