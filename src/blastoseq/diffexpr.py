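"""Negative-binomial differential expression with unwanted-variation factors.

A self-contained reimplementation of the model class used throughout the
analysis: median-of-ratios size factors, per-gene NB log-link GLMs with
arbitrary covariate columns (DNA-contamination FPKM, batch, latent W
factors), gene-wise Cox–Reid-adjusted ML dispersion shrunk toward a fitted
mean–dispersion trend, Wald tests on the condition coefficient,
Benjamini–Hochberg correction and independent filtering, plus the
supporting utilities: TPM, control-gene selection, RUV-style factor
estimation from negative controls, and top-variance PCA.

The model for gene g, sample j:

    K_gj ~ NB(mean = s_j * q_gj, dispersion = alpha_g)
    log q_gj = x_j' beta_g                      (s_j enters as an offset)

Wald inference uses z = beta_hat / SE(beta_hat) on the condition
coefficient, referred to a t distribution with n - p degrees of freedom
(the package's finite-sample choice; with many covariates and ~20 samples
the normal reference is visibly anticonservative). Fold changes are
reported as unshrunken MLEs on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import t as t_dist

__all__ = [
    "SizeFactorError",
    "size_factors_median_ratios",
    "normalized_counts",
    "tpm",
    "nb_wald_test",
    "bh_adjust",
    "independent_filtering",
    "select_control_genes",
    "ruv_factors",
    "RuvFactors",
    "pca_embed",
]

_MIN_DISP, _MAX_DISP = 1e-8, 10.0


class SizeFactorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization


def size_factors_median_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features (positive in every sample) of
    count_ij / geometric-mean_i. A single sample gets size factor 1 by
    convention.
    """
    if counts.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns)
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise SizeFactorError(
            "no feature has positive counts in all samples; consider a "
            "pseudo-reference fallback (not enabled by default)"
        )
    logs = np.log(mat[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns)


def normalized_counts(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = size_factors_median_ratios(counts)
    return counts.div(size_factors, axis=1)


def tpm(counts: pd.DataFrame, length_kb: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-first normalization, each sample
    summing to 1e6 (all-zero samples stay zero, with a warning)."""
    length_kb = length_kb.reindex(counts.index)
    if (length_kb <= 0).any() or length_kb.isna().any():
        raise ValueError("feature lengths must be > 0 for all features")
    rate = counts.div(length_kb, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero samples in TPM: {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    out = rate.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes; X is shared)


def _irls(Y, X, offset, alpha, n_iter=60, tol=1e-10):
    """Per-gene NB IRLS with shared design. Y (G,n), alpha (G,). Returns
    beta (G,p), mu (G,n), converged (G,)."""
    G, n = Y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)  # (p, n)
    init = np.log(Y + 0.5) - offset[None, :]
    beta = init @ pinv.T
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-9 * np.eye(p)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -60.0, 60.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", W, X, X) + ridge
        b = np.einsum("gn,gn,ni->gi", W, z, X)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        converged |= delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -60.0, 60.0)
    return beta, np.exp(eta), converged


def _nb_loglik(Y, mu, alpha):
    """Profile NB log-likelihood per gene. alpha (G,1) broadcastable."""
    r = 1.0 / alpha
    return (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu))
    ).sum(axis=1)


def _cr_term(X, mu, alpha):
    """Cox–Reid adjustment −0.5 log det(X' W X) per gene."""
    W = mu / (1.0 + alpha * mu)
    A = np.einsum("gn,ni,nj->gij", W, X, X)
    sign, logdet = np.linalg.slogdet(A)
    return -0.5 * logdet


def _disp_objective(log_alpha, Y, mu, X, prior=None):
    alpha = np.exp(log_alpha)[:, None]
    obj = _nb_loglik(Y, mu, alpha) + _cr_term(X, mu, alpha)
    if prior is not None:
        lt, s2 = prior
        obj = obj - (log_alpha - lt) ** 2 / (2.0 * s2)
    return obj


def _maximize_dispersion(Y, mu, X, prior=None, grid_size=40, refine=30):
    """Vectorized grid + golden-section maximization over log dispersion."""
    G = Y.shape[0]
    grid = np.linspace(np.log(_MIN_DISP), np.log(_MAX_DISP), grid_size)
    vals = np.stack([_disp_objective(np.full(G, la), Y, mu, X, prior) for la in grid])
    best = np.argmax(vals, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid_size - 1)]
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = _disp_objective(c, Y, mu, X, prior)
    fd = _disp_objective(d, Y, mu, X, prior)
    for _ in range(refine):
        take_c = fc > fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = _disp_objective(c, Y, mu, X, prior)
        fd = _disp_objective(d, Y, mu, X, prior)
    return np.exp((a + b) / 2.0)


def _fit_dispersion_trend(alpha_gw, base_mean):
    """Parametric trend a(mu) = a0 + a1/mu by iterative gamma-weighted LS."""
    ok = (alpha_gw > _MIN_DISP * 10) & (base_mean > 0)
    a = alpha_gw[ok]
    m = base_mean[ok]
    if ok.sum() < 10:
        med = float(np.median(alpha_gw)) if len(alpha_gw) else 0.1
        return lambda mu: np.full_like(np.asarray(mu, dtype=float), max(med, 1e-6))
    Xt = np.column_stack([np.ones_like(m), 1.0 / m])
    fitted = np.full_like(a, a.mean())
    coef = np.array([a.mean(), 0.0])
    for _ in range(8):
        w = 1.0 / np.maximum(fitted, 1e-8) ** 2
        WX = Xt * w[:, None]
        coef_new, *_ = np.linalg.lstsq(WX.T @ Xt, WX.T @ a, rcond=None)
        coef_new = np.maximum(coef_new, [1e-8, 0.0])
        fitted = Xt @ coef_new
        ratio = a / np.maximum(fitted, 1e-12)
        keep = (ratio < 15) & (ratio > 1e-4)
        if keep.sum() >= 10:
            Xt, a, fitted = Xt[keep], a[keep], fitted[keep]
        if np.allclose(coef_new, coef, rtol=1e-6):
            coef = coef_new
            break
        coef = coef_new
    a0, a1 = coef
    return lambda mu: a0 + a1 / np.maximum(np.asarray(mu, dtype=float), 1e-8)


def build_design(meta: pd.DataFrame, condition: str, covariates: list[str] | None = None):
    """Intercept + numeric covariates + a 0/1 condition indicator (tested
    coefficient last). Two-level condition columns are indicator-coded."""
    covariates = covariates or []
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for c in covariates:
        v = meta[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(pd.unique(v))
            for lv in levels[1:]:
                cols.append((v == lv).to_numpy(dtype=float))
                names.append(f"{c}_{lv}")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    cond = meta[condition]
    levels = sorted(pd.unique(cond))
    if len(levels) != 2:
        raise ValueError(f"condition {condition} must have exactly 2 levels, got {levels}")
    cols.append((cond == levels[1]).to_numpy(dtype=float))
    names.append(f"{condition}_{levels[1]}_vs_{levels[0]}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X, names


def nb_wald_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str,
    covariates: list[str] | None = None,
    size_factors: pd.Series | None = None,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the condition coefficient.

    Returns a DEResult frame indexed by feature with columns ``baseMean``
    (mean normalized count), ``log2FC`` (unshrunken MLE), ``lfcSE``,
    ``stat``, ``pvalue`` and ``padj`` (plain BH; use
    :func:`independent_filtering` to refresh padj under filtering).
    Features whose fit fails get NA p-values and are excluded from the BH
    denominator.
    """
    meta = meta.loc[counts.columns]
    X, names = build_design(meta, condition, covariates)
    n, p = X.shape
    if (meta.groupby(condition).size() < 2).any():
        raise ValueError("need >= 2 samples per condition level")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")

    if size_factors is None:
        size_factors = size_factors_median_ratios(counts)
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(sf)
    Y = counts.to_numpy(dtype=float)
    base_mean = (Y / sf[None, :]).mean(axis=1)

    usable = Y.sum(axis=1) > 0
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": np.nan,
            "lfcSE": np.nan,
            "stat": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
            "converged": False,
        },
        index=counts.index,
    )
    if usable.sum() == 0:
        return res

    Yu = Y[usable]
    bm = base_mean[usable]
    # moment initialization of dispersion from normalized counts
    norm = Yu / sf[None, :]
    v = norm.var(axis=1, ddof=1)
    m = norm.mean(axis=1)
    alpha0 = np.clip((v - m) / np.maximum(m, 1e-8) ** 2, 0.01, _MAX_DISP)

    beta, mu, conv = _irls(Yu, X, offset, alpha0)
    alpha_gw = _maximize_dispersion(Yu, mu, X)
    beta, mu, conv = _irls(Yu, X, offset, alpha_gw)

    if shrink_dispersion and usable.sum() >= 20:
        trend = _fit_dispersion_trend(alpha_gw, bm)
        log_trend = np.log(np.maximum(trend(bm), _MIN_DISP))
        lr = np.log(np.maximum(alpha_gw, _MIN_DISP)) - log_trend
        mad = np.median(np.abs(lr - np.median(lr))) * 1.4826
        sampling_var = float(polygamma(1, max((n - p) / 2.0, 0.5)))
        prior_var = max(mad**2 - sampling_var, 0.25)
        alpha_final = _maximize_dispersion(Yu, mu, X, prior=(log_trend, prior_var))
        beta, mu, conv = _irls(Yu, X, offset, alpha_final)
    else:
        alpha_final = alpha_gw

    W = mu / (1.0 + alpha_final[:, None] * mu)
    A = np.einsum("gn,ni,nj->gij", W, X, X)
    cov = np.linalg.inv(A + 1e-12 * np.eye(p))
    se = np.sqrt(np.maximum(cov[:, -1, -1], 0.0))
    coef = beta[:, -1]
    stat = np.where(se > 0, coef / se, np.nan)
    pval = 2.0 * t_dist.sf(np.abs(stat), df=n - p)

    bad = ~np.isfinite(stat) | ~conv
    pval = np.where(bad, np.nan, pval)

    res.loc[counts.index[usable], "log2FC"] = coef / np.log(2.0)
    res.loc[counts.index[usable], "lfcSE"] = se / np.log(2.0)
    res.loc[counts.index[usable], "stat"] = stat
    res.loc[counts.index[usable], "pvalue"] = pval
    res.loc[counts.index[usable], "converged"] = conv & ~bad
    res["padj"] = bh_adjust(res["pvalue"])
    res.attrs["dispersion"] = pd.Series(alpha_final, index=counts.index[usable])
    res.attrs["coef_names"] = names
    return res


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues) -> pd.Series:
    """Benjamini–Hochberg step-up over non-NA entries; NA propagated."""
    p = pd.Series(pvalues, dtype=float)
    mask = p.notna()
    out = pd.Series(np.nan, index=p.index)
    x = p[mask].to_numpy()
    m = len(x)
    if m == 0:
        return out
    order = np.argsort(x, kind="mergesort")
    ranked = x[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[mask] = vals
    return out


def independent_filtering(results: pd.DataFrame, alpha: float = 0.05, step: float = 0.01) -> pd.DataFrame:
    """Mean-expression independent filtering before FDR adjustment.

    Scans baseMean-quantile thresholds 0..0.95 (``step`` increments); for
    each, BH is recomputed over surviving features and the threshold
    maximizing rejections at ``alpha`` wins (ties: lowest threshold).
    Filtered features get padj = NA and ``filtered`` = True.
    """
    res = results.copy()
    bm = res["baseMean"].to_numpy(dtype=float)
    qs = np.arange(0.0, 0.95 + 1e-9, step)
    thresholds = np.quantile(bm, qs)
    best_rej, best_thr = -1, thresholds[0]
    for thr in thresholds:
        mask = bm >= thr
        padj = bh_adjust(res["pvalue"].where(mask))
        rej = int((padj < alpha).sum())
        if rej > best_rej:
            best_rej, best_thr = rej, thr
    keep = bm >= best_thr
    res["filtered"] = ~keep
    res["padj"] = bh_adjust(res["pvalue"].where(keep))
    res.attrs["filter_threshold"] = float(best_thr)
    res.attrs["rejections"] = int(best_rej)
    return res


# ---------------------------------------------------------------------------
# control genes and unwanted-variation factors


def select_control_genes(
    results: list[pd.DataFrame],
    min_mean: float = 100.0,
    min_padj: float = 0.8,
    max_abs_lfc: float = 0.05,
    signed: bool = False,
) -> list[str]:
    """Empirical negative controls: stably expressed in every comparison.

    A gene qualifies iff in EVERY provided result frame: baseMean >
    ``min_mean``, padj > ``min_padj`` and |log2FC| < ``max_abs_lfc``
    (``signed=True`` switches to the literal signed reading
    log2FC < max_abs_lfc)."""
    if not results:
        raise ValueError("need at least one DEResult")
    sets = []
    for res in results:
        lfc = res["log2FC"] if signed else res["log2FC"].abs()
        ok = (res["baseMean"] > min_mean) & (res["padj"] > min_padj) & (lfc < max_abs_lfc)
        sets.append(set(res.index[ok.fillna(False)]))
    controls = sorted(set.intersection(*sets))
    if not controls:
        raise ValueError("empty control set; relax the selection thresholds")
    return controls


@dataclass
class RuvFactors:
    W: pd.DataFrame  # samples x k
    control_ids: list[str]
    singular_values: np.ndarray


def ruv_factors(
    counts: pd.DataFrame,
    control_ids: list[str],
    k: int = 6,
    size_factors: pd.Series | None = None,
) -> RuvFactors:
    """Unwanted-variation factors from negative-control genes (RUVg-style).

    log(normalized count + 1) of the controls is row-centered and the first
    ``k`` sample-side singular vectors become the factor matrix W
    (samples × k, orthogonal columns, sign fixed so each column's largest-
    magnitude entry is positive). Controls constant across samples give
    all-zero columns with a warning.
    """
    missing = [c for c in control_ids if c not in counts.index]
    if missing:
        raise KeyError(f"controls not in count matrix: {missing[:5]}")
    if k >= counts.shape[1]:
        raise ValueError(f"k={k} must be < number of samples ({counts.shape[1]})")
    norm = normalized_counts(counts, size_factors)
    M = np.log(norm.loc[control_ids].to_numpy(dtype=float) + 1.0)
    M = M - M.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if S[0] <= 1e-12:
        warnings.warn("control genes are constant across samples; W is degenerate")
        W = np.zeros((counts.shape[1], k))
    else:
        W = Vt[:k].T.copy()
        for j in range(W.shape[1]):
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        if W.shape[1] < k:
            W = np.pad(W, ((0, 0), (0, k - W.shape[1])))
    cols = [f"W{i + 1}" for i in range(k)]
    return RuvFactors(
        W=pd.DataFrame(W[:, :k], index=counts.columns, columns=cols),
        control_ids=list(control_ids),
        singular_values=S[:k],
    )


# ---------------------------------------------------------------------------
# PCA


def pca_embed(
    counts: pd.DataFrame,
    n_top: int = 1000,
    min_mean: float = 10.0,
    size_factors: pd.Series | None = None,
):
    """Sample PCA of log2 normalized counts.

    Features with mean normalized count <= ``min_mean`` are removed, the
    ``n_top`` highest-variance features kept, and centered PCA run on
    log2(normalized + 1). Returns (coordinates: samples × PCs,
    variance_explained fractions)."""
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    norm = normalized_counts(counts, size_factors)
    keep = norm.mean(axis=1) > min_mean
    mat = np.log2(norm[keep].to_numpy(dtype=float) + 1.0)
    if mat.shape[0] == 0:
        raise ValueError("no features left after the mean filter")
    if mat.shape[0] > n_top:
        order = np.argsort(mat.var(axis=1, ddof=1))[::-1][:n_top]
        mat = mat[np.sort(order)]
    centered = mat - mat.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(counts.shape[1] - 1, len(S))
    coords = (Vt[:n_comp].T * S[:n_comp])
    total_var = (centered**2).sum()
    var_exp = (S[:n_comp] ** 2) / total_var if total_var > 0 else np.zeros(n_comp)
    pcs = [f"PC{i + 1}" for i in range(n_comp)]
    return (
        pd.DataFrame(coords, index=counts.columns, columns=pcs),
        pd.Series(var_exp, index=pcs),
    )
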