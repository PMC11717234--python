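"""Gene-set enrichment and the study's secondary statistics.

Covers: signed-significance ranking of DE results, a weighted running-sum
GSEA with a gene-label permutation null, hypergeometric over-representation,
the developmental-delay constructions (max-of-ICM/TE blastocyst expression,
75/25-weighted developmental log2FC, delay correlation), nonparametric
bootstrap CIs for the mean, and the classical tests used in the figures
(chi-squared goodness of fit vs Mendelian ratios, exact Wilcoxon rank-sum,
Fisher exact, Welch t).

The classical tests delegate to scipy.stats; the enrichment statistics are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "rank_by_signed_significance",
    "enrichment_score",
    "gsea",
    "ora_hypergeometric",
    "read_gmt",
    "blastocyst_stage_value",
    "weighted_dev_log2fc",
    "delay_correlation",
    "bootstrap_mean_ci",
    "chisq_goodness_of_fit",
    "wilcoxon_ranksum_exact",
    "fisher_exact_2x2",
    "welch_ttest",
]

PADJ_FLOOR = 1e-300


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    pvalue: float
    padj: float
    gene_ratio: float
    set_size: int


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(str(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(path, sets: list[GeneSet]) -> None:
    with open(str(path), "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.members)) + "\n")


# ---------------------------------------------------------------------------
# ranking


def rank_by_signed_significance(results: pd.DataFrame, padj_floor: float = PADJ_FLOOR) -> pd.Series:
    """Score features by -log10(padj) * sign(log2FC) and sort descending.

    NA padj features are dropped; padj is floored to avoid infinities. Ties
    are broken by |log2FC| toward the extreme end of the list (larger fold
    changes rank more extreme), then by feature id, so the order is fully
    deterministic.
    """
    res = results.dropna(subset=["padj"])
    padj = np.maximum(res["padj"].to_numpy(dtype=float), padj_floor)
    lfc = res["log2FC"].to_numpy(dtype=float)
    score = -np.log10(padj) * np.sign(lfc)
    absfc = np.abs(lfc)
    direction = np.where(score >= 0, 1.0, -1.0)
    ids = res.index.to_numpy(dtype=object)
    order = np.lexsort((ids, -direction * absfc, -score))
    return pd.Series(score[order], index=ids[order], name="score")


# ---------------------------------------------------------------------------
# GSEA


def _es_from_positions(pos, weights_at, total_w, n, n_hit):
    """ES (and extremum position) from sorted 0-based hit positions.

    The running sum increases by weight/total at each hit and decreases by
    1/(n - n_hit) per miss; its extrema occur immediately after a hit or
    immediately before one, which is all we evaluate. ``pos`` may be 2-D
    (permutations in rows).
    """
    pos = np.sort(pos, axis=-1)
    miss = 1.0 / (n - n_hit) if n > n_hit else 0.0
    cum = np.cumsum(weights_at / total_w[..., None], axis=-1)
    idx = np.arange(1, n_hit + 1)
    after = cum - (pos + 1 - idx) * miss
    before = np.concatenate(
        [np.zeros(pos.shape[:-1] + (1,)), cum[..., :-1]], axis=-1
    ) - (pos - (idx - 1)) * miss
    cand = np.concatenate([after, before], axis=-1)
    cand_pos = np.concatenate([pos, pos - 1], axis=-1)
    # extremum tie-break: the earliest list position wins (the first extremum
    # a left-to-right walk of the running sum encounters); 1e-9 absorbs
    # float-noise differences between equal-magnitude deviations
    absc = np.abs(cand)
    is_max = absc >= absc.max(axis=-1, keepdims=True) - 1e-9
    masked_pos = np.where(is_max, cand_pos, n + 1)
    flat = np.argmin(masked_pos, axis=-1)
    es = np.take_along_axis(cand, flat[..., None], axis=-1)[..., 0]
    peak = np.take_along_axis(cand_pos, flat[..., None], axis=-1)[..., 0]
    return es, peak


def enrichment_score(ranked: pd.Series, members, weight: float = 1.0):
    """Weighted Kolmogorov–Smirnov-style enrichment score of one set.

    Returns ``(ES, leading_edge_size)``; ES is the signed maximum deviation
    of the running sum, in [-1, 1]."""
    n = len(ranked)
    in_set = ranked.index.isin(list(members))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("set has no members in the ranked list")
    if n_hit == n:
        return 1.0, n
    s = np.abs(ranked.to_numpy(dtype=float)) ** weight
    pos = np.flatnonzero(in_set)
    w = s[pos]
    total = w.sum()
    if total <= 0:  # all-zero scores degenerate to equal hit weights
        w = np.ones_like(w)
        total = float(n_hit)
    es, peak = _es_from_positions(pos, w, np.asarray(total), n, n_hit)
    if es >= 0:
        leading = int((pos <= peak).sum())
    else:
        leading = int((pos >= peak).sum())
    return float(es), leading


def gsea(
    ranked: pd.Series,
    sets: list[GeneSet],
    weight: float = 1.0,
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Running-sum GSEA over a ranked list with a gene-label permutation null.

    For each set: ES as in :func:`enrichment_score`; the null redraws the
    set's positions uniformly among the ranked genes; NES = ES divided by
    the mean |null ES| of matching sign; p is two-sided empirical with +1
    smoothing, p = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm); BH across
    sets. Sets outside [min_size, max_size] after intersection (or empty)
    are skipped with a note in the ``skipped`` attr.
    """
    rng = np.random.default_rng(seed)
    n = len(ranked)
    s = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rows, skipped = [], []
    for gs in sets:
        in_set = ranked.index.isin(list(gs.members))
        n_hit = int(in_set.sum())
        if n_hit == 0:
            skipped.append((gs.name, "no members in ranked list"))
            continue
        if not (min_size <= n_hit <= max_size):
            skipped.append((gs.name, f"size {n_hit} outside [{min_size}, {max_size}]"))
            continue
        es, leading = enrichment_score(ranked, gs.members, weight)
        if n_hit == n:
            rows.append((gs.name, es, np.nan, 1.0 / (1 + n_perm), 1.0, n_hit))
            continue
        perm_pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hit]
        perm_pos = np.sort(perm_pos, axis=1)
        w_at = np.take(s, perm_pos)
        totals = w_at.sum(axis=1)
        zero = totals <= 0
        if zero.any():
            w_at[zero] = 1.0
            totals[zero] = n_hit
        null_es, _ = _es_from_positions(perm_pos, w_at, totals, n, n_hit)
        same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        p = (1.0 + (np.abs(null_es) >= abs(es)).sum()) / (1.0 + n_perm)
        rows.append((gs.name, es, nes, p, leading / n_hit, n_hit))
    out = pd.DataFrame(
        rows, columns=["name", "ES", "NES", "pvalue", "gene_ratio", "set_size"]
    ).set_index("name")
    from .diffexpr import bh_adjust

    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else np.nan
    out.attrs["skipped"] = skipped
    return out


def ora_hypergeometric(hits, universe, sets: list[GeneSet]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set among hits."""
    hits, universe = set(hits), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    rows = []
    for gs in sets:
        K = len(gs.members & universe)
        k = len(gs.members & hits)
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append((gs.name, k, K, p, (k / n) if n else 0.0))
    out = pd.DataFrame(
        rows, columns=["name", "overlap", "set_size", "pvalue", "gene_ratio"]
    ).set_index("name")
    from .diffexpr import bh_adjust

    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else np.nan
    return out


# ---------------------------------------------------------------------------
# developmental-delay constructions


def blastocyst_stage_value(
    stage_expr: pd.DataFrame, icm_col: str = "E3.5_ICM", te_col: str = "E3.5_TE"
) -> pd.Series:
    """Per-feature E3.5 blastocyst expression: max of the ICM and
    trophectoderm values."""
    for c in (icm_col, te_col):
        if c not in stage_expr.columns:
            raise KeyError(f"stage column {c} missing")
    return stage_expr[[icm_col, te_col]].max(axis=1)


def weighted_dev_log2fc(lfc_te_vs_8c, lfc_icm_vs_8c, te_weight: float = 0.75):
    """Blastocyst-vs-8-cell developmental log2FC: 75% TE + 25% ICM."""
    a = np.asarray(lfc_te_vs_8c, dtype=float)
    b = np.asarray(lfc_icm_vs_8c, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    out = te_weight * a + (1.0 - te_weight) * b
    if isinstance(lfc_te_vs_8c, pd.Series):
        return pd.Series(out, index=lfc_te_vs_8c.index)
    return out


def delay_correlation(mutant_lfc: pd.Series, dev_lfc: pd.Series, significant=None) -> dict:
    """Pearson r between mutation-induced and developmental log2FC.

    Reported for all features and, when a boolean mask of significant
    features is given, for that subset too. Zero-variance input yields NA
    with a warning.
    """
    common = mutant_lfc.index.intersection(dev_lfc.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired features")

    def _r(idx):
        x = mutant_lfc.loc[idx].to_numpy(dtype=float)
        y = dev_lfc.loc[idx].to_numpy(dtype=float)
        if len(x) < 3:
            return np.nan
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("zero variance; correlation undefined")
            return np.nan
        return float(stats.pearsonr(x, y)[0])

    out = {"all": _r(common)}
    if significant is not None:
        sig_idx = common[pd.Series(significant).reindex(common).fillna(False)]
        out["significant"] = _r(sig_idx)
    return out


def bootstrap_mean_ci(values, B: int = 1000, level: float = 0.95, seed: int = 0):
    """Basic nonparametric bootstrap percentile CI of the mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(B, len(x)))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(x.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# classical tests


def chisq_goodness_of_fit(observed, proportions):
    """Chi-squared goodness of fit of observed counts against stated
    proportions (e.g. Mendelian ratios). Returns (X2, df, p)."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and proportions must align")
    if (obs < 0).any():
        raise ValueError("observed counts must be >= 0")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    expected = obs.sum() * props
    if (expected == 0).any():
        raise ValueError("zero expected count")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def wilcoxon_ranksum_exact(x, y, exact_limit: int = 25) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Exact enumeration of the rank-sum null when there are no ties and the
    smaller group has <= ``exact_limit`` observations; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 1.0
    method = "exact" if (not ties and min(len(x), len(y)) <= exact_limit) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities no
    larger than the observed table's)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative entries")
    if t.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def welch_ttest(x, y) -> float:
    """Two-sided Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
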