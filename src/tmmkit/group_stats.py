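"""Between-group statistics: differential expression with an empirical-Bayes
moderated t, BH false-discovery control, hypergeometric over-representation,
rank-sum location tests, mutation/copy-number burden metrics, contingency
analysis and correlation matrices."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import (
    CNVSegmentTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    NONSYNONYMOUS_CLASSES,
    VARIANT_CLASSES,
)

__all__ = [
    "moderated_t_deg",
    "bh_adjust",
    "hypergeom_ora",
    "mannwhitney",
    "tmb",
    "cnv_burden",
    "mutation_frequency_compare",
    "contingency_chisq",
    "correlation_matrix",
    "CorrelationResult",
]


# ---------------------------------------------------------------------------
# moderated t differential expression


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Returns inf for y <= 0 (no finite solution; trigamma > 0 everywhere).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to gene-wise
    variances ``s2`` with residual degrees of freedom ``df``.

    Uses the log-variance representation e_g = log s_g^2 - digamma(df_g/2)
    + log(df_g/2): the prior df solves trigamma(d0/2) = var(e) -
    mean(trigamma(df_g/2)) (d0 = inf when the right side is <= 0) and
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all gene variances are zero; prior undefined")
    e = (
        np.log(s2[ok])
        - special.digamma(df[ok] / 2.0)
        + np.log(df[ok] / 2.0)
    )
    mean_e = float(e.mean())
    if e.size < 2:
        return np.inf, float(np.exp(mean_e))
    var_e = float(e.var(ddof=1))
    target = var_e - float(special.polygamma(1, df[ok] / 2.0).mean())
    if target <= 0:
        return np.inf, float(np.exp(mean_e))
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(
        np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


def moderated_t_deg(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group differential expression with variance shrinkage.

    Per gene: log_fc = mean(A) - mean(B); the pooled variance s_g^2
    (df = nA + nB - 2) is shrunk toward an empirical-Bayes prior (d0, s0^2)
    fitted across genes; t_mod = log_fc / sqrt(s2_post (1/nA + 1/nB)) with a
    two-sided p from t on d0 + d_g df.  q values are BH-adjusted.

    ``d0_override`` forces the prior df (0 recovers the ordinary pooled t;
    inf gives full shrinkage to s0^2) — used for calibration checks.
    """
    group_a = [str(s) for s in group_a]
    group_b = [str(s) for s in group_b]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:3]}")
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    d_g = float(na + nb - 2)
    s2 = (ssa + ssb) / d_g
    df = np.full(s2.shape, d_g)

    if d0_override is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    elif d0_override == 0:
        d0, s0_sq = 0.0, np.nan
        if (s2 == 0).any():
            raise ValueError("zero-variance gene with d0 = 0")
    else:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d_g
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log_fc": log_fc,
            "t_mod": t_mod,
            "p_value": p,
            "q_value": bh_adjust(p),
            "s2_post": s2_post,
            "d0": d0,
            "s0_sq": s0_sq,
        }
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# over-representation


def hypergeom_ora(
    query: Sequence[str],
    universe: Sequence[str],
    annotation: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of ``query`` in each
    annotation set, with BH adjustment across sets.

    p = P(overlap >= x) for N = |universe|, K = |set & universe|,
    n = |query|.  Query genes must be a subset of the universe.
    """
    universe_set = {str(g) for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query_set = {str(g) for g in query}
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:3]}")
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name in annotation.names():
        members = set(annotation[name]) & universe_set
        K = len(members)
        x = len(members & query_set)
        # upper tail including x: sf(x - 1)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": x,
                "set_size_in_universe": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"])
    return out


# ---------------------------------------------------------------------------
# rank-sum test


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mannwhitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact p by complete enumeration of group assignments when
    nA + nB <= 12 (ties handled through midranks); otherwise a normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled, method="average")
    u_obs = _u_statistic(ranks[:na], na, nb)
    center = na * nb / 2.0
    if na + nb <= 12:
        # exact null: every assignment of na labels to the pooled midranks
        dev_obs = abs(u_obs - center)
        total = 0
        hits = 0
        for idx in combinations(range(na + nb), na):
            u = _u_statistic(ranks[list(idx)], na, nb)
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - center) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u_obs, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# molecular burden


def tmb(
    mut: MutationTable,
    sample_ids: Sequence[str] | None = None,
    nonsyn_classes: Iterable[str] = NONSYNONYMOUS_CLASSES,
) -> pd.Series:
    """Nonsynonymous variant count per sample.

    Samples listed in ``sample_ids`` but absent from the table get 0.
    """
    classes = set(nonsyn_classes)
    unknown = classes - set(VARIANT_CLASSES)
    if unknown:
        raise ValueError(f"unknown variant classes: {sorted(unknown)}")
    t = mut.table
    hits = t[t["variant_classification"].isin(classes)]
    counts = hits.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex([str(s) for s in sample_ids], fill_value=0)
    return counts.astype(int).rename("tmb")


def cnv_burden(
    cnv: CNVSegmentTable, seg_mean_threshold: float = 0.2
) -> pd.Series:
    """Fraction of the covered genome altered, per sample.

    fga = sum of lengths of segments with |seg_mean| >= threshold divided by
    the total covered length.  Length is ``end - start``.
    """
    t = cnv.table
    if t.empty:
        raise ValueError("empty segment table")
    length = (t["end"] - t["start"]).astype(float)
    altered = (t["seg_mean"].abs() >= seg_mean_threshold).astype(float)
    per = pd.DataFrame(
        {"sample_id": t["sample_id"], "len": length, "alt": length * altered}
    ).groupby("sample_id").sum()
    if (per["len"] <= 0).any():
        raise ValueError("sample with zero covered genome length")
    return (per["alt"] / per["len"]).rename("fga")


def mutation_frequency_compare(
    mut: MutationTable,
    labels: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene mutated-sample frequencies in two label groups with
    two-sided Fisher exact tests and BH adjustment across genes."""
    lab = labels.set_index(labels["sample_id"].astype(str))["label"]
    ids_a = list(lab.index[lab == group_a])
    ids_b = list(lab.index[lab == group_b])
    if not ids_a or not ids_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    t = mut.table
    t = t[t["sample_id"].isin(set(ids_a) | set(ids_b))]
    genes = sorted(set(t["gene_id"]))
    mutated = {
        g: set(t.loc[t["gene_id"] == g, "sample_id"]) for g in genes
    }
    na, nb = len(ids_a), len(ids_b)
    rows = []
    for g in genes:
        xa = len(mutated[g] & set(ids_a))
        xb = len(mutated[g] & set(ids_b))
        table = [[xa, na - xa], [xb, nb - xb]]
        if xa == 0 and xb == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            {
                "gene_id": g,
                "freq_a": xa / na,
                "freq_b": xb / nb,
                "n_a": na,
                "n_b": nb,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"])
    else:
        out["q_value"] = []
    return out


# ---------------------------------------------------------------------------
# contingency analysis


def contingency_chisq(
    labels: pd.DataFrame, category: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, float, int, float, bool]:
    """Pearson chi-square (no continuity correction) of TMM label vs an
    ordinal category (stage/grade).

    ``category`` is indexed by sample_id; missing values are dropped.
    Returns (counts, per-category proportions, chi2, df, p, low_expected)
    where ``low_expected`` flags any expected count < 5.
    """
    lab = labels.set_index(labels["sample_id"].astype(str))["label"]
    cat = category.dropna()
    cat.index = cat.index.astype(str)
    common = lab.index.intersection(cat.index)
    joined = pd.DataFrame({"label": lab.loc[common], "cat": cat.loc[common]})
    counts = pd.crosstab(joined["label"], joined["cat"])
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >= 2 levels on both margins")
    obs = counts.to_numpy(dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2_stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2_stat, df))
    proportions = counts / counts.sum(axis=0)
    return counts, proportions, chi2_stat, df, p, bool((expected < 5).any())


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationResult:
    """Pearson r for every (row gene, column gene) pair; ``defined`` is False
    where either gene is constant (r left as NaN, never propagated)."""

    r: pd.DataFrame
    defined: pd.DataFrame


def correlation_matrix(
    expr: ExpressionMatrix,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
) -> CorrelationResult:
    """Pearson correlation of each gene in ``genes_a`` against each in
    ``genes_b`` across samples (>= 3 samples required)."""
    for g in list(genes_a) + list(genes_b):
        if g not in expr.values.index:
            raise KeyError(f"gene {g!r} absent from the expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    A = expr.values.loc[list(genes_a)].to_numpy(dtype=float)
    B = expr.values.loc[list(genes_b)].to_numpy(dtype=float)
    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A_c**2).sum(axis=1))
    sb = np.sqrt((B_c**2).sum(axis=1))
    defined = (sa[:, None] > 0) & (sb[None, :] > 0)
    denom = np.where(defined, sa[:, None] * sb[None, :], 1.0)
    r = np.where(defined, A_c @ B_c.T / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    idx_a = [str(g) for g in genes_a]
    idx_b = [str(g) for g in genes_b]
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx_a, columns=idx_b),
        defined=pd.DataFrame(defined, index=idx_a, columns=idx_b),
    )
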