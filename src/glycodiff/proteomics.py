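"""Protein-level differential expression for tumor vs adjacent tissue.

The pipeline consumes a MaxQuant-style protein-group intensity table and
follows the label-free convention: drop reverse-database and contaminant
entries, keep proteins quantified in at least two thirds of either group,
log2-transform, impute left-censored missing values by drawing from the left
tail of a per-sample censored-normal fit (QRILC-style), then test each
protein with an empirical-Bayes moderated t-statistic that shrinks per-protein
variances toward a common prior, and control the FDR with Benjamini-Hochberg.
The moderated t-statistics rank the genes for preranked gene set enrichment
analysis (weighted Kolmogorov-Smirnov running sum, gene-label permutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .glyco import GROUPS, bh_adjust

__all__ = [
    "ProteinGroupTable",
    "filter_protein_groups",
    "impute_left_censored",
    "fit_variance_prior",
    "moderated_t",
    "preranked_gsea",
    "enrichment_score",
    "run_proteomics_pipeline",
]


@dataclass
class ProteinGroupTable:
    """Protein-group intensity matrix with decoy/contaminant flags.

    ``intensities`` is proteins x samples with NaN for missing (never zero);
    ``meta`` carries per-protein ``gene``, ``reverse`` and ``contaminant``
    columns; ``groups`` maps sample -> tumor/adjacent.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        missing = set(self.intensities.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if not self.meta.index.equals(self.intensities.index):
            raise ValueError("meta and intensity tables must share the protein index")
        if (self.intensities.fillna(1) <= 0).any().any():
            raise ValueError("intensities must be positive; missing values are NaN")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == group]


def filter_protein_groups(
    table: ProteinGroupTable, min_fraction: float = 2 / 3
) -> ProteinGroupTable:
    """Drop reverse/contaminant rows, then require a non-missing fraction of
    at least ``min_fraction`` in the tumor or the adjacent group.

    At the study size (12 per group) the default keeps proteins observed in
    at least 8 samples of either group.
    """
    keep_meta = ~(table.meta["reverse"] | table.meta["contaminant"])
    intens = table.intensities.loc[keep_meta]
    keep = np.zeros(len(intens), dtype=bool)
    for g in GROUPS:
        cols = table.samples(g)
        if cols:
            frac = intens[cols].notna().sum(axis=1) / len(cols)
            keep |= (frac >= min_fraction - 1e-12).to_numpy()
    return ProteinGroupTable(
        intensities=intens.loc[keep],
        meta=table.meta.loc[keep_meta].loc[keep],
        groups=table.groups,
    )


def _fit_censored_normal(observed: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate (mu, sd) of a left-censored normal by quantile matching.

    The observed values are treated as the upper ``1 - f_miss`` quantiles of
    the underlying distribution; regressing their order statistics on the
    corresponding standard-normal quantiles recovers mean and sd.
    """
    obs = np.sort(observed)
    n_obs = len(obs)
    f_miss = 1.0 - n_obs / n_total
    probs = f_miss + (1.0 - f_miss) * (np.arange(1, n_obs + 1) - 0.5) / n_obs
    z = stats.norm.ppf(probs)
    slope, intercept = np.polyfit(z, obs, 1)
    if slope <= 0:  # degenerate (near-constant column); fall back to sd of obs
        slope = max(np.std(obs, ddof=1), 1e-6)
    return float(intercept), float(slope)


def impute_left_censored(
    m: pd.DataFrame,
    q_cens: float = 0.01,
    seed: int | np.random.Generator | None = None,
    tune_sigma: float = 1.0,
) -> pd.DataFrame:
    """QRILC-style left-censored imputation of a log-intensity matrix.

    Column-wise (left-censoring is a per-run detection-limit phenomenon): fit
    a censored normal to each sample's observed values by quantile matching,
    then draw its missing entries from that normal truncated above at its
    ``q_cens`` quantile — i.e. from the far left tail. Observed cells are
    untouched; a fixed ``seed`` reproduces the draws exactly.
    """
    if not 0 < q_cens < 1:
        raise ValueError("q_cens must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = m.copy()
    for col in m.columns:
        v = m[col]
        missing = v.isna()
        if not missing.any():
            continue
        observed = v.dropna().to_numpy(dtype=float)
        if len(observed) < 3:
            raise ValueError(
                f"sample {col!r} has only {len(observed)} observed values; "
                "cannot fit the censored-normal model"
            )
        mu, sd = _fit_censored_normal(observed, n_total=len(v))
        upper = stats.norm.ppf(q_cens, loc=mu, scale=sd)
        scale = sd * tune_sigma
        b = (upper - mu) / scale
        draws = stats.truncnorm.rvs(
            a=-np.inf, b=b, loc=mu, scale=scale, size=int(missing.sum()), random_state=rng
        )
        out.loc[missing, col] = draws
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the sample variances to a scaled F distribution.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0), log(s2) has known
    mean/variance offsets (digamma/trigamma); matching the empirical moments
    of log(s2) yields the prior degrees of freedom d0 and prior variance s0^2.
    Returns ``(d0, s0_sq)``; d0 is ``inf`` when the variances are no more
    dispersed than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError("all per-protein variances are zero; prior not estimable")
    floor = s2[s2 > 0].min()
    s2 = np.where(s2 > 0, s2, floor)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def moderated_t(
    m: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per protein on a complete log2 matrix.

    Per protein the pooled two-sample variance s2 (df = n1 + n2 - 2) is shrunk
    toward the prior: s2_post = (d0*s0^2 + df*s2) / (d0 + df), and
    t = log2FC / sqrt(s2_post * (1/n1 + 1/n2)) is referred to a t distribution
    on d0 + df degrees of freedom. The prior (d0, s0^2) is estimated from the
    variance distribution unless ``prior_df`` forces d0 (0 recovers the
    classical pooled t; inf gives complete shrinkage to s0^2).
    """
    groups = pd.Series(groups)
    cols1 = [c for c in m.columns if groups[c] == "tumor"]
    cols2 = [c for c in m.columns if groups[c] == "adjacent"]
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    if m.isna().any().any():
        raise ValueError("matrix must be complete (impute first)")
    x1 = m[cols1].to_numpy(dtype=float)
    x2 = m[cols2].to_numpy(dtype=float)
    log2_fc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / df_resid

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        # with a forced prior df we still need a prior variance location
        s0_sq = fit_variance_prior(s2, df_resid)[1] if d0 > 0 else np.nan

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    # total df capped at the pooled residual df across all proteins
    df_total = float(min(d0 + df_resid, len(s2) * df_resid))

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2_fc / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=m.index,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def enrichment_score(
    ranked_genes: Sequence[str],
    ranked_stats: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Hits advance the running sum proportionally to |stat|^weight (normalized
    over the set's hits), misses retreat by 1/(N - Nh); the ES is the running
    sum's maximum deviation from zero, signed.
    """
    n = len(ranked_genes)
    hit = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool, count=n)
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        return 0.0
    w = np.abs(np.asarray(ranked_stats, dtype=float)) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hits have zero statistic: fall back to unweighted
        hit_w = hit.astype(float)
        total = float(nh)
    steps = hit_w / total - (~hit).astype(float) / (n - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranking: pd.Series,
    sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    nperm: int = 1000,
    min_size: int = 10,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutations.

    ``ranking`` maps unique gene ids to the ranking statistic (moderated t);
    genes are sorted descending, ties broken by gene id so the order is
    deterministic and seed-independent. Sets are intersected with the ranking
    universe; sets smaller than ``min_size`` or spanning the whole universe
    are skipped with a warning. For each set, ``nperm`` random same-size gene
    sets give the null ES distribution; NES is the ES divided by the mean |ES|
    of the sign-matched permutations and the permutation p-value counts
    sign-matched null ES at least as extreme. BH adjusts across sets.
    Positive NES means enrichment among tumor-overexpressed genes.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking gene ids must be unique")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    ranked_stats = ranking.loc[order].to_numpy(dtype=float)
    universe = set(order)
    n = len(order)

    kept: list[tuple[str, set[str]]] = []
    for set_id, genes in sets.items():
        members = set(genes) & universe
        if len(members) < min_size:
            warnings.warn(f"gene set {set_id!r}: only {len(members)} genes in the "
                          f"ranking universe (< {min_size}); skipped")
            continue
        if len(members) == n:
            warnings.warn(f"gene set {set_id!r} spans the entire universe; skipped")
            continue
        kept.append((set_id, members))

    rows = []
    gene_array = np.array(order)
    for set_id, members in kept:
        es = enrichment_score(order, ranked_stats, members, weight=weight)
        k = len(members)
        null_es = np.empty(nperm)
        for j in range(nperm):
            perm = set(gene_array[rng.choice(n, size=k, replace=False)])
            null_es[j] = enrichment_score(order, ranked_stats, perm, weight=weight)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign):
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
        else:
            nes = 0.0
            p = 1.0
        rows.append(
            {"set_id": set_id, "set_size": k, "es": es, "nes": nes, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set_id", "set_size", "es", "nes", "p"])
    if len(out):
        out = out.set_index("set_id")
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out = out.set_index("set_id")
        out["q"] = np.nan
    return out


def run_proteomics_pipeline(
    table: ProteinGroupTable,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    min_fraction: float = 2 / 3,
    q_cens: float = 0.01,
    alpha: float = 0.05,
    nperm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Full protein cascade: filter, log2, impute, moderated t, optional GSEA.

    Returns the filtered table, the imputed log2 matrix, per-protein
    differential results, the gene-level ranking, enrichment results (when
    gene sets are supplied), and stage counts.
    """
    filtered = filter_protein_groups(table, min_fraction=min_fraction)
    log2_m = np.log2(filtered.intensities)
    imputed = impute_left_censored(log2_m, q_cens=q_cens, seed=seed)
    results = moderated_t(imputed, filtered.groups)
    genes = filtered.meta["gene"]
    # one statistic per gene: keep the most significant protein per symbol
    ranking = (
        results.assign(gene=genes.values)
        .sort_values("p")
        .drop_duplicates("gene")
        .set_index("gene")["t_mod"]
    )
    counts = {
        "quantified": len(table.intensities),
        "after_filters": len(filtered.intensities),
        "significant": int((results["q"] < alpha).sum()),
        "up_in_tumor": int(((results["q"] < alpha) & (results["log2_fc"] > 0)).sum()),
        "down_in_tumor": int(((results["q"] < alpha) & (results["log2_fc"] < 0)).sum()),
    }
    out = {
        "filtered": filtered,
        "imputed": imputed,
        "results": results,
        "ranking": ranking,
        "counts": counts,
    }
    if gene_sets is not None:
        out["enrichment"] = preranked_gsea(
            ranking, gene_sets, nperm=nperm, seed=seed
        )
    return out
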