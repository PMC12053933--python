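"""Glycopeptide-level differential analysis between tumor and adjacent tissue.

Per-sample glycopeptide quantification tables (one row per identified
glycoform: protein accession, glycosite, glycan composition, abundance, MS1
and MS2 scores) are score-filtered, merged into a (protein, site, glycan) x
sample abundance matrix, presence-filtered, and compared between groups with
an adaptive two-sample test: Shapiro normality checks in both groups gate a
Levene (Brown-Forsythe) equal-variance check, which selects Student's t,
Welch's t, or the Wilcoxon rank-sum test. BH controls the FDR. Per-sample
overall glycosylation metrics (sialylation, galactosylation, fucosylation)
are computed abundance-weighted, and significant glycopeptide changes are
overlaid with protein-level fold-changes to attribute each change to protein
expression or to glycosylation itself.

Glycosites may be ambiguous (the peptide carries several sequons); such sites
are a single feature keyed by the rendered set, e.g. ``"197/553"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glycan import (
    ClassificationRules,
    DEFAULT_RULES,
    OverallMetrics,
    glycan_metrics,
    parse_composition,
    weighted_overall_metrics,
)

__all__ = [
    "GROUPS",
    "GlycopeptideMatrix",
    "AdaptiveTestResult",
    "filter_by_scores",
    "merge_samples",
    "presence_filter",
    "singleton_fraction",
    "per_sample_overall_metrics",
    "compare_overall_metrics",
    "adaptive_test",
    "bh_adjust",
    "differential_expression",
    "fold_change_overlay",
    "render_site",
    "run_glyco_pipeline",
]

GROUPS = ("tumor", "adjacent")

RECORD_COLUMNS = ["protein", "site", "glycan", "abundance", "ms1_score", "ms2_score"]

KEY = ["protein", "site", "glycan"]


def render_site(site) -> str:
    """Canonical rendering of a glycosite: ``"197"`` or ``"197/553"``.

    Ambiguous sites (iterables of positions) are sorted ascending and joined
    with ``/``; every position must be a positive integer.
    """
    if isinstance(site, str):
        parts = site.split("/")
    elif isinstance(site, (int, np.integer)):
        parts = [site]
    else:
        parts = list(site)
    positions = []
    for p in parts:
        p = int(p)
        if p < 1:
            raise ValueError(f"glycosite positions are 1-based, got {p}")
        positions.append(p)
    if not positions:
        raise ValueError("empty glycosite")
    return "/".join(str(p) for p in sorted(set(positions)))


@dataclass
class GlycopeptideMatrix:
    """Merged (protein, site, glycan) x sample abundance matrix.

    ``abundance`` is indexed by the (protein, site, glycan) MultiIndex with
    one column per sample; missing observations are NaN (never zero).
    ``groups`` maps each sample column to ``"tumor"`` or ``"adjacent"``.
    """

    abundance: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        missing = set(self.abundance.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate (protein, site, glycan) keys")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.abundance.columns if self.groups[s] == group]

    @property
    def n_glycopeptides(self) -> int:
        return len(self.abundance)

    @property
    def n_glycoproteins(self) -> int:
        return self.abundance.index.get_level_values("protein").nunique()


def _require_scores(records: pd.DataFrame) -> None:
    for col in ("ms1_score", "ms2_score"):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")
        bad = records.index[records[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col} on record(s) {list(bad[:5])}")


def filter_by_scores(
    records: pd.DataFrame, ms1_min: float = 3.0, ms2_min: float = 5.0
) -> pd.DataFrame:
    """Keep records with MS1 score >= ``ms1_min`` and MS2 score >= ``ms2_min``.

    Both cutoffs are inclusive; input order is preserved.
    """
    _require_scores(records)
    mask = (records["ms1_score"] >= ms1_min) & (records["ms2_score"] >= ms2_min)
    return records.loc[mask]


def merge_samples(
    per_sample_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
) -> GlycopeptideMatrix:
    """Combine per-sample tables into one abundance matrix.

    One row per distinct (protein, site, glycan); duplicate observations of
    the same key within a sample are summed; keys unobserved in a sample are
    NaN. Each sample id must map to exactly one group.
    """
    if not per_sample_tables:
        raise ValueError("no per-sample tables supplied")
    groups = dict(groups)
    columns = {}
    for sample, table in per_sample_tables.items():
        if sample not in groups:
            raise ValueError(f"sample {sample!r} missing from the sample sheet")
        t = table.copy()
        t["site"] = t["site"].map(render_site)
        t["glycan"] = t["glycan"].map(lambda g: parse_composition(g).format())
        columns[sample] = t.groupby(KEY)["abundance"].sum()
    abundance = pd.DataFrame(columns)
    abundance.index.names = KEY
    group_series = pd.Series({s: groups[s] for s in abundance.columns})
    return GlycopeptideMatrix(abundance=abundance.sort_index(), groups=group_series)


def presence_filter(
    m: GlycopeptideMatrix, min_per_group: int = 5
) -> GlycopeptideMatrix:
    """Keep rows observed in >= ``min_per_group`` samples of either group."""
    sizes = {g: len(m.samples(g)) for g in GROUPS}
    if min_per_group > max(sizes.values()):
        raise ValueError(
            f"min_per_group={min_per_group} exceeds both group sizes {sizes}"
        )
    keep = np.zeros(len(m.abundance), dtype=bool)
    for g in GROUPS:
        cols = m.samples(g)
        if cols:
            keep |= (m.abundance[cols].notna().sum(axis=1) >= min_per_group).to_numpy()
    return GlycopeptideMatrix(abundance=m.abundance.loc[keep], groups=m.groups)


def singleton_fraction(m: GlycopeptideMatrix) -> tuple[int, float]:
    """Count and fraction of glycopeptides observed in exactly one sample."""
    if m.n_glycopeptides == 0:
        raise ValueError("empty matrix")
    n_obs = m.abundance.notna().sum(axis=1)
    count = int((n_obs == 1).sum())
    return count, count / m.n_glycopeptides


def per_sample_overall_metrics(
    m: GlycopeptideMatrix,
    rules: ClassificationRules = DEFAULT_RULES,
    weighting: str = "proportion",
) -> pd.DataFrame:
    """Abundance-weighted overall glycosylation metrics per sample.

    Returns one row per sample with columns group, sialylation,
    galactosylation, fucosylation (NaN where undefined, e.g. a sample with no
    observations or no antennary glycans).
    """
    metric_cache = {
        g: glycan_metrics(parse_composition(g), rules)
        for g in m.abundance.index.get_level_values("glycan").unique()
    }
    glycans = m.abundance.index.get_level_values("glycan")
    out = []
    for sample in m.abundance.columns:
        col = m.abundance[sample]
        observed = col.notna() & (col > 0)
        rows = [
            (metric_cache[g], ab)
            for g, ab in zip(glycans[observed.to_numpy()], col[observed])
        ]
        if rows:
            om = weighted_overall_metrics(rows, weighting=weighting)
        else:
            om = OverallMetrics(None, None, None)
        out.append(
            {
                "sample": sample,
                "group": m.groups[sample],
                "sialylation": np.nan if om.sialylation is None else om.sialylation,
                "galactosylation": np.nan
                if om.galactosylation is None
                else om.galactosylation,
                "fucosylation": np.nan if om.fucosylation is None else om.fucosylation,
            }
        )
    return pd.DataFrame(out).set_index("sample")


def compare_overall_metrics(
    metrics: pd.DataFrame, alpha_pre: float = 0.05
) -> pd.DataFrame:
    """Group comparison of each overall metric via the adaptive test."""
    rows = []
    for metric in ("sialylation", "galactosylation", "fucosylation"):
        x = metrics.loc[metrics["group"] == "tumor", metric].dropna().to_numpy()
        y = metrics.loc[metrics["group"] == "adjacent", metric].dropna().to_numpy()
        res = adaptive_test(x, y, alpha_pre=alpha_pre)
        rows.append(
            {
                "metric": metric,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class AdaptiveTestResult:
    test_used: str  # student | welch | wilcoxon
    statistic: float
    p: float
    shapiro_p: tuple[float, float] = field(default=(np.nan, np.nan))
    levene_p: float = np.nan


def _shapiro_p(v: np.ndarray) -> float:
    # constant vectors are degenerate for Shapiro; treat as non-normal so the
    # rank test (which tolerates ties) handles them
    if np.ptp(v) == 0:
        return 0.0
    return float(stats.shapiro(v).pvalue)


def adaptive_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha_pre: float = 0.05,
    levene_center: str = "median",
) -> AdaptiveTestResult:
    """Normality/variance-gated two-sample test.

    If Shapiro's test does not reject normality (p >= ``alpha_pre``) in both
    groups, Levene's test (median-centered by default, i.e. Brown-Forsythe)
    chooses between Student's t (equal variances) and Welch's t; otherwise the
    Wilcoxon rank-sum (Mann-Whitney) test is used, exact at small n without
    ties and normal-approximated with continuity correction otherwise.
    Returns the chosen test, its statistic, and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"adaptive test needs >= 3 observations per group, got {len(x)} and {len(y)}"
        )
    sp = (_shapiro_p(x), _shapiro_p(y))
    if sp[0] >= alpha_pre and sp[1] >= alpha_pre:
        lev = float(stats.levene(x, y, center=levene_center).pvalue)
        if lev >= alpha_pre:
            t = stats.ttest_ind(x, y, equal_var=True)
            return AdaptiveTestResult("student", float(t.statistic), float(t.pvalue), sp, lev)
        t = stats.ttest_ind(x, y, equal_var=False)
        return AdaptiveTestResult("welch", float(t.statistic), float(t.pvalue), sp, lev)
    w = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return AdaptiveTestResult("wilcoxon", float(w.statistic), float(w.pvalue), sp)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    m: GlycopeptideMatrix,
    alpha_pre: float = 0.05,
    log_transform: bool = True,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Adaptive-test differential abundance per glycopeptide.

    Tests observed abundances only (no imputation on the glycopeptide side);
    parametric tests act on log2 abundances when ``log_transform`` is set.
    Fold-change is the tumor/adjacent ratio of group means of the observed
    raw-scale values. Rows with fewer than ``min_obs`` observations in either
    group are reported with NaN statistics and excluded from the BH
    adjustment.
    """
    tumor_cols = m.samples("tumor")
    adj_cols = m.samples("adjacent")
    rows = []
    for key, row in m.abundance.iterrows():
        x = row[tumor_cols].dropna().to_numpy(dtype=float)
        y = row[adj_cols].dropna().to_numpy(dtype=float)
        fc = x.mean() / y.mean() if len(x) and len(y) and y.mean() > 0 else np.nan
        if len(x) >= min_obs and len(y) >= min_obs:
            tx, ty = (np.log2(x), np.log2(y)) if log_transform else (x, y)
            res = adaptive_test(tx, ty, alpha_pre=alpha_pre)
            rows.append(
                dict(
                    zip(KEY, key),
                    n_tumor=len(x),
                    n_adjacent=len(y),
                    mean_tumor=x.mean() if len(x) else np.nan,
                    mean_adjacent=y.mean() if len(y) else np.nan,
                    fold_change=fc,
                    test_used=res.test_used,
                    statistic=res.statistic,
                    p=res.p,
                )
            )
        else:
            rows.append(
                dict(
                    zip(KEY, key),
                    n_tumor=len(x),
                    n_adjacent=len(y),
                    mean_tumor=x.mean() if len(x) else np.nan,
                    mean_adjacent=y.mean() if len(y) else np.nan,
                    fold_change=fc,
                    test_used="insufficient",
                    statistic=np.nan,
                    p=np.nan,
                )
            )
    out = pd.DataFrame(rows).set_index(KEY)
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def fold_change_overlay(
    glyco_results: pd.DataFrame,
    protein_fold_changes: Mapping[str, float],
    q_threshold: float = 0.05,
    protein_change_threshold: float = 1.5,
) -> pd.DataFrame:
    """Overlay significant glycopeptide changes with protein fold-changes.

    One row per glycopeptide with q < ``q_threshold``: group means, the
    glycopeptide fold-change, the protein fold-change (NaN when the protein
    was not quantified), and an attribution flag. A change is
    ``expression-driven`` when the protein changes in the same direction by at
    least ``protein_change_threshold``-fold; ``glycosylation-driven`` when the
    protein is flat (within the threshold band around 1) or moves the other
    way; ``unattributed`` when no protein fold-change is available. The value
    1 is the under/over-expression boundary for both fold-changes.
    """
    sig = glyco_results[glyco_results["q"] < q_threshold].copy()
    band = math.log2(protein_change_threshold)
    prot_fc = []
    attribution = []
    for key in sig.index:
        protein = key[0]
        g_fc = sig.loc[key, "fold_change"]
        p_fc = protein_fold_changes.get(protein, np.nan)
        prot_fc.append(p_fc)
        if not np.isfinite(p_fc) or p_fc <= 0:
            attribution.append("unattributed")
            continue
        g_dir = math.log2(g_fc) if g_fc > 0 else 0.0
        p_dir = math.log2(p_fc)
        if abs(p_dir) >= band and np.sign(p_dir) == np.sign(g_dir):
            attribution.append("expression-driven")
        else:
            attribution.append("glycosylation-driven")
    sig["protein_fold_change"] = prot_fc
    sig["attribution"] = attribution
    cols = [
        "mean_tumor",
        "mean_adjacent",
        "fold_change",
        "protein_fold_change",
        "attribution",
        "test_used",
        "statistic",
        "p",
        "q",
    ]
    return sig[[c for c in cols if c in sig.columns]]


def run_glyco_pipeline(
    per_sample_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    ms1_min: float = 3.0,
    ms2_min: float = 5.0,
    min_per_group: int = 5,
    alpha_pre: float = 0.05,
    q_threshold: float = 0.05,
    protein_fold_changes: Mapping[str, float] | None = None,
    rules: ClassificationRules = DEFAULT_RULES,
) -> dict:
    """Full glycopeptide cascade: score filter, merge, presence filter,
    per-sample metrics, adaptive differential testing, BH, optional overlay.

    Returns a dict with the merged and filtered matrices, stage counts
    (glycopeptide/glycoprotein counts before and after each filter, singleton
    statistics), per-sample metrics with their group comparison, differential
    results, and the overlay table when protein fold-changes are given.
    """
    filtered_tables = {
        s: filter_by_scores(t, ms1_min=ms1_min, ms2_min=ms2_min)
        for s, t in per_sample_tables.items()
    }
    merged_all = merge_samples(per_sample_tables, groups)
    merged = merge_samples(filtered_tables, groups)
    n_single, frac_single = singleton_fraction(merged)
    present = presence_filter(merged, min_per_group=min_per_group)
    metrics = per_sample_overall_metrics(present, rules=rules)
    metric_tests = compare_overall_metrics(metrics, alpha_pre=alpha_pre)
    results = differential_expression(present, alpha_pre=alpha_pre)
    counts = {
        "glycopeptides_pre_score_filter": merged_all.n_glycopeptides,
        "glycoproteins_pre_score_filter": merged_all.n_glycoproteins,
        "glycopeptides": merged.n_glycopeptides,
        "glycoproteins": merged.n_glycoproteins,
        "singletons": n_single,
        "singleton_fraction": frac_single,
        "glycopeptides_present": present.n_glycopeptides,
        "glycoproteins_present": present.n_glycoproteins,
        "significant": int((results["q"] < q_threshold).sum()),
        "significant_glycoproteins": results[results["q"] < q_threshold]
        .index.get_level_values("protein")
        .nunique(),
    }
    out = {
        "merged": merged,
        "presence_filtered": present,
        "counts": counts,
        "sample_metrics": metrics,
        "metric_tests": metric_tests,
        "results": results,
    }
    if protein_fold_changes is not None:
        out["overlay"] = fold_change_overlay(
            results, protein_fold_changes, q_threshold=q_threshold
        )
    return out
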