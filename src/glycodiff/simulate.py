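"""Synthetic search-engine outputs with known ground truth.

Emulates the statistical structure of a paired tumor/adjacent FFPE cohort of
12 individuals profiled by label-free proteomics and site-specific
N-glycoproteomics:

* a MaxQuant-style protein-group intensity table — log-normal intensities,
  left-censored (MNAR) missingness, reverse/contaminant decoy rows, and a
  fraction of proteins with planted group shifts;
* GlycReSoft-style per-sample glycopeptide tables — glycoproteins carrying
  1-3 glycosites with several glycoforms each, drawn from a curated pool of
  plausible compositions spanning high-mannose through sialylated/fucosylated
  complex types; a large majority of glycopeptides observed in a single
  sample (the study's hallmark sparsity); MS1/MS2 scores with a configurable
  fraction of sub-threshold records; and planted effects of two kinds —
  "expression-driven" (all glycoforms of a protein shift with the protein)
  and "glycosylation-driven" (one glycoform shifts while the protein stays
  flat).

Every generated value is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .proteomics import ProteinGroupTable

__all__ = [
    "SimulationConfig",
    "COMPOSITION_POOL",
    "generate_protein_dataset",
    "generate_glyco_dataset",
    "generate_study",
]

#: Curated pool of plausible N-glycan compositions: paucimannose and
#: high-mannose series, hybrids, and bi/tri/tetra-antennary complex glycans
#: with optional fucose and partial sialylation.
COMPOSITION_POOL = (
    # paucimannose
    "H3N2", "H4N2", "F1H3N2", "F1H4N2",
    # high-mannose
    "H5N2", "H6N2", "H7N2", "H8N2", "H9N2",
    # hybrid
    "H5N3", "H6N3", "F1H5N3", "H6N3S1",
    # complex biantennary
    "H3N4", "H4N4", "H5N4", "H4N4S1", "H5N4S1", "H5N4S2",
    "F1H4N4", "F1H5N4", "F1H5N4S1", "F1H5N4S2",
    # complex triantennary
    "H6N5", "H6N5S1", "H6N5S2", "H6N5S3", "F1H6N5", "F1H6N5S1", "F1H6N5S2",
    # complex tetraantennary
    "H7N6", "H7N6S1", "H7N6S2", "H7N6S3", "H7N6S4", "F1H7N6", "F1H7N6S2",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 12 samples per group, ~68% of
    glycopeptides observed in a single sample, 365 glycoproteins with a few
    glycoforms per site, log-normal intensities, left-censored missingness,
    2-log2 planted protein effects on 10% of proteins and 4-fold planted
    glycosylation effects.
    """

    n_per_group: int = 12
    n_proteins: int = 2000
    n_glycoproteins: int = 365
    max_sites_per_protein: int = 3
    glycoforms_per_site_mean: float = 2.2
    max_glycoforms_per_site: int = 8
    ambiguous_site_prob: float = 0.05
    log2_abundance_mean: float = 23.0
    log2_abundance_sd: float = 2.0
    log2_noise_sd: float = 0.6
    censoring_quantile: float = 0.2
    mcar_fraction: float = 0.0
    singleton_inflation: float = 0.68
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    glyco_effect_fraction: float = 0.1
    glyco_fold: float = 4.0
    score_fail_fraction: float = 0.1
    ms1_pass_range: tuple[float, float] = (3.0, 40.0)
    ms2_pass_range: tuple[float, float] = (5.0, 200.0)
    n_decoys: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "singleton_inflation",
            "de_fraction",
            "glyco_effect_fraction",
            "score_fail_fraction",
            "mcar_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.censoring_quantile < 1:
            raise ValueError("censoring_quantile must lie in (0, 1)")
        for name in ("n_per_group", "n_proteins", "n_glycoproteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.de_fraction > 0 and round(self.de_fraction * self.n_proteins) < 1:
            raise ValueError(
                "de_fraction and n_proteins imply fewer than one planted protein"
            )


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    tumor = [f"T{i:02d}" for i in range(1, cfg.n_per_group + 1)]
    adjacent = [f"A{i:02d}" for i in range(1, cfg.n_per_group + 1)]
    return tumor, adjacent


def sample_groups(cfg: SimulationConfig) -> pd.Series:
    tumor, adjacent = _sample_ids(cfg)
    return pd.Series(
        {**{s: "tumor" for s in tumor}, **{s: "adjacent" for s in adjacent}}
    )


def generate_protein_dataset(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinGroupTable, pd.DataFrame]:
    """MaxQuant-like protein intensity table with planted group shifts.

    Intensities are log-normal around a per-protein baseline; a
    ``de_fraction`` of proteins carry a +/- ``de_log2fc`` tumor shift;
    missingness is left-censoring at each sample's ``censoring_quantile``
    (plus an optional MCAR admixture); ``n_decoys`` reverse/contaminant rows
    are appended. Returns the table and the per-protein truth (``is_de``,
    ``log2fc``).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tumor, adjacent = _sample_ids(cfg)
    samples = tumor + adjacent
    proteins = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    genes = [f"GENE{i:04d}" for i in range(1, cfg.n_proteins + 1)]

    n_de = int(round(cfg.de_fraction * cfg.n_proteins))
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    log2fc = np.zeros(cfg.n_proteins)
    log2fc[de_idx] = cfg.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)

    base = rng.normal(cfg.log2_abundance_mean, cfg.log2_abundance_sd, cfg.n_proteins)
    noise = rng.normal(0.0, cfg.log2_noise_sd, (cfg.n_proteins, len(samples)))
    is_tumor = np.array([s in tumor for s in samples], dtype=float)
    log2_m = base[:, None] + np.outer(log2fc, is_tumor) + noise

    intens = pd.DataFrame(2.0 ** log2_m, index=proteins, columns=samples)
    for s in samples:  # left censoring: the dimmest fraction of each run is lost
        thr = intens[s].quantile(cfg.censoring_quantile)
        intens.loc[intens[s] < thr, s] = np.nan
    if cfg.mcar_fraction > 0:
        mcar = rng.random(intens.shape) < cfg.mcar_fraction
        intens = intens.mask(mcar)

    meta = pd.DataFrame(
        {"gene": genes, "reverse": False, "contaminant": False}, index=proteins
    )
    if cfg.n_decoys:
        decoy_ids = [f"DECOY{i:03d}" for i in range(1, cfg.n_decoys + 1)]
        decoy_int = pd.DataFrame(
            2.0
            ** rng.normal(
                cfg.log2_abundance_mean, cfg.log2_abundance_sd, (cfg.n_decoys, len(samples))
            ),
            index=decoy_ids,
            columns=samples,
        )
        half = cfg.n_decoys // 2
        decoy_meta = pd.DataFrame(
            {
                "gene": decoy_ids,
                "reverse": [i < half for i in range(cfg.n_decoys)],
                "contaminant": [i >= half for i in range(cfg.n_decoys)],
            },
            index=decoy_ids,
        )
        intens = pd.concat([intens, decoy_int])
        meta = pd.concat([meta, decoy_meta])
    meta.index.name = intens.index.name = "protein"

    truth = pd.DataFrame(
        {"is_de": log2fc != 0, "log2fc": log2fc}, index=proteins
    )
    truth.index.name = "protein"
    table = ProteinGroupTable(
        intensities=intens, meta=meta, groups=sample_groups(cfg)
    )
    return table, truth


def _draw_glycopeptide_keys(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """(protein, site, glycan) universe: 1-3 sites per glycoprotein, a few
    glycoforms per site, occasional ambiguous two-sequon sites."""
    rows = []
    for i in range(1, cfg.n_glycoproteins + 1):
        protein = f"P{i:04d}"
        n_sites = int(rng.integers(1, cfg.max_sites_per_protein + 1))
        positions = np.sort(rng.choice(np.arange(30, 900), size=n_sites, replace=False))
        for pos in positions:
            if rng.random() < cfg.ambiguous_site_prob:
                site = f"{pos}/{pos + int(rng.integers(10, 400))}"
            else:
                site = str(pos)
            lam = max(cfg.glycoforms_per_site_mean - 1.0, 0.0)
            n_forms = 1 + int(rng.poisson(lam))
            n_forms = min(n_forms, cfg.max_glycoforms_per_site, len(COMPOSITION_POOL))
            forms = rng.choice(len(COMPOSITION_POOL), size=n_forms, replace=False)
            for f in sorted(forms):
                rows.append((protein, site, COMPOSITION_POOL[f]))
    return pd.DataFrame(rows, columns=["protein", "site", "glycan"])


def generate_glyco_dataset(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    protein_truth: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """GlycReSoft-like per-sample tables plus the glycopeptide truth table.

    Observation masks make ~``singleton_inflation`` of glycopeptides
    single-sample observations. Planted effects are drawn from the
    well-observed remainder: glycoforms of protein-level DE glycoproteins
    shift coherently with the protein ("expression-driven"; protein effects
    come from ``protein_truth`` when given, otherwise planted here), and a
    ``glyco_effect_fraction`` of glycopeptides on flat proteins shift by
    ``glyco_fold`` on their own ("glycosylation-driven"). Effect carriers are
    observed in most samples of both groups so their recovery is a question
    of statistics, not of presence. A ``score_fail_fraction`` of records draw
    sub-threshold MS1 or MS2 scores.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    tumor, adjacent = _sample_ids(cfg)
    samples = tumor + adjacent
    keys = _draw_glycopeptide_keys(cfg, rng)
    n_keys = len(keys)

    if protein_truth is None:
        n_de = int(round(cfg.de_fraction * cfg.n_glycoproteins))
        de_rows = rng.choice(cfg.n_glycoproteins, size=n_de, replace=False)
        fc = np.zeros(cfg.n_glycoproteins)
        fc[de_rows] = cfg.de_log2fc * rng.choice([-1.0, 1.0], size=n_de)
        protein_truth = pd.DataFrame(
            {"is_de": fc != 0, "log2fc": fc},
            index=[f"P{i:04d}" for i in range(1, cfg.n_glycoproteins + 1)],
        )
    prot_fc = keys["protein"].map(protein_truth["log2fc"]).fillna(0.0).to_numpy()

    # observation masks: singletons first, then multi-sample rows
    singleton = rng.random(n_keys) < cfg.singleton_inflation
    mask = np.zeros((n_keys, len(samples)), dtype=bool)
    for i in range(n_keys):
        if singleton[i]:
            mask[i, rng.integers(len(samples))] = True
        else:
            k = int(rng.integers(2, len(samples) + 1))
            mask[i, rng.choice(len(samples), size=k, replace=False)] = True

    # glycosylation-driven effects on flat proteins among multi-sample rows
    eligible = np.flatnonzero(~singleton & (prot_fc == 0.0))
    n_glyco_fx = int(round(cfg.glyco_effect_fraction * n_keys))
    if n_glyco_fx > len(eligible):
        raise ValueError(
            f"cannot plant {n_glyco_fx} glycosylation effects: only "
            f"{len(eligible)} multi-sample glycopeptides on flat proteins"
        )
    glyco_fx_rows = rng.choice(eligible, size=n_glyco_fx, replace=False)
    glyco_log2 = np.zeros(n_keys)
    glyco_log2[glyco_fx_rows] = math.log2(cfg.glyco_fold) * rng.choice(
        [-1.0, 1.0], size=n_glyco_fx
    )

    total_log2fc = prot_fc + glyco_log2
    carrier = np.flatnonzero((total_log2fc != 0.0) & ~singleton)
    # effect carriers are observed in most samples of both groups
    min_obs = max(cfg.n_per_group - 2, min(3, cfg.n_per_group))
    for i in carrier:
        for offset, group_sz in ((0, cfg.n_per_group), (cfg.n_per_group, cfg.n_per_group)):
            cols = offset + np.arange(group_sz)
            have = mask[i, cols].sum()
            if have < min_obs:
                off = cols[~mask[i, cols]]
                add = rng.choice(off, size=min_obs - have, replace=False)
                mask[i, add] = True

    base = rng.normal(cfg.log2_abundance_mean, cfg.log2_abundance_sd, n_keys)
    is_tumor = np.array([s in tumor for s in samples], dtype=float)
    noise = rng.normal(0.0, cfg.log2_noise_sd, (n_keys, len(samples)))
    log2_m = base[:, None] + np.outer(total_log2fc, is_tumor) + noise
    abundance = 2.0 ** log2_m

    lo1, hi1 = cfg.ms1_pass_range
    lo2, hi2 = cfg.ms2_pass_range
    tables: dict[str, pd.DataFrame] = {}
    for j, s in enumerate(samples):
        idx = np.flatnonzero(mask[:, j])
        n = len(idx)
        ms1 = rng.uniform(lo1, hi1, n)
        ms2 = rng.uniform(lo2, hi2, n)
        fail = rng.random(n) < cfg.score_fail_fraction
        which = rng.integers(0, 3, n)  # 0: ms1 fails, 1: ms2 fails, 2: both
        ms1[fail & (which != 1)] = rng.uniform(0, lo1, int((fail & (which != 1)).sum()))
        ms2[fail & (which != 0)] = rng.uniform(0, lo2, int((fail & (which != 0)).sum()))
        tables[s] = pd.DataFrame(
            {
                "protein": keys["protein"].to_numpy()[idx],
                "site": keys["site"].to_numpy()[idx],
                "glycan": keys["glycan"].to_numpy()[idx],
                "abundance": abundance[idx, j],
                "ms1_score": np.round(ms1, 4),
                "ms2_score": np.round(ms2, 4),
            }
        )

    attribution = np.where(
        glyco_log2 != 0,
        "glycosylation-driven",
        np.where(prot_fc != 0, "expression-driven", "none"),
    )
    truth = keys.copy()
    truth["is_differential"] = total_log2fc != 0
    truth["planted_fold"] = 2.0 ** total_log2fc
    truth["protein_log2fc"] = prot_fc
    truth["attribution"] = attribution
    truth["singleton"] = singleton
    truth["n_observed"] = mask.sum(axis=1)
    return tables, truth.set_index(["protein", "site", "glycan"])


def generate_study(
    cfg: SimulationConfig,
) -> dict:
    """Coherent protein + glycopeptide cohort from one seed.

    Glycoproteins are the first ``n_glycoproteins`` protein accessions, so
    expression-driven glycopeptide shifts coincide with planted protein
    effects and the fold-change overlay can be tested end to end.
    """
    rng = np.random.default_rng(cfg.seed)
    protein_table, protein_truth = generate_protein_dataset(cfg, rng=rng)
    glyco_tables, glyco_truth = generate_glyco_dataset(
        cfg, rng=rng, protein_truth=protein_truth
    )
    return {
        "protein_table": protein_table,
        "protein_truth": protein_truth,
        "glyco_tables": glyco_tables,
        "glyco_truth": glyco_truth,
        "groups": sample_groups(cfg),
    }
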