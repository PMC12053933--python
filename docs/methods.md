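# Methods

## Scope and data model

`glycodiff` analyses two arms of a paired tumor/adjacent tissue study:

* **Protein arm** — a protein-group intensity matrix (proteins × samples)
  with reverse-database and contaminant flags, as produced by label-free
  quantification software. Intensities are positive; a missing value means
  the protein was not quantified in that run (never zero).
* **Glycopeptide arm** — per-sample tables of identified glycoforms, each a
  (protein accession, glycosite, glycan composition) triple with an
  abundance and MS1/MS2 identification scores. A glycosite may be ambiguous
  when the peptide carries more than one sequon; such sites are one feature,
  keyed by the sorted rendering (`197/553`), never duplicated per position.

The package consumes search-engine *output shapes* only; identification and
quantification themselves are out of scope.

## Glycan model

Compositions are residue counts (fucose F, hexose H, HexNAc N, sialic acid
S) with no topology; the total is bounded by 26 monosaccharides, the search
space limit of the consensus human N-glycan database used upstream. The
canonical string is F,H,N,S order with zero counts omitted; parsing accepts
any letter order, each letter at most once.

Classification uses composition-only heuristics (configurable via a YAML
rule table):

| rule | label |
| --- | --- |
| HexNAc < 2 | unclassified (cannot carry the chitobiose core) |
| HexNAc = 2, H ≥ 5 | high-mannose |
| HexNAc = 2, H ≤ 4 | paucimannose |
| HexNAc = 3, H ≥ 5 | hybrid |
| HexNAc ≥ 3 otherwise | complex |

Bisecting GlcNAc is not inferable from composition, so all non-core HexNAc
is counted as antennal: a complex/hybrid glycan has `max(N − 2, 0)`
antennae; high-mannose and paucimannose glycans have none.

Per-glycopeptide metrics, for antenna count *a*:

* sialylation = `min(S, a) / a` — the proportion of sialylated antennae;
* galactosylation = `min(max(H − 3, 0), a) / a` — antennal galactoses are
  the hexoses beyond the three core mannoses, capped at *a*;
* fucosylation = `F ≥ 1`, a binary indicator; core and antennal fucose are
  not distinguished.

Sialylation and galactosylation are **undefined** (not zero) when *a* = 0: a
proportion of antennae has no meaning without antennae. Zero-antenna glycans
are therefore excluded from both numerator and denominator of the weighted
averages; the fucosylation indicator is averaged over all glycopeptides.

Overall metrics weight each glycopeptide by its abundance:
`Σ wᵢ mᵢ / Σ wᵢ`. Whether the average should run over glycopeptides
(abundance weights) or over antennae (abundance × antenna-count weights) is
a genuinely open convention; the per-glycopeptide average is the default and
the antenna-weighted variant is available via `weighting="antenna"`.

## Glycopeptide pipeline

1. **Score filter**: keep records with MS1 score ≥ 3.0 *and* MS2 score
   ≥ 5.0. Cutoffs are inclusive ("cutoff 3.0" is read as the minimum
   acceptable score). Counts are reported both before and after this filter,
   since either can serve as the "identified glycopeptides" census.
2. **Merge**: one row per distinct (protein, site, glycan); duplicate
   observations of one key within a sample are summed; absence is missing.
3. **Presence filter**: keep rows observed in ≥ 5 samples of either group
   (default; configurable). The filter errors if the threshold exceeds both
   group sizes.
4. **Adaptive test** per glycopeptide, on observed values only — no
   imputation on this arm, where missingness is dominated by genuine
   absence of the glycoform rather than detection limits. Parametric tests
   act on log2 abundances (toggleable). The gates: Shapiro–Wilk in both
   groups at α_pre = 0.05; if neither rejects, Brown–Forsythe Levene
   (median-centered, the robust default) at the same α_pre chooses Student
   (equal variances) versus Welch; if either Shapiro rejects, the Wilcoxon
   rank-sum (Mann–Whitney) test is used — exact p at small n without ties,
   normal approximation with continuity correction otherwise. Constant
   vectors, degenerate for Shapiro, are routed to the rank test, which
   tolerates ties. Groups with fewer than 3 observations cannot be gated
   (Shapiro is undefined) and are reported untested, excluded from the
   multiplicity adjustment.
5. **BH FDR** over the tested rows (step-up, order-preserving, capped at 1).
6. **Fold-change**: tumor/adjacent ratio of group means of the observed
   raw-scale values. The group mean (not median) is used; with the skewed,
   partially observed abundances this is the convention that matches the
   ratio-of-bars reading of a grouped bar chart.

Per-sample overall glycosylation metrics are computed on the
presence-filtered matrix and compared between groups with the same adaptive
test.

**Overlay and attribution.** Significant glycopeptides (q < 0.05 default;
the upstream convention wavers between 1% and 5%, so the threshold is a
flag) are joined with protein fold-changes from the protein arm. The
qualitative call is quantified as: a protein is *changed* when its
|log2 fold-change| ≥ log2(1.5); a glycopeptide change is
`expression-driven` when the protein is changed in the same direction,
`glycosylation-driven` when the protein is flat or moves oppositely, and
`unattributed` when the protein was not quantified on the protein arm. The
1.5-fold band separates "comparable magnitude" from "absent" protein
changes; it is configurable (`protein_change_threshold`).

## Protein pipeline

1. **Filters**: drop Reverse and Contaminant rows, then require
   quantification in ≥ 2/3 of either group (≥ 8 of 12 at the study size).
2. **Imputation** (QRILC-style, per sample): left-censoring is a per-run
   detection-limit phenomenon, so each sample column is fit separately. The
   observed values are treated as the upper quantiles of a censored normal;
   regressing their order statistics on standard-normal quantiles (offset by
   the missing fraction) recovers mean and sd. Missing cells are drawn from
   that normal truncated above at its q = 0.01 quantile — the far left
   tail. Draws are reproducible under a fixed seed; observed cells are never
   modified; a sample needs ≥ 3 observed values.
3. **Moderated t**: per protein, pooled two-sample variance s² on
   d = n₁ + n₂ − 2 df; the prior (d₀, s₀²) is estimated by closed-form
   moment matching of log s² to a scaled-F model (digamma/trigamma
   corrections, trigamma-inverse by Newton iteration); posterior variance
   s̃² = (d₀s₀² + ds²)/(d₀ + d); t = log2FC / (s̃·√(1/n₁ + 1/n₂)) on
   d₀ + d df (capped at the pooled residual df, the limma convention).
   Zero variances are floored at the smallest positive s² before the fit.
   d₀ = 0 reduces exactly to the classical pooled t; d₀ = ∞ shrinks every
   variance to s₀². The implementation matches Bioconductor limma's
   `lmFit`/`eBayes` to ~1e−9 on the t statistics (verified in the suite).
   The design is unpaired two-group; a paired design would be a natural
   extension for tumor/adjacent pairs from the same individuals, but the
   two-group description is the default analysis here.
4. **Preranked GSEA** on the moderated-t ranking (one statistic per gene
   symbol, the most significant protein per symbol; ties in the ranking
   broken by gene id, so the order is deterministic and seed-independent).
   ES is the weighted KS running sum (hit increments ∝ |t|^weight, weight 1
   by default). The null is gene-label permutation — same-size random gene
   sets — since phenotype permutation is impossible from a ranking alone.
   NES divides ES by the mean |ES| of sign-matched permutations; the
   permutation p counts sign-matched null |ES| ≥ |ES| with the +1
   correction; BH adjusts across sets. Sets with fewer than 10 genes in the
   ranking universe, or spanning the whole universe, are skipped with a
   warning. Positive NES = enriched among tumor-overexpressed genes.

Intensity data fit the moderated-t path; count-model alternatives are out of
scope because no count data exist in this design.

## Synthetic data generator

The generator emulates the study conditions, not a dial to turn: 12 samples
per group; 2000 proteins (plus 50 reverse/contaminant decoys); 365
glycoproteins with 1–3 sites and a Poisson-distributed number of glycoforms
per site (mean 2.2, giving ≈ 1600 glycopeptides), drawn from a curated pool
of 37 plausible compositions spanning paucimannose to tetraantennary
sialylated/fucosylated complex types; log-normal abundances (log2 mean 23,
between-feature sd 2, within-feature sd 0.6 — a typical label-free CV);
left-censored missingness at each sample's 20 % quantile on the protein arm
(an MCAR admixture knob exists but defaults to 0); 68 % of glycopeptides
observed in exactly one sample; 10 % of records drawing sub-threshold MS1 or
MS2 scores; planted protein effects of ±2 log2 on 10 % of proteins; planted
glycosylation-driven effects of 4-fold on 10 % of glycopeptides sitting on
flat proteins. Expression-driven glycopeptide effects are inherited: every
glycoform of a protein-level DE glycoprotein shifts with the protein.
Multi-sample effect carriers are densified to ≥ 10 observations per group so
that their recovery tests the statistics rather than the presence filter;
singleton glycoforms of DE proteins keep their sparsity.

What the generator does **not** emulate: retention-time or batch structure
(none was observed in the emulated study), correlated glycoforms within a
site, intensity-dependent variance, isotope/charge artifacts, or the true
448-entry glycan database (not redistributed). Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
statistics under a faithful sparsity/censoring structure — not performance
on any particular real cohort.

## Numerical choices and degenerate inputs

* Score/presence filters are inclusive (≥) and idempotent.
* BH is the standard step-up; inputs outside [0, 1] are rejected.
* `mannwhitneyu(method="auto")` switches between exact and corrected-normal
  p-values; identical constant groups yield p = 1 through the tie-handling
  path.
* The trigamma inverse uses Newton iteration with the asymptotic branches
  for extreme arguments; variance priors with non-positive excess dispersion
  give d₀ = ∞ (complete shrinkage), which is the correct limit for
  homoscedastic data.
* The censored-normal fit falls back to the observed sd if the
  quantile-regression slope is non-positive (near-constant column).
* Empty defined sets make a weighted metric undefined (`None`/NaN), never 0.
* All randomness (imputation draws, GSEA permutations, simulation) flows
  through `numpy.random.default_rng` seeds passed explicitly.

## Problem sizes in the test suite

The suite runs the full study-scale synthetic cohort (12 + 12 samples, 2000
proteins, ≈ 1600 glycopeptides) for the end-to-end checks, 10 000
simulations for the type-I calibration of the adaptive test, a
2000-protein null for moderated-t uniformity, and 20 replicate 800-protein
simulations for FDR control — sizes chosen to make the Monte-Carlo bands
tight enough to be meaningful while keeping the suite comfortably fast on a
single CPU.

## Known limitations

* Classification is composition-only; hybrid/complex assignments for
  unusual compositions (e.g. bisected structures) are heuristic, and the
  binning of paucimannose glycans varies between studies — hence the
  configurable rule table.
* Sialylation/galactosylation are undefined for zero-antenna glycans rather
  than zero; overall metrics consequently describe the antennary
  subpopulation.
* The glycopeptide arm tests observed values only; severe informative
  missingness below the presence filter's floor is not modeled.
* Attribution is a two-threshold heuristic on fold-changes, not a formal
  decomposition with uncertainty propagation.
* GSEA p-values are permutation-based with nperm default 1000; q-values
  below ~1/nperm are resolution-limited.
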