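# Methods

This note documents the models and procedures implemented in `regshift`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Scope and data model

The package covers the downstream analysis layer of a single-cell
multiome / base-resolution accessibility study of endothelial cell state:
everything from "contribution tracks, count matrices and motif models
exist" to "differential footprints, motif deviations, filtered eRegulons,
perturbation scores and overlap statistics". Upstream steps — read
alignment, peak calling on reads, normalization/clustering/annotation of
cells, topic modelling, neural-network accessibility models and de-novo
motif discovery — are out of scope; their outputs are the package's inputs,
and the synthetic module generates statistically analogous stand-ins
directly.

Coordinates are 0-based half-open (BED convention) everywhere internally;
conversion happens only at format boundaries. bedGraph is the canonical
track interchange (dense per-base arrays in memory); bigWig is not
required. All writers order output deterministically so a fixed config
yields byte-identical files.

## Synthetic data with planted ground truth

The generator exists so that every pipeline stage is testable without
cohort data. One `SimulationConfig.seed` determines all outputs through
named sub-generators (CRC-derived per output stream), giving full
determinism.

**Genome and seqlets.** Background bases are i.i.d. with GC fraction 0.41
(human-like; affects decoy motif-match rates). Motif instances are planted
non-overlapping with a 100 bp edge margin and ≥150 bp start separation so
±30 bp profile windows never truncate and rarely overlap another planted
instance. Ambiguous consensus letters are realized by PFM-weighted draws;
strand is random and the genomic substring always matches the consensus
under its recorded strand.

**Contribution tracks.** Per condition, background positions are
Normal(0, noise_sd = 0.1) — Gaussian, not count-based, because attribution
scores are real-valued — and every planted seqlet adds a fixed positive
contribution (default 1.0) over its span. A chosen fraction of seqlets is
additionally multiplied by δ in the non-control conditions. The amplitude
is deliberately constant across seqlets: the planted model is "elevated
contribution plus noise", so the disease/control mean ratio at flagged
seqlets is exactly δ in expectation.

**Accessibility counts.** Per-peak Gamma(2, 0.5) weights; in the affected
group the weights of motif-bearing peaks are multiplied by the group
effect. Counts are Poisson(depth_cell × weight/Σweights) with lognormal
per-cell depths (mean 2,000), so a cell's total concentrates at its drawn
depth. GC content per peak comes from the generated genome.

**Expression.** A linear structural-equation model on a planted acyclic
TF→target network: root TFs vary per cell as Normal(baseline, tf_sd = 1.0)
— roughly 50% CV on baselines of 1–3, a realistic single-cell scale of
regulator variability — and each target adds the weighted deviations of its
regulators plus Normal(0, 0.3) noise. The designated disease driver
(FOSL2) is elevated by Δ = 1 in the disease group, so its targets shift by
weight × Δ. Counts are negative binomial (dispersion 0.1, a typical scRNA
overdispersion scale) around latent × scale with lognormal per-cell depth
factors. A second namespace with Title-case symbols emulates mouse data,
with an explicit ortholog table mapping to the upper-case namespace.

**Regulon dataset.** For the eRegulon filter, paired per-cell TF expression
and region signal are generated directly: genuine TFs' target regions are
a linear function of the TF's expression (coupling 1.5, noise SD 0.5),
decoy TFs' assigned regions are independent noise at the same scale.
Coupling 1.5 makes the pseudo-bulk TF-to-enrichment correlation land near
0.9 for genuine TFs — the intended "activator by construction" regime;
stronger coupling saturates the rank-based AUC and paradoxically lowers the
correlation.

**What the generator does not emulate** (and what passing tests therefore
do not show about real data): read-level noise, Tn5 sequence bias,
doublets, ambient RNA, batch effects, cell-type heterogeneity beyond a
single labelled type, nonlinear or combinatorial regulation, and chromatin
context beyond i.i.d. background sequence. The generator validates the
*procedures* — recovery, calibration, directionality — under a known model,
not biological discovery.

## Stage-by-stage notes

**Peak calling on contribution tracks** uses an explicit threshold /
run-length caller (|score| above a threshold for ≥ min_run bases, gaps ≤
merge_gap merged; defaults: 95th percentile of |score|, 5, 10). Count-based
callers are ill-defined on signed attribution values, so this operation is
specified directly rather than delegated to a fragment-based tool.

**Motif scanning** supports exact IUPAC consensus matching (the default for
`TGAGTCA`, as the element is conventionally written), mismatch-tolerant
matching, and PWM log-odds scanning against background base frequencies.
Both strands are scanned; a position matching both strands reports '+'.
Duplicate identical intervals are collapsed; overlapping distinct seqlets
are retained independently.

**Profile extraction** is strand-oriented by default so asymmetric flanks
align across instances; rows are dropped (and counted) when any condition's
window leaves the track.

**Clustering** is standard k-means (k-means++ init, best of 10 restarts,
seeded) on the concatenated condition blocks, with clusters relabelled in
decreasing size order. k defaults to 4 and is configurable — the cluster
count is an exploratory choice, so differential clusters are identified by
the Δ statistic and its permutation p rather than by eye. The permutation
null swaps the two condition blocks within each row independently
(sign-flipping the per-row contrast), with the add-one estimator
p = (b + 1)/(n_perm + 1).

**Nearest-gene assignment** uses genomic distance with the bedtools
convention (overlap → 0, adjacency → 1), ties broken toward the smaller
gene start and flagged.

**Motif deviations.** Expected count for cell i and motif m is
total_i × Σ_{p∈m} f_p with f_p the peak's share of all counts; the raw
deviation (obs − exp)/exp is standardized against n_background = 50 peak
sets drawn per peak from a 10×10 quantile grid of GC × mean accessibility.
Counts enter raw — the expectation self-normalizes depth. A background SD
below 1e-12 (exactly-proportional matrices) yields z = 0 with a warning.
The group comparison is a two-sided rank-sum test, exact when both groups
have ≤ 10 cells, tie- and continuity-corrected normal approximation
otherwise, Bonferroni-adjusted over motifs (matching the study-wide
correction convention), ranked by adjusted p then |effect|.

**eRegulon scoring.** The enrichment AUC integrates the recovery curve
y(x) = members among the top-x ranks over x = 1..X, X = ⌈0.05 n⌉,
normalized by X · min(|set|, X) so a small fully-recovered set scores
exactly 1 (the exact normalization of ranking-AUC tools varies; this choice
is pinned by a brute-force curve oracle in the tests). Ties in rankings
break by feature id. Pseudo-bulks average 5 cells sampled without
replacement within each cell-type × condition stratum (50 draws per
stratum by default; understaffed strata are skipped with a warning), and
enrichment is recomputed on the averaged profile. Pearson correlation
(configurable) against pseudo-bulk TF expression classifies eRegulons at
the ±0.5 cutoff. The regulon specificity score is 1 minus the
Jensen–Shannon distance (base 2, so it lives in [0, 1]) between the
regulon's normalized enrichment distribution over cells and the label's
indicator distribution.

**GRN fitting and perturbation.** Region→gene links are distance-based
(nearest gene start within 100 kb) rather than co-accessibility-based; the
synthetic truth uses the same rule, keeping recovery well-posed. Edge
p-values come from the Gaussian posterior of the Bayesian ridge coefficient
(two-sided tail at zero) — a concrete realization of "edge strength as a
distribution"; the p < 0.001 filter applies before the top-2,000 cut, which
is per network overall, not per sign. Perturbation propagates
breadth-first: at step k the shift reaches genes first reachable at graph
distance k (delta += W·delta on newly reached genes), with the perturbed TF
clamped throughout and n_propagation = 3 by default; unreachable genes keep
delta 0. Propagation is linear, so per-cell deltas are the unit propagation
scaled by (perturbed − observed) at the TF. Transition scores are cosine
similarities in log-normalized expression space between the cell's delta
and the direction to the target condition's centroid; a 2D PCA projection
of the delta exists for visualization only and never enters the scores.

**Overlap statistics.** Fold changes are log₂ of de-logged group means with
pseudocount 1; thresholds are strict inequalities exactly as printed
(P_adj < 0.05; log₂FC > 0.1 / 0.25 / 0.32 depending on the comparison).
The hypergeometric upper tail is evaluated through the log survival
function; when the probability underflows double precision the result
carries `log10_p` as the authoritative value and p is floored at the
smallest positive double to preserve p ∈ (0, 1]. The Monte-Carlo multi-set
test draws same-sized subsets uniformly without replacement (default
B = 100,000) and uses the add-one estimator, so p ≥ 1/(B+1). The overlap
universe must be supplied explicitly; for cross-dataset comparisons the
natural default is the intersection of detected-gene sets. Differential
accessibility is a likelihood-ratio test between logistic models
(accessible ~ group + depth covariate vs. covariate alone), with constant
regions flagged at p = 1.

**Cell QC** applies the removal rules disjunctively and literally as
printed, including the removal of cells with RNA reads ≥ 50,000 (a doublet
proxy) and TSS enrichment ≤ 1; rules are applied globally, not per sample.
Metrics are inputs — the package does not compute nucleosome ratios or TSS
enrichment from fragments.

## Problem sizes and calibration checks

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which the statistical properties are
well-resolved: 200 planted seqlets (50 differential, δ = 2, noise 0.1) for
footprint recovery; 20 null + 20 effect replicates of an 11-motif,
200-cell deviation analysis for calibration and power; 100 replicates of
the 11-TF regulon dataset for the filter; a 10-TF / 200-target network
with 500 cells per condition for edge recovery and KO/OE directionality;
200 cells per group and 200 genes (20 at 2-fold) for DE power and type-I
error. Empirical rates are judged against their binomial sampling error
(nominal ± 3 SE): a calibrated test's empirical type-I rate fluctuates
symmetrically around the nominal level, so a one-sided literal bound would
reject calibrated behaviour about half the time. The Wilcoxon path was
verified calibrated to 0.049 ± 0.002 on 20,000 simulated null genes.

## Known limitations

- Consensus-exact scanning finds chance matches in background sequence
  (≈8 extra seqlets per 200 planted at these genome sizes); they land in
  their own low-signal cluster and do not perturb the differential call.
- The LR accessibility test refits per region via IRLS; at very large
  region counts a vectorized score test would be preferable.
- The Monte-Carlo overlap loop is O(B · m); B = 100,000 with small sets
  takes seconds, but very large universes would warrant a bit-set
  implementation.
- The perturbation model is linear and first-order: no saturation,
  no feedback within a propagation step, and KO/OE effects are exactly
  anti-parallel when the OE target exceeds every observed value — a feature
  of the model, not evidence about real regulatory response.
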