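# Methods

`effectorscan` implements the computational core of a proteotranscriptomic
effector screen for parasitoid wasps: deciding which genes are expressed in a
secretory tissue, which of those are backed by proteomic peptide evidence,
which gene families are anomalously expanded in the focal genome, and how the
accompanying parasitism and host-choice assays are summarized and tested.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data validation does and does not establish.

## Expression screening

**Input model.** The substrate is a gene × sample matrix of TPM
(transcripts per million; dimensionless, ≥ 0) with per-sample metadata
(tissue, stage, sex, replicate). TPM is a within-sample relative measure, so
every statistic here is either rank-based within a sample group or a ratio
across groups; no cross-sample normalisation is attempted. A *group* is a
unique (tissue, stage, sex) combination; replicate libraries within a group
are averaged before any thresholding or ratio (group-level is the default;
per-sample thresholds remain available through `compute_n99` directly).

**N99 expressed-gene threshold.** For a sample group, sort the per-gene TPM
values in descending order and walk down the list accumulating expression;
the threshold is the TPM value at the first position where the running sum
reaches a fraction `n99_fraction` (default 0.99) of the total. Genes at or
above the threshold are called expressed (`inclusive_ge`, the default). The
strict variant (`strict_gt`) is available: the two differ only for genes tied
with the threshold value, but the threshold-defining gene itself carries
expression evidence by construction, which is why the inclusive rule is the
default. An all-zero group yields threshold 0 and an empty expressed set.

**Tissue-specialization index.** For gene *g* and focal tissue *F*:

    SI(g, F) = mean TPM of g over F's replicates
               ─────────────────────────────────────────────
               mean over non-focal groups of (group-mean TPM)

The denominator averages each non-focal group's replicates first and then
averages across groups, so a heavily replicated group cannot dominate the
baseline. Degenerate cases keep the plain-ratio semantics: 0/positive → 0,
positive/0 → +∞ sentinel, 0/0 → NaN (undefined). For *ranking* genes, an
optional pseudocount ε (added to numerator and denominator) is exposed;
ε = 1 TPM is used internally when ordering genes for profile clustering, so
that infinite ratios do not erase the ordering information of the numerator.
The index is invariant to rescaling all TPMs by any c > 0; in floating-point
arithmetic the invariance is bit-exact for dyadic factors (c = 2^k, since
scaling by a power of two commutes with rounding) and holds to ~1e-12
relative for arbitrary factors, which is how the property is tested.

**High-expression Z test.** Within a candidate set (e.g. all venom-protein
calls, or all teratocyte-expressed genes), expression is transformed to
log2(TPM + 1) — TPM is heavy-tailed and roughly log-normal — and each
candidate's standard score uses the candidate-set mean and the sample (n−1)
standard deviation. The upper-tail standard-normal probability is compared
one-sided against `alpha` (default 0.05); "highly expressed" is a directional
claim, hence one tail. At least 3 candidates and non-zero dispersion are
required; a zero-dispersion candidate set raises a dedicated error rather
than silently calling nothing.

Because mean and SD are estimated from the same candidates, the statistic is
an internally studentized residual, not an exact standard normal: its null
call rate at n candidates is `0.5 · P(Beta(1/2, (n−2)/2) > r²/(n−1))` with
r = z·√(n/(n−1)), e.g. 0.04963 instead of 0.05000 at n = 200, converging to
α as n grows. The calibration battery therefore checks the empirical rate
against this closed form (implementation correctness) and the closed form
against α within the binomial Monte-Carlo error of the simulation
(calibration), rather than conflating the two comparisons.

**Profile clustering and ordination.** Gene expression-pattern ordering uses
agglomerative clustering with distance 1 − Pearson correlation and average
linkage on per-gene z-scored profiles; genes are pre-sorted lexicographically
so ties break deterministically, and zero-variance genes (no defined
correlation) are appended last. Sample ordination is PCA on log2(TPM + 1)
with per-gene centering, computed by SVD; each axis's sign is fixed by making
its largest-magnitude gene loading positive, so projections are reproducible.
The qPCR utility returns 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference) per
condition and ΔΔCt = ΔCt(sample) − ΔCt(control).

## Effector calling

**Peptide matching.** A proteomic peptide supports a protein when it occurs
as an exact contiguous substring of the protein sequence ("fully aligned").
Distinct peptide sequences are counted once regardless of spectral count;
spectra remain in the evidence trail. Isoleucine/leucine equivalence (the
residues are isobaric in MS) is off by default — database search engines
resolve I/L from context — but can be switched on, in which case both
peptide and protein are compared in an I/L-collapsed alphabet. A peptide
matching several proteins supports each of them; no razor/parsimony rule is
applied, so paralogous families can share support (this inflates support for
recently duplicated venom genes, which is the conservative direction for a
screen whose point is to find such families).

**Venom proteins.** venom_protein = expressed in the venom-gland group
(N99 rule above) AND supported by at least `min_peptides` (default 3)
distinct matched peptides. The highly expressed subset re-applies the Z test
within the venom-protein set's venom-gland expression. By construction
highly_expressed ⊆ venom_protein ⊆ VG-expressed, and calls are monotone:
adding a peptide observation can only add calls, raising `min_peptides` can
only remove them.

**Teratocyte effectors.** The expressed set comes from the N99 threshold on
the teratocyte group; the high subset from the Z test over the expressed
set. Free-text functional annotation is reduced to coarse classes by
case-insensitive keyword matching with fixed priority digestion > ribosome >
immunity (first matching keyword wins within a class); text with no keyword
is `other`, and empty/placeholder text is `unknown`. The keyword lists are
configuration, not code — the class vocabulary of any given annotation
pipeline differs, and the shipped defaults (trypsin, protease, peptidase,
…; ribosom…; immun…, lectin, …) are a starting point.

## Family-expansion ranking

From per-species gene → domain annotations, a domain's count in a species is
the number of distinct genes carrying it. Expansion of the focal species is
scored against the *best* comparator — `score = focal − max(others)` — because
the claim of interest is "more copies than *any* other species"; the max is
also insensitive to how many weak comparators are included. `ratio =
(focal+1)/(max_other+1)` breaks score ties (then accession, so the ranking is
total and deterministic). Domains missing from the focal species stay in the
ranking with score ≤ 0, keeping contractions visible.

Outliers are flagged with a robust z score over the score distribution:
`(score − median) / (1.4826·MAD)`, cutoff 5 by default (conservative, and
configurable). Expansion scores are heavy-tailed by construction, which is
why mean/SD z-scores are avoided. If the MAD is zero (more than half the
scores identical) the scale falls back to the mean absolute deviation from
the median; if that is also zero every score equals the median and nothing is
flagged.

## Assay statistics

Replicate-level records are the unit of analysis throughout; figures-style
summaries are mean ± SEM (sample SD/√n) of per-replicate rates, with SEM
undefined (NaN) at n = 1.

* parasitism rate = (1 − emerged host adults / total hosts) × 100
* wasp emergence rate = (emerged wasps / total hosts) × 100
* oviposition index = (N₁ − Nₓ)/(N₁ + Nₓ) × 100 (positive = preference for
  the 1-day-old side); replicates with zero eggs on both sides carry no
  preference information and are excluded with a logged warning rather than
  imputed
* oviposition rate (competition assay) = dissected hosts containing ≥ 1 egg,
  per cent
* superparasitism fold recovery = mean super-parasitism rate / mean
  mono-parasitism rate, computed on replicate means (matching the mean ± SEM
  presentation), not on pooled host counts

**Wilcoxon signed-rank test** (index vs 0): zeros dropped before ranking
(Wilcoxon's convention; Pratt's zero-rank method available by flag), midranks
for ties. For n ≤ 25 the p value is exact: a dynamic program over doubled
(integer) midranks tabulates the full 2^n sign-assignment distribution, and
the two-sided p is 2·min(upper tail, lower tail) capped at 1. Beyond n = 25
a normal approximation with continuity correction is used; with midranks,
Σr²/4 is the null variance and embeds the tie correction. The policy actually
applied is recorded in the result's method detail.

**Mann-Whitney U test** (two groups): exact null distribution when
nA + nB ≤ 16 with no cross-group ties, otherwise the normal approximation
with tie and continuity corrections; delegated to scipy with the method
chosen by this policy and recorded. The package's test battery checks both
tests against brute-force enumeration oracles (all 2^n sign assignments; all
C(n, nA) labelings).

## Synthetic data with planted truth

The generator emulates the screen's six inputs at TPM level — not reads, not
spectra — because the pipeline consumes TPM tables and peptide lists; this
keeps the generator exact and dependency-free.

* **Expression**: TPM = 2^N(μ, σ) i.i.d. per gene × sample (defaults μ = 3,
  σ = 1, i.e. median ~8 TPM with ~2 log2-fold spread), over a 21-library
  panel (7 whole-body developmental stages, adult male/female bodies, 3 venom
  gland replicates, 3 teratocyte replicates, and 2 replicates each of
  ovipositor, antenna, leg). A planted specialized gene has its focal-tissue
  samples multiplied by a fold factor (default 8; the screen's reference
  conditions plant 30 venom-gland and 15 teratocyte genes among 5,000).
  Fold 1 is allowed and is a no-op, which gives the null configuration its
  tests use.
* **Proteins**: one random sequence per gene (150–450 residues,
  proteome-like residue frequencies with K+R ≈ 11%, so tryptic peptides
  average ~9 residues).
* **Peptide evidence**: in-silico tryptic digestion (cleave after K/R unless
  followed by P, zero missed cleavages — an exact partition of the sequence,
  which the conservation invariant tests; missed-cleavage emission is left as
  a config extension point). Every peptide of length ≥ 6 (a pragmatic MS
  detectability floor that also avoids trivially shared short peptides) from
  a *secreted* protein enters the table independently with detection
  probability 0.8; non-secreted proteins contribute nothing. Spectral counts
  are 1 + Poisson(2) decoration.
* **Domain counts**: 200 domains × (1 focal + 13 comparator) species,
  i.i.d. Poisson(2) counts, with one planted accession forced to 29 copies in
  the focal species — the regime of a single extreme family expansion.
* **Assays**: per host, parasitization occurs with p_par; a parasitized host
  yields an adult wasp with p_emg/p_par. This joint model preserves the
  marginal Binomial(n, 1−p_par) emerged-adult and Binomial(n, p_emg)
  emerged-wasp distributions while guaranteeing adults + wasps ≤ hosts,
  which independent draws would occasionally violate; configurations with
  p_emg > p_par are rejected (a wasp cannot emerge from an unparasitized
  host). Default cells cover host ages 1–4 days × {mono, super} with
  efficiency decaying in age under monoparasitism (0.85/0.77 at day 1 down
  to 0.30/0.20 at day 4) and largely rescued by superparasitism (0.66/0.64
  at day 4 — true fold recoveries 2.2 and 3.2), 6 replicates × 20 hosts per
  cell. Two-choice records draw per-side Poisson egg totals (intensity 30
  per side per 2 h, no side bias by default); dissection records are
  Binomial(30, 0.93) for non-parasitized and Binomial(30, 0.05) for
  pre-parasitized hosts.

Each output table draws from its own random stream spawned from the master
seed (`SeedSequence(seed, spawn_key=(table,))`), so editing one design block
never perturbs another table's draw, and identical configurations emit
byte-identical files.

**What passing the synthetic battery shows — and what it does not.** The
planted-truth runs demonstrate that the *decision rules* recover the
structure they were designed for under a clean generative model: near-exact
precision/recall for venom-protein calls, rank-1 recovery of the planted
expansion, and fold estimates centered on the planted truth. Real data add
everything this generator omits: correlated expression across genes and
tissues, compositional coupling of TPM, incomplete or erroneous protein
models, peptide detectability that depends on physicochemistry rather than a
coin flip, shared peptides from true paralogs, annotation noise, and
overdispersed assay counts. Passing here validates the machinery, not the
biology of any particular dataset.

## Numerical and engineering choices

* Thresholds and expressed-set rules are exact comparisons; no float fudge
  factors. Randomized agreement checks against naive oracles (sort-and-scan
  N99, quadratic substring scan) are run at 10³–10⁴ cases.
* Determinism: one master seed drives everything; pipeline payloads are
  canonical JSON (sorted keys, no timestamps) and byte-identical across runs
  with the same seed and inputs. ±∞/NaN sentinels serialize as strings.
* Error taxonomy: malformed inputs raise `InputError` naming the offending
  row/column; invalid configurations raise `ConfigError`; degenerate
  statistics raise dedicated errors (`DegenerateDistributionError`,
  `NoInformationError`); stage failures abort with the stage name and cause.
* Validation problem sizes (100 seeds for the venom screen, 1,000 for
  expansion, 10,000 replicates for Z-test calibration, 500 for fold
  recovery) are the package's reference battery; they finish in a few
  minutes on one core.

## Known limitations

* No PSM-level FDR control, no signal-peptide or secretion prediction, and
  no spectral search — peptide lists are trusted inputs, as in the screen
  this package reproduces.
* The expansion ranking is count-based; it does not model gene gain/loss
  rates or phylogenetic non-independence of comparator species.
* The specialization index compares one focal tissue against the average
  non-focal group and will under-score genes specialized in two tissues at
  once.
* Two-way ANOVA with multiple-comparison correction for factorial assay
  designs is deliberately out of scope; standard statistical packages handle
  it, and the replicate-level records exported here are the correct input.
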