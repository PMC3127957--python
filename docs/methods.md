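# Methods

This note documents the models and procedures implemented in `adipodiff`,
the defaults chosen where the workflow leaves room, and what the synthetic
data does and does not emulate.

## Microarray processing and differential expression

The input is a spot-level table of log2(Cy5/Cy3) ratios from replicated
two-colour hybridisations: per biological experiment and time point one
forward array and (optionally) one reversed-dye partner, each carrying
every EST on replicate spots.

1. **Global median normalisation.** Per array, the median of unflagged
   spots is subtracted, removing array-wide additive offsets (labelling
   and scanning gain on the log scale). Idempotent by construction.
2. **Dye-swap combination.** The partner array measures the same sample
   pair with dyes reversed, so its log ratio is the negated signal plus
   the same dye bias; `(forward − partner)/2` cancels bias common to both.
   Spots missing in either array propagate as missing; an unpaired array
   passes through with a warning.
3. **Replicate-spot collapse.** Per EST, spots further than 3 MAD from the
   spot median are discarded (strict inequality, so with MAD = 0 any value
   different from the median is an outlier), then the median of the
   survivors is taken. The multiplier is configurable; MAD was chosen
   because it is robust and parameter-light.
4. **z-scores.** Collapsed values of one array/time point are standardised
   against the whole array (population SD). This references each EST to
   the expression distribution of the array rather than to a fitted error
   model, which keeps the statistic reproducible from the data alone. An
   array with literally zero spread (possible only in noise-free
   simulation, at the reference time point) carries no evidence of
   differential expression and is assigned z = 0 throughout; the
   standalone `compute_z_scores` operation treats it as an error.
5. **Replication p.** Per EST and time point, the per-experiment collapsed
   values are tested against 0 with a one-sample z statistic,
   mean/(SD/√n), referred to the standard normal (two-sided). With
   typically n = 3 experiments this understates the tail relative to a
   t-test; the t alternative is exposed (`DEConfig.replication_test="t"`)
   but the z form is the default because it is the workflow's stated test.
   SD = 0 with nonzero mean gives p = 0 (perfect replication of a nonzero
   signal), SD = 0 at mean 0 gives p = 1.
6. **DE rule.** An EST is differential iff at some time point |z| > 1.5
   and p < 0.05, both strict. The cutoff is applied to |z| by default so
   repressed ESTs qualify — the clustered programs contain repression
   archetypes — with a one-sided mode (`z_mode="positive"`) available.

## Clustering and PCA

Profiles of the two cell models are inner-joined on EST id and
concatenated (7 + 7 time points → 14-dimensional vectors). k-means uses
Euclidean distance on the raw log2 ratios — the profiles are already on a
common fold-change scale, and amplitude is biologically meaningful here —
with k-means++ initialisation, 20 restarts keeping the best
within-cluster sum of squares, and a fixed seed for reproducibility.
Per-column standardisation is available as a switch but off by default.
PCA is column-centred; the first three components are used for visual
validation of cluster separation, and cluster labels are exported as
letters A–F.

## Overrepresentation analysis

For a cluster against the annotated universe, each GO term annotating at
least one cluster gene yields the 2×2 table (in-set annotated / not,
rest-of-universe annotated / not), tested with Fisher's exact test —
two-sided for GO (depletion can be as informative as enrichment),
one-sided (greater) for motif targets, where only overrepresentation is
reported. Benjamini–Hochberg adjustment runs within each cluster's family
of tests; significance is adjusted p < 0.05. Terms annotating no in-set
gene are skipped: they cannot be overrepresented and would only dilute
the FDR correction. GO annotations are taken as given (no is-a
propagation up the ontology graph).

## PWM scanning

Matrices are parsed from TRANSFAC (row-per-position) or JASPAR
(row-per-base) text. Frequencies use a pseudocount proportional to the
column total (10⁻⁴ × total by default) so empty cells never produce zero
frequencies while heavily and lightly sampled matrices are treated alike.
Conservation weights are c_i = (100/ln 4) Σ_b f ln(4f) ∈ [0, 100]; the
window score is the c-weighted frequency sum normalised by its maximum,
so score 1.0 ⇔ the window matches a per-position argmax wherever c_i > 0.
The core score is the same quantity restricted to the 4 consecutive
positions with maximal Σc_i (ties resolved leftmost; the whole matrix
when L < 4). N bases contribute 0 to the numerator; other ambiguity codes
are rejected at parse time.

**Threshold calibration.** Both strands of a background pool (coding
sequence in practice, uniform i.i.d. in simulation) are scanned and all
window scores sorted; the threshold is the smallest achievable score
whose background hit count per base of sequence is ≤ the target rate
(default 1 per 10 kb). The search is exact over observed scores, not a
parametric approximation. Hit rates are expressed per base of sequence
with both strands contributing hits; a per-strand denominator is exposed
(`per_strand=True`) since the two conventions differ two-fold. If even a
perfect score is too frequent the threshold caps at 1.0 with a warning.
Because achievable scores are discrete, the empirical threshold is only
identifiable when the matrix's score levels do not sit exactly at the
target rate; the acceptance fixtures are constructed with well-separated
levels for this reason.

**Regions.** Promoters span −3000..+2000 around the TSS in gene
orientation ('−' genes mirror the genomic interval and are
reverse-complemented), 0-based half-open, clipped and flagged at
chromosome ends. Scans report every window at or above threshold on both
strands, overlapping hits included, with region and genomic coordinates.
DR1 (Pparg:Rxra direct-repeat) annotation uses a fixed strictly-greater
cutoff of 0.90 instead of a calibrated threshold.

## ChIP integration

Gene windows extend 20 kb beyond both transcription ends. Interval
intersection is half-open (abutting intervals do not overlap) and backed
by an interval tree; tests compare it against a quadratic all-pairs
oracle. A predicted target is *supported* when, in **both** ChIP
datasets (configurable to any-one), a peak midpoint lies within 1 kb of
the TSS (strict) or a peak with height strictly above 70 falls inside an
intron. Peak position is anchored at the midpoint — the datasets report
regions of differing widths, and the midpoint is the least biased single
anchor. Peaks without a height are ineligible for the intronic rule
(logged). A first-intron flag (strand-aware) is reported because
first-intron binding is a recurrent feature of functional
nuclear-receptor targets.

## Perturbation screen and qPCR

Per EST the four measures between perturbed (A) and wild-type (B)
3-point profiles: sum of differences Σ(A−B) (the selection statistic;
positive = up in the perturbed model), Manhattan, Euclidean, Pearson.
Pearson on a constant profile is undefined and reported as missing, not
coerced to 0 or 1. Selection is strict: sum > 4 up, < −4 down, with a
±5 display subset. Selection operates per EST; collapsing to unique
genes is left to the caller's annotation, and both granularities can be
reported.

ΔΔCt quantification assumes ideal amplification efficiency
(fold change = 2^−ΔΔCt), matching the validation design; the package's
Ct interface keeps target and reference Ct side by side so an
efficiency-corrected variant can be layered on. Agreement between qPCR
and microarray log2 fold changes is an OLS regression; for the simple
regression R² = r² (asserted internally).

## Synthetic data: what it emulates, and what not

The generator reproduces the *design* of the study conditions: 3
independent experiments × 7 time points (d0, d1, d2, d3, d4, d6, d10),
dye-swap partner arrays carrying sign-flipped raw ratios, 2 replicate
spots per EST; 1000 genes of which 400 are null and 600 follow six
temporal archetypes (mid-stage induction, double clonal-expansion peaks
at d1/d3, sustained repression, early transient induction, late switch,
monotone late induction) with amplitudes of 2–3.5 log2 units; Gaussian
noise (SD 0.3 log2 units) on the log scale — the standard model for
log-ratio microarray noise, and the regime in which the z filter behaves
predictably. The perturbation pair plants 100 up and 100 down genes at 2
log2 units per time point over 3 time points (d1, d3, d8) among 800
nulls, on top of a shared N(0, 0.5) baseline profile. Promoters are
5 kb of i.i.d. uniform background (configurable composition) with motif
instances sampled per position from the matrix frequencies (consensus
mode for exact-score tests); the GO generator annotates at a 5%
background rate with a planted term covering 80% of one cluster.

Not emulated: spatial/print-tip artefacts, intensity-dependent (lowess)
bias, correlated noise between replicate spots, EST-to-gene multiplicity,
realistic promoter composition (CpG islands, repeats), or GO term
dependency structure. Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability under the stated noise
model, not robustness to every artefact of real arrays or genomes.

## Numerical choices and problem sizes

* Fixed seeds everywhere (`numpy.random.default_rng` seeded per
  generator via `SeedSequence`); identical seeds give byte-identical
  datasets.
* k-means ties in assignment resolve to the lowest centroid index
  (scikit-learn's convention); empty clusters are re-seeded internally.
* Thresholds of the DE rule, the ±4/±5 selection, the 0.90 DR1 cutoff,
  the <1 kb TSS distance and the >70 intronic peak height are all strict
  inequalities.
* The acceptance checks run at deliberately desk-scale sizes chosen as
  adequate for their statistical purpose: 100 × 5 kb promoters × 5
  matrices for the scanner oracle; a 4 Mb uniform background for the
  calibration-vs-enumeration comparison (large enough that the discrete
  score levels around the 1/10 kb tail are resolved with ≥4σ margin);
  exhaustive 2×2 tables to N = 16 plus 300 random tables with margins up
  to 30 for the Fisher oracle; the default 1000-gene simulation for
  parameter recovery; 200 replicates of a 240-promoter null for the FDR
  control.

## Known limitations

* The replication z-test is anticonservative at n = 3 (normal instead of
  t tails); the practical consequence is a null DE rate slightly above
  nominal, visible in the simulations (~1–2% instead of the nominal
  joint rate). The t option tightens this at the cost of sensitivity.
* Exclusive overrepresentation compares adjusted p-values across
  clusters of different sizes; a motif barely non-significant in a
  second cluster is reported as exclusive.
* The scanner is exhaustive (no heuristic skipping); for genome-scale
  scans the per-matrix cost is linear in sequence length with a
  vectorised inner loop, which is adequate for promoter sets but not for
  whole-genome scans.
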