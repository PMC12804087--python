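# Methods

## The problem

In mutagen-treated intestinal epithelium, the tumours that emerge are shaped
both by which mutations the mutagen tends to produce and by which mutant
clones the tissue lets persist. `cryptselect` implements the quantitative
machinery to disentangle the two: an expectation model built from the
mutational process itself, a neutral-dynamics model of crypt stem-cell
clones, and the human-cohort analyses (APC repeat retention, VAF chronology)
that look for the same selective forces in colorectal cancers and polyps.

## Mutational signature and expectation

SNVs are classed on the pyrimidine strand by substitution and flanking bases
(96 channels, COSMIC SBS96 naming, e.g. `A[C>T]G`). The signature is
estimated from passenger SNVs only: catalog rows matching configurable
exclusion rules (defaults: high-impact *Apc* SNVs; everything in *Ctnnb1*,
*Ros1*, *Ntrk3*) are removed first. Per-channel counts are divided by the
count of the channel's source trinucleotide in the sequenced territory
(*opportunity normalization*) and renormalized to sum to one. Channels whose
trinucleotide is absent from the territory have an undefined rate and are
dropped from normalization rather than imputed; a mutation observed in such
a channel is an inconsistency error, not a silent zero.

Expected probabilities of protein-level outcomes come from exhaustive
enumeration: every CDS position admits three substitutions, each annotated
with its mutant codon translation (standard nuclear code) and its folded
channel. Flanking context at the two terminal CDS positions is taken from
supplied padding sequence when available and otherwise the position carries
no channel — context is never fabricated. Stop-loss and start-loss outcomes
are classed `other` and excluded from truncation mass; splice variants
cannot be enumerated from a CDS and contribute only to observed tables.
An outcome set (missense changes at degron codons; stop-gains per domain
bin) is assigned probability proportional to the summed frequency of its
generating channels, renormalized over the set. For two-hit truncation
analyses, the 15 unordered combinations of the five analyzed bins get
probability 2·p(X)·p(Y) for X≠Y and p(X)² for homotypic pairs — the
unordered-pair expectation of two independent draws. A switch reproduces the
bare product without the factor 2 for comparison with conventions that omit
it.

Selection is reported as O/E with a class-vs-rest χ² (1 d.f., no continuity
correction) per class, and log₂ fold changes; significance is displayed as
*/**/*** tiers at 0.05/0.01/0.001 with no multiple-testing correction,
matching the reporting style of the cohort analyses this package supports.
Classes with zero expectation are flagged (`X`) rather than dropped.
Two-sample proportion comparisons use Fisher's exact test or the
continuity-corrected χ² (R `prop.test` convention), both via scipy.

## Crypt drift

A labelled clone's size k ∈ {0..Nₛ} evolves as a continuous-time birth–death
chain: for 0 < k < Nₛ, k→k+1 at rate λ·pᵣ·w(k) and k→k−1 at rate
λ·(1−pᵣ)·w(k); 0 (loss) and Nₛ (crypt fixation) are absorbing. The default
contact kernel w(k)=1 reflects a contiguous clone in a one-dimensional ring
of niche cells, where replacement happens only at the clone's two
boundaries, making the propensity size-independent; w(k)=k (per-cell rates)
is available as a config option since both conventions appear in the
neutral-drift literature. Under neutrality the embedded walk is symmetric
either way, so the fixation probability from size k is k/Nₛ and the
long-time surviving fraction from a single labelled cell is 1/Nₛ.

The exact solution exponentiates the (Nₛ+1)-state generator
(`scipy.linalg.expm`), so the oracle has no time-discretization error; the
Gillespie simulator draws exponential waiting times per event and is
bitwise reproducible under its seed. Defaults are the small-intestinal
parameter set used throughout: Nₛ = 5, λ = 0.1 events/day, pᵣ = 0.5
(neutral; 0.3/0.7 model negative/positive bias), reported on the grid
days 1–30 in steps of 0.5 with tau = 1 setting only the grid start — the
survival curve itself is normalized to 1 at clone induction (t = 0).

Cohort decay tests compare the observed number of driver-class tumours
remaining at a rescue timepoint against the neutral expectation
(drift survival fraction × baseline count) with a two-category
(remaining/lost) χ², so expected counts always sum to the baseline.
Percent reductions are rounded to the nearest integer, with a nearest-ten
rendering available because headline figures are often quoted at that
precision (109 vs 967 is 88.7%, quoted as 90%). Cellularity (2 × mean VAF)
is capped at 1 on probability grounds.

## Post-caller filters

Both filter dialects are pure conjunctions of row-level predicates, so the
outcome is independent of evaluation order and filtering is idempotent.
Capture rules: caller-internal pass; no SNP/germline overlap with the same
allele; ≥2 alt reads with at least half at base alignment quality ≥30;
fewer than 4 normals with ≥4 gapped reads within 10 bp; mappability exactly
1; called in somatic mode in <2 normals; and a low-VAF recurrence rule that
removes variants shared by tumours of ≥2 mice when the maximum VAF across
carriers is ≤0.05 *or* a matched normal carries it at VAF ≥0.01 (the
either-sufficient reading; a `both` mode exists). Rows lacking an optional
field (e.g. no matched normal) skip only the rules needing it, and the skip
is logged. Amplicon rules: SNV alleles only, allele fraction ≥0.01
(inclusive), ≥2 overlapping amplicons, ≥5 mutant reads, caller noise pass.
Per-rule removal counts allow a row to hit several rules, so they sum to at
least the number of removed rows.

## Human APC analyses

Registry samples (one per donor, APC-truncating) are excluded when they
carry more than two driver mutations from a fixed 10-gene set (*ATM*,
*ARID1A*, *AMER1*, *BRAF*, *FBXW7*, *PTEN*, *PIK3CA*, *SMAD4*, *SOX9*,
*TCF7L2*) or more than two APC mutations. Retention scoring counts the
20-amino-acid repeats ending strictly before the truncated residue (0–7);
for two-hit samples the most C-terminal hit governs. Chronology calls build
binomial confidence intervals for the LOH-adjusted APC VAF (highest-ranked
VAF halved when strictly above 0.5; ties broken toward the more N-terminal
mutation) and the KRAS VAF; a verdict requires disjoint intervals. Wilson
score intervals are the default (well-behaved at amplicon depths);
Clopper–Pearson is available. Under the null of equal true VAFs, two
disjoint (1−α) intervals occur less often than α, which the calibration
test checks.

## Shipped annotation data (approximate, overridable)

- `mouse_apc_bins.tsv`: A 1–336, B 337–765 (Armadillo repeats), C 766–1000,
  D 1001–1260, E 1261–1600 (20-AA-repeat region), F 1601–2000, G 2001–2400,
  H 2401–2842. Only B's span is anchored in published coordinates; the
  others are documented approximations and every analysis accepts an
  override TSV.
- `human_apc_20aa_repeats.tsv`: seven repeat intervals from standard APC
  annotation (1262–1281, 1376–1395, 1486–1505, 1577–1596, 1857–1876,
  2009–2028, 2052–2071), chosen so a truncation at Arg1450 retains exactly
  two full repeats.
- `colon_signature_synthetic.tsv`: a constructed, SBS1-dominant normal-colon
  stand-in (heavy C>T at NpCpG over a flat clock-like background) — synthetic
  by construction and clearly labelled so; replace with measured colon
  trinucleotide frequencies for real analyses.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:
multinomial SNV draws over enumerate-able outcomes weighted by signature ×
selection multiplier; overdispersed (negative binomial) per-mouse tumour
counts with mixture-drawn driver classes, thinned through the drift model's
survival probability at the rescue day; and polyp VAFs where the earlier
mutation of an ordered pair occupies a larger cancer-cell fraction, read out
through binomial sampling at Poisson depths. They do not emulate read-level
artefacts, alignment error, copy-number distortion of VAFs beyond the
single LOH halving rule, germline contamination, or realistic genome
coordinates — so passing tests demonstrate the correctness and calibration
of the estimators under their stated model, not robustness to upstream
calling artefacts in real data.

Problem sizes used by the test suite and the acceptance script (10,000
simulated clones per drift comparison; 1,000–1,500 replicates for
calibration checks; 20,000-mutation catalogs for multiplier recovery; 50
random CDSs ≤300 nt for the enumeration oracle) were chosen so Monte-Carlo
error is small against the 3-standard-error acceptance bands while keeping
a full run in the tens of seconds.

## Numerical and design notes

- Coordinates are 1-based inclusive everywhere (genomic, CDS, residue).
- All stochastic operations take explicit integer seeds
  (`numpy.random.default_rng`); generators derive child seeds from a single
  root so one seed reproduces a whole pipeline run.
- The O/E of an injected multiplier s on an outcome with base probability p
  converges to s/(1+(s−1)p), not s exactly — renormalizing the tilted draw
  distribution shifts every other outcome down. Recovery tests compare
  against this analytic value; with p ≈ 0.005 the distinction is ~2%.
- Degenerate inputs fail loudly: zero-opportunity channels with observed
  mutations, empty outcome sets, zero expected counts, bins beyond the
  protein, and missing filter support columns all raise typed errors naming
  the offending rule or object.

## Known limitations

- Splice-site truncations are binned only when a residue is supplied and
  never contribute to expected stop mass, which slightly deflates expected
  totals for genes where splice drivers are common.
- The drift model is zero-dimensional: no crypt fission, no spatial lattice,
  no niche-size variation between crypts.
- Chronology inference assumes both mutations are clonal within their
  lineages and diploid at the locus after the single LOH adjustment;
  subclonal copy-number change will bias VAF ordering.
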