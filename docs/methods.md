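# Methods

## Scope and coordinate conventions

`pavpan` analyzes presence/absence variation between two inbred
genomes — a *donor* that carries the variant sequences and an
*acceptor* that lacks them — and genotypes the variants across a panel
of further inbred lines from read counts.  Read mapping, primary SV
calling and SNP calling are upstream of the package: it consumes
candidate intervals, coverage profiles and count matrices as
plain-text tables.  All intervals are 0-based half-open, internally
and in emitted BED/TSV.

## The filter cascade

Candidate deletion calls are filtered conjunctively; the per-candidate
verdict is therefore independent of stage order, and the staged
implementation exists to attribute each rejection to a single reason.
Defaults, all configurable:

| rule | default | note |
| --- | --- | --- |
| self-consistency | any-overlap | a call also detected in the donor-vs-own-assembly control is an assembly artifact; a reciprocal-50% mode is available since the overlap rule is a convention |
| minimum size | ≥ 1000 bp, inclusive | reported size classes start at 1 kb, so the boundary is taken as inclusive |
| specificity | depth < 5× over ≥ 70% of bases | strict "< 5", inclusive "≥ 70%"; computed on the supplied opposite-genotype profile as-is (no extra mapping-quality filtering is applied at this stage) |
| assembly support | properly-paired coverage > 90% | strict inequality |
| oversize | > 200 kb flagged | large "deletions" are in practice misclassified duplications; they are flagged and excluded rather than dropped silently, preserving auditability |
| scaffold incompleteness | < 20% bases covered AND specificity rule | both criteria required; "covered" means depth ≥ 1 |

Caller support thresholds (e.g. minimum read support at calling time)
are treated as ingestion preconditions: they were applied inside the
upstream caller and are not re-checked by default.

Anchoring is deliberately a toy: the junction the deletion leaves in
the acceptor (default 100 bp of flank on each side) is matched exactly
against the acceptor sequence; 1 placement → unambiguous (with
breakpoint), ≥ 2 → ambiguous, 0 → unanchored.  Real-data anchoring
with alignment tolerance is out of scope, so anchoring results are
only meaningful on synthetic or high-identity data.

## Microhomology

At a deletion breakpoint the microhomology (MH) is the longest exact
match between the deleted segment's prefix and the sequence following
the deletion (right side), or between its suffix and the sequence
preceding it (left side); the reported value is the larger, with ties
going right.  Because a deletion inside an MH tract is positionally
ambiguous, the window is first canonicalized to its leftmost
placement, making the reported length invariant to where the caller
happened to put the breakpoint.  MH "presence" uses a 3 bp threshold:
1–2 bp matches occur by chance at almost any junction.

The size distribution is modelled as geometric decay (the MMEJ
expectation — short matches are simply more frequent) plus a possible
point mass at 5 bp (LTR-retrotransposon target-site duplication).  The
decay parameter is fitted by maximum likelihood on the histogram bins
excluding the 5 bp bin, renormalized over the remaining support; the
*excess* at the mode is the observed share minus the fitted null's
share.  Because a true point mass of size *s* also displaces geometric
mass, the excess has expectation s·(1 − null share); the reported
`spike_mass = excess / (1 − null share)` is the consistent estimate of
*s* and is the quantity compared against generator truth in tests.
Uncertainty comes from a seeded multinomial bootstrap (B = 1000).
Degenerate histograms (fewer than two occupied bins) are rejected.

## Pan-genome pseudomolecules

Anchored and unanchored variant sequences are concatenated into two
pseudomolecules (`pav_anchored`, `pav_unanchored`) appended to the
reference, adjacent blocks separated by exactly 100 N (a parameter);
spacers are internal only — no leading or trailing N.  Anchored
sequences are expected in reference-position order, unanchored keep
input order; an empty unanchored set omits that pseudomolecule.  The
coordinate map is exact and bidirectional; spacer positions map to a
sentinel.  FASTA is emitted 60-column wrapped.

## The genotyping model

For one target line and regions i = 1..n, let x_i be the square root
of the donor's read count over region i and Y_i the square root of the
target's.  The square root is the variance-stabilizing transform for
counts, under which a homoscedastic Gaussian error is a reasonable
approximation, and the transform is guarded against accidental double
application.  The model is a two-component mixture of linear
regressions: absent regions (cluster 0) follow a_0 + b_0 x_i,
present regions (cluster 1) follow a_1 + b_1 x_i, with independent
N(0, σ_k²) errors and mixing proportion π = P(present).

EM estimation: the E-step computes posterior memberships τ_ik from the
two Gaussian regression densities (in log space, so extreme outliers
never produce NaN); the M-step solves two weighted least-squares
problems and weighted variances.  Five starts are used — the first
splits points at the median of y/x, the rest draw random
responsibilities from a seeded generator — and the best log-likelihood
wins.  Labels are canonicalized so cluster 1 has the larger slope,
which makes calls invariant to label swaps in initialization.
Variances are floored at 1e-12 for numerical safety; convergence is a
relative log-likelihood change below 1e-8 (max 500 iterations; a fit
that hits the cap is returned flagged unconverged).  A component whose
effective weight falls below 2 points, or a fit in which both
components converge to the same line (single-cluster data), raises a
degenerate-fit error.

Calling under BFDR control: with q_i = 1 − max(τ_i0, τ_i1) the
posterior misclassification probability of the maximum-a-posteriori
call, regions sorted by ascending q are classified as long as the
running mean of q — the posterior expected FDR of the calls made so
far — stays at or below the nominal level (default 0.01); the rest
stay unclassified, and the running mean at the cut estimates the
realized BFDR.

Lines are fitted independently; the donor and the opposite reference
are processed identically and serve as positive/negative controls.  A
control line carries either every region or none, so the mixture is
unidentifiable on it; such lines are detected by BIC comparison
against a single regression (the mixture spends 4 extra parameters)
or by the degenerate-fit guard, and are then called wholesale by the
single fitted slope: above 0.5 the counts track the donor's (all
present), below, background (all absent).  Counts of zero are allowed
(sqrt 0 = 0, no pseudo-count).  Optional per-line depth normalization
is not applied by default: whether counts should be rescaled for
line-specific sequencing depth before the transform is left to the
caller, since region counts from a uniform pipeline are already on a
common scale per line within the regression (the slope absorbs a
line's global depth factor).

## Population summaries

Missing-call (NA) policy is explicit per operation: shared fractions
exclude NA from the denominator; sharing classification (donor-only /
one-group-only / all-groups / other) uses complete-case rows only,
mirroring the usual "no missing data" subset for such classifications;
LD uses pairwise-complete observations.  PCA centers loci but does not
scale them to unit variance by default (presence frequencies carry
signal); the sign of each component is fixed by making its
largest-magnitude loading positive.  On a fully inbred panel genotype
codes are haplotype-equivalent, so LD is the squared Pearson
correlation of 0/1 allele codes; monomorphic loci yield NA.  For
distances, a 0/1-coded PAV sits at its breakpoint; alternatively it is
represented by its internal SNP closest to the breakpoint.  Decay
curves average r² in distance bins (default 500 bp up to 20 kb);
empty bins are omitted, not zero-filled.  Density tracks count
feature midpoints in sliding windows (default 10 Mb window, 1 Mb
step) with optional scaling to the genome-wide maximum.

## The synthetic-data generator

The generator is the package's study design: its defaults are the
conditions under which the pipeline is validated.

* **Genome pair.**  One random chromosome (default 400 kb; 1.5 Mb in
  the adversarial configuration) with 20 planted PAVs of 1–4 kb, of
  which 3 are made ambiguous by planting a copy of their junction
  elsewhere, plus 5 donor-only scaffolds of 3–10 kb (incomplete PAVs).
  Each anchored breakpoint carries an exact MH whose length is drawn
  from the mixture below and *enforced* exactly — chance extensions are
  broken on both sides — so extraction can be compared to truth base
  by base.  The acceptor is the donor with removed segments excised.
* **Microhomology law.**  No MH with probability 0.6 (matching a
  ~40% MH fraction among breakpoints); otherwise geometric decay
  (p = 0.3) truncated to 3–37 bp renormalized to 0.9, plus a 0.10
  point mass at 5 bp.
* **Decoys.**  Sub-threshold deletions (300–999 bp), duplication
  decoys (intervals never removed, so opposite coverage stays at base
  depth), self-mapping artifacts, assembly decoys (no properly-paired
  coverage) and one oversize call (250 kb); each targets exactly one
  cascade stage.  Decoy counts default to zero and are enabled by
  `adversarial_config()`.
* **Coverage.**  Poisson per base: mean 40× over shared sequence
  (a typical short-read depth), leak fraction 0.001 of base depth
  over truly absent regions.  The residual depth over deleted regions
  in real data is unknown; the leak is an assumption, exposed as a
  parameter.
* **Counts.**  x_i ~ U(10, 40) on the sqrt scale; given cluster
  membership, Y = a_Z + b_Z x + σ_Z N(0,1), truncated at 0, squared
  back to a count.  Defaults a0 = 2, b0 = 0, a1 = 0, b1 = 1,
  σ = 0.8: the absent background is kept slightly above zero because
  truncation at zero would otherwise put a point mass at Y = 0 and
  break the Gaussian assumption the fixtures are meant to satisfy
  exactly.  A `poisson` mode draws counts with mean (a_Z + b_Z x)²
  instead, deliberately misspecifying the model for robustness tests.
  `simulate_mixture_xy` samples the regression mixture directly (no
  count constraint) for calibration and recovery studies of the
  genotyper itself.
* **Panel.**  23 lines in four groups (7/5/7/4) with per-group Beta
  frequency laws (means ≈ 0.5 / 0.4 / 0.25 / 0.19, highest in the
  donor's group), plus the donor (all-carrier) and the opposite
  reference (non-carrier); two PAVs are forced private to the donor's
  group.
* **Determinism.**  One global seed; each stage derives its own
  stream from a stable label (CRC32 of the stage name mixed into the
  seed sequence), so adding a stage never shifts another stage's
  draws, and identical configurations give byte-identical outputs.

What the generator does *not* emulate: read-level artifacts (mapping
bias, PCR duplicates, GC effects), sequence divergence between
genomes outside planted events, overlapping or nested variants, and
real LD structure (panel genotypes are exchangeable within groups;
the separate LD generator uses a thresholded Gaussian process with
exponential distance decay).  Passing tests therefore demonstrate
correctness of the rules and calibration of the statistics under the
stated models, not robustness to every real-data pathology.

## Validation design and problem sizes

* Filter cascade: equality with an independent brute-force
  re-application of the five rules on adversarial sets (seconds).
* BFDR calibration: 20 replicates × 5000 regions from the mixture
  (a0 = a1 = 0, b0 = 0, b1 = 1, σ = 0.8, π = 0.5, x ~ U(10, 40));
  mean realized FDR + 2 Monte-Carlo s.e. must not exceed the nominal
  0.01.  This is also what `scripts/acceptance.py` recomputes.
* EM recovery: with x ~ U(10, 40) a single replicate's intercept
  standard error is ≈ 0.049 at n = 5000 (the intercept extrapolates
  to x = 0), so recovery is asserted on the mean estimate over 10
  seeded replicates — a three-sigma test of unbiasedness at the
  ±0.05 tolerance (±0.03 for π).  Widening the x range to include 0
  is not an alternative: cluster overlap near x = 0 induces genuine
  EM membership bias in the intercepts.
* Microhomology: extraction equals an all-k brute-force scan on 1000
  random breakpoints; a planted 0.10 spike at 5 bp is recovered
  within ±0.03 from 2000 MH lengths via the `spike_mass` estimator.
* Pan-genome: spacer runs, slice reconstruction and coordinate round
  trips are exact.

## Known limitations

* Anchoring is exact-match only; diverged flanks defeat it.
* Panels with fewer than a few dozen regions cannot support the
  mixture fit; such lines fall back to wholesale single-cluster
  calls, which are only meaningful for genuine control lines.
* The BFDR guarantee is model-based: under misspecification (e.g.
  Poisson counts at low depth) the realized FDR may exceed the
  nominal level; the generator's `poisson` mode exists to probe this.
* `classify_sharing` drops rows with any missing call, so its classes
  are biased toward well-covered PAVs, as complete-case analyses are.
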