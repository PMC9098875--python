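# Methods

This note documents the models and procedures condenseq implements, the
parameters that matter, and what the simulator does and does not emulate.

## The measurement being modeled

A dispersion of phase-separated droplets is sorted by FACS, one droplet
per well; each droplet's RNA is converted into a sequencing library and
quantified against a transcriptome, yielding a transcript × condensate
count matrix plus per-condensate covariates: FSC (forward scatter, a size
proxy), SSC, the condensate type and experiment batch, and the
pseudoalignment fraction of the library. A transcript is *detected* in a
condensate when its post-filter TPM is at least 1 — the same threshold
used to zero out sub-1-TPM entries, so "filtered out" and "not detected"
coincide by construction.

## Quality control

Filters run in a fixed order and are idempotent:

1. **Condensate filter.** Drop condensates with pseudoalignment < 5%
   *and* FSC > 2×10⁴. The rule is conjunctive: large droplets should
   yield good libraries, so the combination flags failed wells; small
   droplets legitimately produce sparse libraries and are kept.
2. **Coverage filter.** When the dataset's mean pseudoalignment is below
   40% and per-transcript read-coverage fractions are supplied, drop
   transcripts with coverage < 20%. Coverage comes from upstream
   pseudoaligner output; condenseq consumes it as a provided fraction.
3. **Detection threshold.** Recompute TPM on the survivors and zero
   entries below 1 TPM.

TPM is recomputed after any transcript removal (TPM is compositional;
frequencies downstream should use the renormalized values). This
renormalization-after-filtering behavior is switchable by skipping the
re-filter.

Partition coefficients K are computed from fluorescence intensity tables
as droplet/supernatant intensity ratios, reported as mean ± sample SD
(n−1 denominator; 0 for a single droplet).

## Enrichment calling

Let f_t be the detection frequency of transcript t in percent and a_t its
input-pool abundance (TPM). The model fits

    f_t = s(log10(a_t + 1)) + ε_t

with s a penalized cubic smoothing spline; the smoothing parameter is
chosen by generalized cross-validation. Transcripts with a_t = 0 are
excluded from the fit and reported separately. A transcript is called
**enriched** when its residual f_t − ŝ strictly exceeds 30 percentage
points. The threshold is expressed in percentage points because the
frequencies are; it is configurable (`residual_threshold`).

Numerical details: the abscissa is rescaled to [0, 1] and quantized to a
1/2048 grid, collapsing near-duplicate abundances into weighted
observations — without this the penalized normal equations can become
ill-conditioned and scipy's GCV search either fails or returns a
divergent fit. The GCV solution is additionally sanity-checked against
the data envelope (fitted values must stay within one data range of the
observations); when it fails, the smoothing parameter falls back to
5-fold cross-validation on a 16-point log-spaced grid. A LOESS smoother
(statsmodels lowess, frac = 0.3) is available via `smoother="loess"` and
doubles as an independent oracle in the tests: both smoothers must flag
the same displaced-point outlier.

The length analysis bins transcripts into near-equal-count quantile bins
of input TPM and reports the Pearson correlation of transcript length
with the residual within each bin (bins under 5 transcripts are reported
missing), separating length effects from abundance effects.

## Sequence complementarity

Local alignment uses an affine-gap Smith–Waterman (Gotoh) kernel written
in numba, with the gap convention of the Biostrings/EMBOSS family: a gap
of length L costs `gap_open + L·gap_extend`. Two named schemes exist —
`trans` (match 2, mismatch −1, open 30, extend 0.05) for
trans-complementarity and `sine` (match 2, mismatch −1, open 10,
extend 0) for motif-vs-SINE homology. N scores as a mismatch against
everything, including itself. Under `trans`, any gap costs at least
30.05, more than two 15-nt matched blocks are worth, so optimal
alignments of short sequences are gap-free (verified exhaustively in the
tests); but the near-zero extension makes *long* gaps cheap, so
high-scoring alignments of long transcripts are chains of well-matched
blocks — exactly the behavior needed to pick up motif-pair
complementarity separated by unrelated spacer sequence.

**Trans complementarity** between transcripts a and b is
`sw(a, reverse_complement(b))`, symmetric in its arguments (a direct
similarity mode is exposed as a config alternative, since strand handling
in such analyses is often left implicit). Pool comparisons score all
unordered pairs within an enriched pool, within a length-matched
background pool (sampled by 10-quantile length stratification, seeded),
and across the two, and report whether the enriched×enriched maximum
exceeds the maximum observed anywhere else — the "dotted line" contrast.

**SINE homology**: for each motif, up to five top-scoring hit sequences
are each aligned against every reference; the per-reference mean over
hits is reported. Hits are ranked by scan score.

## Motif operations

Motifs are 4×width letter-probability matrices (consensus strings promote
to hard matrices); the consensus is the per-column argmax with
alphabetical tie-break A<C<G<T. Scanning slides a log2-odds matrix
(probabilities smoothed with a background-proportional pseudocount of
0.01; background = empirical mononucleotide frequencies of the input
pool) over both strands and keeps windows scoring at least
`threshold_frac` (default 0.85) of the motif's maximum attainable score.
This max-score-fraction rule is a deliberate, documented stand-in for
MAST-style E-values, whose significance machinery depends on a sequence
composition model that is out of scope; the threshold is configurable.
Overlapping same-motif same-strand hits keep the higher score (ties:
leftmost). All coordinates are 0-based half-open; minus-strand hits are
reported in transcript coordinates.

Spacing statistics: for every hit, the start-to-start distance to the
closest hit with a strictly smaller start on the same transcript (any
motif), grouped by (hit motif, neighbor motif) with per-group medians.
The neighbor is not restricted to the other motif of a pair — restricting
it would hide spurious intervening hits.

`discover_kmers` is a discovery-lite stand-in for de novo motif
discovery, not an equivalence to it: transcript-level k-mer presence
(either strand) in an enriched vs a background pool, one-sided
hypergeometric enrichment, Bonferroni over all 4^k k-mers, and greedy
assembly of significant k-mers overlapping by k−1 into longer strings.
Because presence counts both strands, a planted word may be reported in
reverse-complement orientation.

## Cross-condensate comparison

Per-type detection-frequency vectors are compared by Pearson correlation
over the shared transcript set. Condensate profiles for clustering are
`log2((condensate TPM + 1)/(input TPM + 1))` over the union of enriched
transcripts, centered and unit-scaled per transcript within each
experiment batch (pseudocount +1 on both numerator and denominator;
transcripts absent from the input are excluded). PCA reduces profiles to
5 components; k-means (seeded) clusters them, with k chosen by silhouette
in 2..6 when not fixed. Differential transcripts between exactly two
clusters use a two-sided Wilcoxon rank-sum test on log2(TPM+1) — the
default test of the single-cell FindMarkers convention — with Bonferroni
correction and significance at adjusted p < 0.01. k-means on principal
components replaces graph clustering + UMAP deliberately: it is
deterministic and dependency-light, and the embedding is used only
descriptively.

## The simulator

`generate_pool` draws transcript lengths log-normal (median 2,000 nt,
σ = 0.6, floor 200 nt), sequences i.i.d. at GC 0.45, and input abundances
log-normal with σ = 1.0 before normalization to 10⁶ TPM — a heavy-tailed
pool whose shares span roughly 2.5 decades. The spread was chosen jointly
with the detection-depth scale so that detection frequencies traverse the
full 0–100% range and a e² uptake boost is resolvable against the
30-point residual threshold across most of the abundance range; with a
much wider spread (σ ≳ 1.5) a fixed multiplicative boost becomes
undetectable at both abundance extremes and no depth setting recovers
planted labels reliably. A fraction of transcripts (default 5%) carries a
motif pair — by default a fixed 25-nt consensus and its reverse
complement, mid-range of typical enriched-motif widths — planted on the
forward strand exactly 70 nt apart start-to-start.

`simulate_condensates` draws per-droplet FSC log-normal (median 10⁴,
σ = 0.35), molecule depth D ~ Poisson(depth_scale · FSC^capacity_exponent)
with capacity exponent 3 (volume scaling of a sphere against a linear
size proxy) and depth_scale 10⁻⁹, giving a median depth of ~10³ captured
molecules; the absolute per-droplet copy-number scale is not something
the assay constrains, so this default is an order-of-magnitude choice
documented as such. Per-transcript uptake weight is

    w_t ∝ a_t^βa · exp(βl·log L_t + βm·1[motif pair] + type offset_t)

with defaults βa = 1 (uptake proportional to input frequency),
βl = 0.3 (a modest positive length effect, echoing the positive
length–enrichment correlation seen within abundance bins) and βm = 2.
Counts are multinomial with D trials over weights mixed with ambient
weights — pure input-pool proportions, modeling RNA in the liquid
surrounding the sorted droplet — at ambient fraction 0.05. Detection
noise is purely multinomial; no extra zero-inflation term is added, the
simplest model consistent with the assay. Pseudoalignment fractions are
Beta(40, 2) (mean ≈ 0.95, matching a healthy library).

What the simulator does **not** emulate: read-level effects (no FASTQ,
no coverage profiles), secondary structure and folding, transcript
homology families, batch effects beyond a type offset, droplet doublets,
and any absolute copy-number calibration. Passing tests therefore
demonstrate that the analysis recovers the statistical structure it
assumes — abundance-dominated uptake with multiplicative deviations and
multinomial sampling — not that it is robust to every artifact of real
libraries.

## Degenerate inputs and tie-breaks

- All-zero condensate columns yield all-zero TPM with a warning.
- Identical condensate profiles make clustering degenerate; the embedding
  is flagged and no labels are emitted.
- Zero-variance frequency vectors yield NaN correlations with a warning.
- PWM consensus ties break alphabetically; overlapping scan hits break
  ties leftmost; alignment tracebacks break ties diagonal > up > left.
- Empty sequences score 0 in alignment (not an error); invalid alphabet
  characters raise.

## Known limitations

- The enrichment smoother is univariate (abundance only), matching the
  analysis it implements; length enters only through the binned
  correlation diagnostics.
- Motif-scan significance is a score-fraction threshold, not a calibrated
  E-value; discovered k-mers are consensus strings, not probabilistic
  models.
- Wilcoxon + Bonferroni is conservative for small groups; with fewer than
  ~5 condensates per group the attainable p-values cannot clear a
  Bonferroni-adjusted 0.01 over thousands of transcripts.
- Clustering reproduces type structure only when the profiled transcript
  set actually differs between types; profiling uninformative transcripts
  lets droplet size dominate the first components.
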