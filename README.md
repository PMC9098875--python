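# condenseq

Analysis toolkit for **single-condensate RNA sequencing** — experiments in
which individual phase-separated droplets (synthetic coacervates such as
CM-Dex:PDDA or CM-Dex:pLys, or protein condensates scaffolded by FUS or
Dhh1) are FACS-sorted one per well and their RNA content is sequenced as a
single-cell-style library. The package answers the questions such
experiments pose:

- **Which transcripts are taken up more often than their input abundance
  predicts?** Detection frequency (percent of sequenced condensates in
  which a transcript is detected, i.e. post-filter TPM ≥ 1) is regressed
  on log10 input TPM with a penalized cubic smoothing spline (smoothing
  parameter chosen by generalized cross-validation, a LOESS alternative is
  built in); transcripts with residuals > 30 percentage points are called
  *enriched*.
- **Do enriched transcripts interact through base-pairing?** Sequence
  complementarity is scored by Smith–Waterman local alignment of one
  transcript against the reverse complement of another, under the scheme
  match 2 / mismatch −1 / gap open 30 / gap extend 0.05 (a gap of length L
  costs `open + L·extend`); motif spacing statistics use
  nearest-5′-neighbor start-to-start distances; motif hits are compared to
  SINE (short interspersed element) references under the scheme gap open
  10 / gap extend 0, averaging each motif's top-5 hits.
- **How do condensate types differ?** Pearson correlation of per-type
  detection-frequency profiles, PCA (5 components) + k-means clustering of
  input-normalized enriched-transcript profiles, and Wilcoxon rank-sum
  differential transcripts with a Bonferroni-adjusted threshold of 0.01.

Because the real experiments require a FACS facility, the package ships a
first-class **simulator**: a heavy-tailed input transcript pool with a
planted pair of mutually reverse-complementary motifs, a droplet
population with log-normal sizes, Poisson molecule depth scaling with
droplet volume, abundance-dominated uptake with a motif-dependent boost,
ambient-RNA contamination and multinomial sampling noise. The planted
labels make every stage of the analysis testable end to end.

## Worked example

```python
import condenseq as cq

# input pool: 2,000 transcripts, 5% carry the complementary motif pair
pool = cq.generate_pool(n_transcripts=2000, frac_enriched=0.05,
                        spacing=70, seed=1)
adata = cq.simulate_condensates(pool, cq.UptakeModel(beta_motif=2.0),
                                n_condensates=192, seed=1)

adata = cq.add_tpm(adata)                   # TPM layer, columns sum to 1e6
adata, report = cq.filter_matrix(adata)     # QC cascade + report
results = cq.EnrichmentModel.from_matrix(adata).fit()
print(results.summary())
```

```
Detection-frequency enrichment
==============================================
transcripts                       2000
in smoother fit                   2000
smoother                        spline
residual threshold                30.0
enriched called                     82
mean residual (fit set)         -0.000
sensitivity vs truth             0.820
precision vs truth               1.000
```

82 of 2,000 transcripts sit more than 30 percentage points above the
abundance-expected detection frequency; 82 of the 100 planted
motif-carriers are recovered with no false positives. `results.table`
holds the per-transcript table (input TPM, detection frequency, fitted
frequency, residual, enriched flag, frequency bin), e.g.:

```
               input_tpm  detect_freq  fitted_freq  residual
transcript_id
T00001            564.97        86.46        39.39     47.07
T00015            189.64        64.06        18.56     45.50
```

T00001 is seen in 86% of droplets although its abundance predicts 39% —
the planted motif pair at work. Downstream, `cq.scan` locates the motifs,
`cq.neighbor_distances` recovers the planted 70-nt spacing as an exact
median, and `cq.pool_complementarity` shows the enriched pool's maximum
complementarity score exceeding everything outside it.

A `condenseq` command-line interface wraps each stage
(`simulate`, `qc`, `enrich`, `scan`, `discover`, `complement`, `sine`,
`compare`, `run`); see `condenseq --help`.

## Layout

- `src/condenseq/simulate.py` — transcript pools, uptake model, droplet simulation, fixtures
- `src/condenseq/qc.py` — TPM, QC filter cascade, partition coefficients
- `src/condenseq/enrichment.py` — `EnrichmentModel`/`EnrichmentResults`, smoothers, length correlations
- `src/condenseq/align.py` — Smith–Waterman kernel, complementarity, SINE homology
- `src/condenseq/motifs.py` — PWM scanning, co-occurrence, spacing, k-mer discovery
- `src/condenseq/compare.py` — type correlations, profiles, clustering, differential tests
- `src/condenseq/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats, configuration, pipeline, CLI
- `docs/methods.md` — model details, parameter choices and limitations
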