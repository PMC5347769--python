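# Methods

## The analysis model

The pipeline analyzes an arrayed knockdown screen in which each well of
a plate receives one shRNA construct, each construct is plated in
replicate wells (triplicates by default), and the readout is per-cell
immunofluorescence in two channels: keratin 5 (basal/myoepithelial
marker) and keratin 8 (luminal marker). The biological premise is that
bi-potential tumor cells co-express both keratins (K5⁺K8⁺) and that
knockdowns inducing differentiation shift cells into the K5⁻K8⁺
luminal gate.

### Gating

Thresholds are *control-anchored*: rather than clustering the screen's
own intensities, each channel's cutoff comes from a cell line known to
be negative in that channel — MCF7 (luminal, K5⁻) for the K5 channel
and MCF10A (basal, K8⁻) for K8. The threshold is the calibration
population's mean + `z · SD` on the linear intensity scale with
`z = 2.5` and the sample SD (ddof = 1); gating wells are pooled across
the entire plate set by default (`gating.threshold_scope: screen`), a
per-plate mode exists behind the same config key. Positivity is a
strict inequality, so a cell exactly at the threshold is negative; the
boundary had to be fixed one way for reproducibility and "above the
mean" reads as strictly above. Cells flagged pyknotic are excluded
before any accounting; the flag is taken from the input (the upstream
image-analysis step that detects condensed nuclei is out of scope).

### Well summaries and QC

Percentages of the four populations are computed over analyzable
(non-pyknotic) cells and sum to 100 within 1e-9 for any non-empty well.
A well passes QC iff it has at least `min_cells = 200` analyzable
cells; "fewer than 200" is the exclusion rule, so exactly 200 passes.
A well with zero analyzable cells reports all-zero percentages and
fails QC.

### Hit calling

Construct scores are means over QC-passing replicate wells only;
constructs with no passing wells are carried as `not_scored`, never
dropped. The null pool is the *vector controls* only (empty,
non-specific, GFP) — gating cell-line wells are a different cell type
and never enter the null. Control wells are grouped into per-plate
pseudo-constructs of `replicates_per_construct` wells so that control
and treatment scores average the same number of wells (56 controls per
plate leaves one 2-well group per plate). z-scores use the control
mean and sample SD at the construct level; a construct hits when
`z ≥ 2.5` (inclusive) in a single-positive percentage, and when the
control SD is zero any strict excess over the control mean is reported
as a signed-infinity z. A gene hits when ≥ 2 distinct constructs hit
in the same direction; two constructs hitting in opposite directions
do not make a gene hit.

The screen-level arithmetic is deliberately simple and exact:
`p = control construct hits / control constructs scored`, chance
double-hit `= p·p`, gene-hit frequency `= gene hits / genes targeted`.
The p² arithmetic treats "two hits on one gene" as two independent
draws at the background rate; a binomial treatment accounting for the
actual 4–10 constructs per gene would be a separate diagnostic, not
the reported quantity. The background-frequency denominator (scored
control constructs, not wells) is a convention fixed here for
reproducibility. The absolute-count annotation (did the mean K5⁻K8⁺
*cell count* exceed the control mean, strict inequality) distinguishes
genuine induction from selective loss of double-positive cells; it is
reported alongside hits but is not a hit criterion.

### Cell-size dichotomy and intensity comparison

Cells are split at 830 μm²; a cell exactly on the cutoff counts as
small (the published "<830 / >830" phrasing leaves the boundary
undefined, so it is fixed here). Group intensity comparisons use the
two-sided Welch (unequal-variance) t-test by default — the robust
choice when only "two-tailed Student's t-test" is specified — with a
pooled-variance mode available. Groups of fewer than two values, or
two constant equal groups, are rejected as degenerate.

### qPCR quantification

The efficiency-corrected ratio `E_t^ΔCt_t / E_ref^ΔCt_ref` with
`ΔCt = Ct(control) − Ct(sample)` and HPRT1 as the default reference.
Efficiencies must lie in (1, 2] and default to 2.0 (perfect doubling)
since no standard-curve efficiencies are available. Replicates are
summarized by mean Ct before the ratio; a delta-method SEM on the log
scale is propagated to the report but not modeled further.

### DE filtering and overlap

Up: `log2FC > 0.5` and adjusted p < 0.05; down: `log2FC < −0.5` —
both strict, and the down cutoff mirrors the stated magnitude.
Supplied adjusted p values take precedence; otherwise raw p values are
adjusted by Benjamini–Hochberg (delegated to
`statsmodels.stats.multitest.multipletests`, verified in tests against
an exhaustive step-up evaluation). The adjustment method behind
externally supplied tables is the producer's responsibility. Overlap
counts are exact set intersections per direction.

## The synthetic-data generator

The generator emulates the screen's statistical structure, not its
images: 420 genes × 4–10 constructs × 3 replicate wells at ~1200
seeded cells/well, 56 vector-control wells and gating wells for both
calibration lines on every 384-well plate.

- **Composition.** Each well's cells are multinomial over the four
  populations. Baseline: 4% K5⁻K8⁺, 6% K5⁺K8⁻, 10% K5⁻K8⁻, remainder
  (80%) K5⁺K8⁺ — a bi-potential line in which double positives
  dominate. Effect wells raise K5⁻K8⁺ to 24% (the strongest published
  hit, FGFR2-like), drawing the shift from the double-positive pool.
- **Penetrance.** Each construct of a differentiator gene carries the
  effect with probability 0.8, drawn once per construct — distinct
  shRNAs differ in knockdown strength, which is exactly what the
  ≥2-construct rule must be robust to.
- **Intensities.** Log-normal per population and channel (fluorescence
  is right-skewed): log-mean ln 1000 when positive, ln 100 when
  negative, log-SD 0.35. These defaults put the calibrated
  mean + 2.5 SD gate between the two components with a ~2% false-positive
  rate per channel, i.e. clean but not perfect separation.
- **Counts.** Per-well cell counts are Poisson around the design mean
  times a log-normal well factor (CV 0.10, unit mean); cytotoxic
  constructs use a mean of 120 cells so their wells fail the 200-cell
  QC. 5% of cells are pyknotic.
- **Areas.** A two-component log-normal mixture (log-means ln 600 and
  ln 1200, log-SD 0.3) straddling 830 μm²; effect wells raise the
  big-cell fraction from 0.25 to 0.55, emulating the enlarged
  morphology of differentiated cells.
- **Layout.** Constructs fill plates round-robin; every plate carries
  the full control complement and gating wells. Identical design +
  seed gives byte-identical tables.

**What a green test does not establish.** The generator has no plate
or edge effects, no intensity drift between plates, no cross-talk
between channels, no segmentation errors, and its populations are
exactly log-normal. Green acceptance tests establish that the analysis
correctly recovers the structure it assumes — not that the assumptions
hold for any particular instrument or cell line. The published
screen-scale biological numbers (residual mRNA levels, microarray DE
gene counts) depend on real biology and are not reproduction targets.

## Numerical and design choices

- Sample SD (ddof = 1) everywhere dispersion is estimated from data;
  the calibration convention is not stated upstream, so it is fixed
  here as the standard choice for estimated dispersion, on linear
  (not log-transformed) intensities.
- z at exactly the 2.5 cutoff is a hit (the threshold value itself is
  quoted as the hit bar); intensity exactly at a gate is negative;
  area exactly at 830 μm² is small; absolute-count increase is strict.
- Degenerate inputs fail loudly (typed exceptions naming the violated
  invariant) rather than returning NaNs: too few gating cells or
  control constructs, mixed well IDs, negative intensities,
  out-of-range efficiencies or p values.
- The pipeline expands one run seed into per-stage substreams
  (`SeedSequence.generate_state`, kept below 2³¹) so stages can be
  rerun in isolation reproducibly.
- The published design is internally inconsistent about the gene count
  (481 in one place, 420 where the hit arithmetic is done); the
  default design and the frequency denominator use 420.

## Limitations

- Construct-level scoring assumes replicate wells are exchangeable;
  there is no plate-effect normalization (e.g. B-score/loess), because
  the analyzed screen calibrates against within-plate-set controls.
- The p² chance arithmetic ignores the varying number of constructs
  per gene and is kept exact to the published convention.
- qPCR efficiencies default to 2.0; with true efficiencies below 2
  this overstates fold changes, so standard-curve efficiencies should
  be supplied when available.
- `user-data` mode trusts the pyknotic flag and intensity units of the
  input table; no background subtraction or normalization is applied.
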