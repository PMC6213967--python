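# Methods

## Model and procedure

`methylsex` classifies methylation-array samples by the shapes of two
per-sample, per-sex-chromosome distributions: the histogram of beta-values
(methylation levels) and the histogram of detection p-values. The working
assumptions are:

1. X-inactivation gives female chrX a substantial intermediate-methylation
   component, while male chrX (one active X, no silenced copy) has the
   genome-typical bimodal shape. The same logic extends to aneuploidies:
   any sample with ≥ 2 X chromosomes silences all but one, so XXY looks
   female-like on chrX, and X0 looks male-like.
2. chrY probes only produce confident signal when a Y is present, so the
   chrY detection-p histogram separates Y-bearing from Y-free samples
   almost degenerately.
3. These distribution shapes are stable across tissues and platforms and
   are insensitive to per-site normalisation, because single-site variation
   barely moves a histogram over thousands of probes.

The estimation procedure: build test profiles under the active bin scheme;
re-bin the reference panel to the same scheme; per chromosome, concatenate
test and reference rows, mean-centre the combined beta + detection-p block,
take all principal components with non-negligible variance
(> 1e-12), and run k-means (k = 2, 10 restarts, seeded) on the score
matrix. A cluster's sex is the majority sex of its reference members; the
per-chromosome assignments combine to F/M/N as described in the README.
Anchoring to the reference panel is what makes single-sex test cohorts safe:
the two clusters are pinned by reference members regardless of the test
composition.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| beta bins | 10 equal bins on [0, 1] | profile resolution for methylation levels |
| detection-p edges | 0, 1e-5, 1e-2, 1 | "confident" / "marginal" / "failed" probes |
| fine beta bins | 100 × width 0.01 | panel storage resolution |
| fine detp bins | 18 decade bins, p ≤ 1e-17 … 0.1 < p ≤ 1 | panel storage resolution |
| `retention_fraction` | 0.875 | fraction of concordant samples kept per sex when curating a panel |
| QC `p_cutoff` / `max_fail_frac` | 0.01 / 0.05 | chrX detection-failure rule; strictly *more than* 5% fails |
| beta offset | 100 | stabiliser in β = M / (M + U + offset) |
| `seed` | per call | drives k-means restarts and all simulation |

Bins are left-open/right-closed (`edges[i] < v ≤ edges[i+1]`) with the first
bin additionally closed at 0, so no value in [0, 1] is ever lost and every
proportion vector sums to 1. The retention default 0.875 is the midpoint of
the two curation outcomes the approach was designed around (≈ 0.880 and
≈ 0.870 of the concordant female and male groups respectively); exactly
⌊retention_fraction · n⌋ samples are kept per group, closest first.

## Reference curation

`build_reference` clusters a labelled cohort (profiled at the fine scheme)
on both axes, keeps samples whose chrX and chrY cluster memberships both
match the cell where the bulk of their own label sits, and then trims each
concordant sex group to the retention fraction by distance to the cluster
centres. Distance is the Euclidean norm over the two axes' clustering
spaces combined (per-axis distance to the k-means centroid, then the
hypotenuse); the design was open between per-axis and combined trimming,
and the combined norm was chosen because a single ranking per sample makes
the retained set well-defined without reconciling two axis-wise cuts.
Curation reports a 2 × 4 concordance table (label × chrX/chrY cluster cell)
so the structure of the input cohort is auditable.

## Numerical choices

* **Re-bin alignment.** A coarse scheme is valid when each of its edges
  coincides with a fine edge. Matching is relative (rtol 1e-9, atol 1e-15)
  rather than absolute, because the fine detection-p decade edges near zero
  are closer together than any absolute tolerance that would still accept
  floating-point representations of 0.1, 0.01, … Misaligned edges raise an
  error naming the edge; no interpolation ever happens, so re-binning is an
  exact sum and the identity re-bin is bit-exact.
* **PCA preprocessing.** Columns are mean-centred but not variance-scaled:
  all features are proportions on a common scale, and scaling would inflate
  near-empty bins into noise axes. k-means runs on the full retained score
  matrix by default (a rotation of the centred feature space); a
  `pc1_only` option restricts it to the first component.
* **Determinism.** All randomness flows from one user seed: k-means
  restarts take `(seed + 7919·axis)` mod 2³¹, and the simulator uses a
  single `numpy` generator. Identical inputs and seed reproduce identical
  panels and calls.
* **Sign convention.** PC1 is oriented so female references average
  negative on both axes, making plots comparable across runs.
* **Degenerate inputs.** A sample × chromosome × metric with zero usable
  probes is an error, not a silent zero vector; a clustering axis whose
  clusters do not each contain reference members of a distinct majority sex
  raises "reference did not split"; a cluster whose reference purity falls
  below 90% attaches a warning to every call from that axis.
* **Missing values** are excluded per metric independently before binning
  (a probe with missing beta but valid detection p still contributes to the
  detection-p histogram), and QC counts a missing detection p-value as a
  failure, since an absent p-value conveys no confidence.
* **Probe matching** between matrix and manifest uses the ID intersection
  with a logged count of dropped probes, which is what lets EPIC cohorts
  run against a 450k-style panel.

## The synthetic generator

`simulate_cohort` emulates exactly the features the classifier consumes.
Beta-values come from three-component Beta mixtures
(low Beta(2, 25) / intermediate Beta(10, 10) / high Beta(25, 2)): present
chromosomes without XCI use weights (0.45, 0.10, 0.45); two-X chromosomes
give the intermediate component weight 0.5 (the XCI effect size, tunable
via `xci_intermediate_weight`); chromosomes absent from the karyotype
(chrY in XX and X0) draw diffuse Beta(1.5, 1.5) noise. Detection p-values
are log-normal on the log10 scale: mean −8, sd 1.5 for present chromosomes
(≈ 98% below 1e-5) and mean −0.5, sd 0.8 for absent ones (≈ 97% above
0.01). A bounded uniform perturbation (± 0.01, clamped to [0, 1]) roughens
the beta-values. Default cohort layout is 1000 chrX, 400 chrY and 2000
autosomal probes; autosomal probes carry no sex signal and exist only to
exercise manifest filtering and realistic file shapes.

These choices reproduce the qualitative sex-specific shapes the method
relies on; they are not fitted to any real dataset. The simulator does not
model probe chemistry (type I/II), cross-reactive probes, batch or tissue
effects, or mosaicism, so passing tests demonstrate the correctness of the
machinery and the separability logic — not performance on real arrays,
where effect sizes are smaller and noise is structured. The
`xci_intermediate_weight` knob exists precisely to probe degradation: tests
verify that separation grows monotonically with it and that near its
collapse point the tool degrades with purity warnings rather than crashing.

Problem sizes used by the test suite and the acceptance script — a
100 + 100 reference cohort, a 100-sample four-karyotype test cohort, and
reduced probe counts (300/150/100) in unit tests — were chosen as the
smallest sizes at which the clustering structure is unambiguous, keeping
the full pipeline fast to re-run.

## Default panel

No data files ship with the package. `synthetic_reference_panel()`
deterministically builds a panel (simulate → fine profiles → curate) from a
seed, with `provenance: synthetic` recorded in its metadata; it is intended
for testing and demonstration. Real analyses should curate a panel from a
labelled cohort of the user's own via `build-ref`, which serialises to a
diff-able TSV bundle (`panel_meta.tsv` with edge definitions and labels,
plus one samples × bins table per chromosome × metric).

## Known limitations

* N-calls flag conflicts; they do not distinguish XXY from XX/XY mosaicism,
  nor quantify mosaic fraction.
* Signal-intensity-based estimation (median chrX/chrY intensity cut-offs)
  is out of scope; the tool deliberately works without raw intensities.
* Samples near the collapse of the XCI effect (e.g. heavily degraded
  arrays) may produce low-purity warnings; such calls should be reviewed
  with `plot-distribution` rather than trusted blindly.
* The wider-bin re-estimation workflow for borderline N-samples is manual:
  re-run `estimate` with `--beta-bins 5`; no automatic re-binning is
  attempted.
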