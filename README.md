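# methylsex

Sex estimation and sex-chromosome abnormality detection for Illumina-style
DNA methylation microarray data (HM450k / EPIC).

## The problem

Sex is one of the strongest influences on the genomic distribution of DNA
methylation, and public methylation datasets routinely contain mislabelled
samples — and, less often, samples with atypical sex-chromosome
constitutions (Klinefelter XXY, Turner X0) that a binary male/female check
silently misclassifies. `methylsex` is a quality-control tool for anyone
assembling methylation-array cohorts: it infers each sample's sex from the
*distributions* of its beta-values and detection p-values on the sex
chromosomes, and flags samples whose chrX and chrY evidence conflict.

Two biological facts make the signal strong:

* **X-inactivation.** Female samples carry one silenced X, so many chrX CpGs
  sit at intermediate methylation (β ≈ 0.5). Male chrX looks genome-typical:
  bimodal, with mass near 0 and 1.
* **chrY dosage.** chrY probes in female samples have no target, so their
  detection p-values are large; in males the vast majority detect at
  p ≤ 1e-5.

Because only distribution shapes are used, no raw idat files, signal
intensities or normalisation are needed — plain beta and detection-p tables
suffice.

## The method

For each sample the proportion of probes per bin is computed on each sex
chromosome: by default 10 beta-value bins (0 < β ≤ 0.1, …, 0.9 < β ≤ 1; bin
edges are right-closed, with β = 0 kept in the first bin) and 3 detection-p
bins (p ≤ 1e-5, 1e-5 < p ≤ 0.01, 0.01 < p ≤ 1). The test profiles are
concatenated with those of a curated, labelled reference panel; per
chromosome, the combined beta + detection-p block goes through PCA
(mean-centred) and k-means with k = 2 on the component scores. Each cluster
inherits the sex of the majority of its reference members, giving every test
sample a chrX sex and a chrY sex; the final call is

* **F** if chrX and chrY both say female,
* **M** if both say male,
* **N** if they conflict — candidate mislabel, mosaic or aneuploidy.
  A female-like chrX with a male-like chrY is the Klinefelter (XXY)
  signature; the reverse is the Turner (X0) signature.

Anchoring test samples to the reference panel means even a cohort that is
100% one sex clusters correctly. Reference panels store fine-grained
profiles (100 beta bins of width 0.01; 18 detection-p decade bins), which
re-bin exactly onto any user scheme whose edges align with the fine edges.

Samples whose chrX probes fail detection (p ≥ 0.01) at more than 5% of
probes are flagged by the QC filter (flag, not drop, at estimation time).

A bundled simulator generates cohorts with these distributional signatures
for all four karyotypes (XX, XY, XXY, X0), so the whole tool is testable
without downloading any data; `methylsex.synthetic_reference_panel()`
builds a deterministic synthetic panel on demand.

## Worked example

```python
import methylsex as ms

panel = ms.synthetic_reference_panel(n_per_sex=100, seed=0)
cohort = ms.simulate_cohort(ms.SimulationConfig(n_xx=3, n_xy=3, n_xxy=1, n_x0=1, seed=42))
res = ms.estimate_sex(cohort.matrix, cohort.annot, panel, seed=1)
print(res.calls[["sex_chrX", "sex_chrY", "predicted", "pc1_x", "pc1_y"]].round(3))
```

```
          sex_chrX sex_chrY predicted  pc1_x  pc1_y
sample_id
XX_0001          f        f         F -0.136 -0.725
XX_0002          f        f         F -0.120 -0.726
XX_0003          f        f         F -0.153 -0.728
XY_0001          m        m         M  0.148  0.731
XY_0002          m        m         M  0.152  0.739
XY_0003          m        m         M  0.145  0.724
XXY_0001         f        m         N -0.152  0.721
X0_0001          m        f         N  0.159 -0.743
```

The XX samples are called F and the XY samples M on both chromosomes. The
XXY sample clusters with females on chrX (negative `pc1_x`, the
X-inactivation signature of its second X) but with males on chrY — the
conflict yields N with the Klinefelter signature. The X0 sample shows the
mirror-image Turner signature. `pc1_x`/`pc1_y` are the first principal
component scores of the chrX and chrY profile blocks, oriented so female
references average negative.

The same pipeline is available from the shell:

```bash
methylsex simulate --config sim.yaml --out data/
methylsex build-ref --beta beta.tsv --detp detp.tsv --manifest manifest.tsv \
    --labels labels.tsv --out panel/ --retention 0.875 --seed 1
methylsex estimate --beta beta.tsv --detp detp.tsv --manifest manifest.tsv \
    --panel panel/ --seed 1 --out results.tsv
methylsex qc --detp detp.tsv --manifest manifest.tsv --out qc.tsv
methylsex plot-estimation --results results.tsv --out pc1.png
methylsex plot-distribution --beta beta.tsv --detp detp.tsv \
    --manifest manifest.tsv --panel panel/ --sample SAMPLE_ID --out dist.png
```

Inputs are tab-separated text (gzip transparent): matrices with a probe-ID
first column and sample-ID header, a manifest with `probe_id` and
`chromosome` columns ("X"/"chrX", "Y"/"chrY", anything else autosomal).

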