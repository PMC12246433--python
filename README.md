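# endomir

Where do the miRNAs circulating in blood come from?  The endothelium — the
cell layer lining every vessel — is in constant contact with the
bloodstream and secretes miRNAs of its own, distinct from the ones it
keeps intracellularly.  `endomir` is an analysis pipeline for microarray
miRNA profiling of endothelial cultures, their conditioned media and blood
samples, built to separate the endothelial secretome's contribution to
circulating miRNA patterns from intracellular release and from blood-cell
sources.  It is aimed at transcriptomics analysts working with
Agilent-style probe-level intensity exports, and ships a synthetic-array
generator with full ground truth so every stage can be validated.

## What it computes

Given probe x sample intensities and a sample sheet (compartment, donor,
culture medium, time point, RNA input), the pipeline chains:

1. **Serial-dilution probe QC** — per-probe Pearson correlation of
   intensity vs input amount across a pooled dilution series; probes
   without significant dose-response (two-sided p >= alpha) are dropped.
2. **Detection threshold** — the mean intensity of probes newly detected
   with each increase of input material; a probe is later called
   "detected" when its signal strictly exceeds this threshold.
3. **Fraction normalization** — each sample's signature is its miRNA
   fractions of total signal, x_p / sum_p x_p, exactly invariant to
   per-sample input scaling (no spike-ins needed).
4. **Signatures and partition** — averaged intracellular (cell pellet) and
   secretory (conditioned medium) signatures; the detected universe splits
   into intracellular-only, secreted-only and shared miRNAs.
5. **Correlation blocks and PCA** — Spearman correlation matrices over
   signatures with block summaries (mean +/- SD of pairwise rho),
   Student/Welch/Mann-Whitney comparisons of coefficient groups, and
   centered-SVD PCA.
6. **Blood attribution** — serum/plasma miRNAs classified as endothelial
   (present in the endothelial reference) or non-endothelial, and block
   correlations of blood samples against endothelial and leukocyte
   signatures.
7. **Time-course trends** — per-miRNA Pearson correlation of expression vs
   time; categories increasing / decreasing / unchanged at p < alpha, in
   both normalized-fraction and raw-intensity modes, cross-referenced
   between the secretory and intracellular fractions.

The model assumptions, default parameters and the synthetic generator's
design are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate the full synthetic study (4 donors x 4 media culture grid,
dilution series, time course, blood panel) and run every stage:

```sh
endomir simulate --preset full_study --seed 1 --outdir scratch/sim
endomir run --stage all --matrix scratch/sim/matrix.tsv \
    --sheet scratch/sim/samples.tsv --flags scratch/sim/flags.tsv \
    --outdir scratch/out
```

The same analyses as numbered scripts (writing summaries under
`results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_probe_qc.py
python analysis/03_culture_signatures.py
python analysis/04_timecourse_trends.py
python analysis/05_blood_panel.py
```

Output of the bundled run (seed 1):

```
probes tested: 900; filtered: 22 (2.44%)
detection threshold (mean intensity of newly detected probes): 0.0526
detected per cell sample: 406 (+/- 1); per conditioned medium: 412 (+/- 1)
partition of 572 detected miRNAs: 157 intracellular-only, 165 secreted-only, 250 both
averaged int vs sec signature: rho = -0.1539 (p = 0.00026)
same donor across media: rho = 0.851 (+/- 0.0058); same medium across donors: rho = 0.9624 (+/- 0.0037); Welch p = 3.1e-44
secretory intensity trends over 414 detected sec-miRs: 160 increasing, 37 decreasing, 217 unchanged
    serum~endo_sec: 0.8281 (+/- 0.0033, 64 pairs)
   plasma~endo_sec: 0.6064 (+/- 0.0062, 64 pairs)
```

Reading the numbers: the dose-response filter removes the 2.4% of probes
without quantitative response (the generator planted 2.7%, a few pass by
chance at this noise level); the detected partition is within a few miRNAs
of the planted 155/166/253 design; the intracellular and secretory
signatures are essentially unrelated patterns (rho near zero over the
union of their supports); culture medium separates samples more than donor
identity does; and serum patterns track the endothelial secretory
signature markedly better than plasma patterns do — the ordering the blood
panel is designed to expose.

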