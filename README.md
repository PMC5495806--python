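# hiriefquant

Downstream analysis of HiRIEF-based TMT 10-plex phosphoproteomics
experiments, with a ground-truth synthetic-data generator for
end-to-end validation.

High-resolution isoelectric focusing (HiRIEF) fractionates tryptic
peptides on immobilized pH-gradient (IPG) strips cut into 72 narrow-pH
fractions before LC-MS. Because each phosphate group adds two acidic
ionizations (pKa ≈ 1.2 and 6.5), phospho-peptides focus at lower pH
than their unmodified counterparts, and multiply phosphorylated
peptides focus at the acidic end of an ultra-acidic (pH 2.5–3.7)
strip. This package implements the computational side of such an
experiment for proteomics analysts: from peptide-spectrum-match (PSM)
tables with TMT reporter intensities down to per-site regulation calls
and functionality annotation.

## What it computes

**Isoelectric model.** Peptide net charge at pH *x* by
Henderson–Hasselbalch summation,

  Z(x) = Σ_basic 1/(1+10^(x−pKa)) − Σ_acidic 1/(1+10^(pKa−x)),

with TMT labeling removing the N-terminal and lysine amine charges and
each phosphate contributing two acidic terms. The pI is the unique
root of Z, found by bisection; a linear strip maps pI to a 1-based
fraction index. A fraction-shift analysis groups peptides into four
acidity/basicity composition classes (counts of D+E vs. K+H+R) and
reports the mean shift induced by one or two phosphorylations.

**Quantification.** PSMs are kept only with a complete set of ten
reporter ions and, for phospho-PSMs, a localization score ≥ 95.
Per-channel ratios divide each intensity by the mean of the four
untreated channels. Phospho-site ratios are medians over supporting
PSM ratios keyed by (gene, protein, position, residue); gene-level
protein ratios are medians over PSM ratios, median-centered per
channel, and subtracted (in log2) from site ratios to remove
protein-abundance changes. Also included: reagent isotopic-impurity
correction by solving the 10×10 mixing system, top-3 precursor-area
protein abundance, peptide-to-fraction assignment, 15-residue sequence
windows, and "picked" target/decoy protein FDR.

**Differential analysis.** Per treated condition, a two-sample t-test
of normalized site log2 ratios against the untreated replicates;
Benjamini–Hochberg correction across sites within a condition; a site
is significantly regulated at q < 0.01 with fold change > 2. A
discordance analysis compares calls made from singly- versus
multiply-phosphorylated peptide rollups, and hierarchical clustering
(complete linkage, Euclidean distance) orders sites and channels.

**Annotation.** Cross-referencing against a known-site reference,
functionality classes from kinase-association scores (functional /
putatively functional at score ≥ 3 / low-scoring / unscored),
Fisher-exact protein-class enrichment, and novel-vs-known abundance
bias tests.

**Synthetic data.** `simulate_experiment` generates a random proteome,
digests it (trypsin, K/R not before P, up to 2 missed cleavages) and
emits PSM tables for both the phospho and the standard arm under the
ten-channel design (4 untreated, 3 pervanadate, 3 mitotic-arrest),
with known per-site fold changes: pervanadate raises pTyr ~10-fold,
mitotic arrest shifts pSer/pThr. Reporter noise is multiplicative
lognormal; intensities pass through a configurable impurity matrix.

## Worked example

```python
import hiriefquant as hq

config = hq.SimConfig(n_proteins=60, seed=11, noise_cv=0.1)
sim = hq.simulate_experiment(config)
result = hq.run_pipeline(
    sim.psms_phospho,
    sim.psms_standard,
    protein_sequences=dict(sim.proteome),
    ground_truth=sim.ground_truth,
)
for key in ("n_psms_phospho_in", "n_psms_phospho_kept", "n_sites_quantified",
            "n_significant_pervanadate", "n_significant_mitotic",
            "n_significant_multiply_only", "median_abs_error_log2fc"):
    print(key, result.summary[key])
```

prints

```
n_psms_phospho_in 2574
n_psms_phospho_kept 2211
n_sites_quantified 249
n_significant_pervanadate 11
n_significant_mitotic 103
n_significant_multiply_only 18
median_abs_error_log2fc 0.03211387099623089
```

Of 2,574 simulated phospho-arm PSMs, 2,211 survive the complete-reporter
and localization filters and quantify 249 unique phospho-sites; 11
sites are called regulated after pervanadate (the simulated pTyr
effect) and 103 after mitotic arrest, 18 sites are regulated only when
seen in multiply phosphorylated peptides, and the recovered log2 fold
changes have a median absolute error of 0.03 against the simulator's
ground truth. `result.sites` carries the per-channel normalized ratios
and sequence windows, e.g.:

```
    gene  position residue sequence_window  n_supporting_psms
GENE0001        17       S LQGDSQLSMYEMLIN                  1
GENE0001       259       S KRIENCQSVLDVTWN                  9
```

The same stages are exposed on the command line via the `hiriefquant`
entry point (`simulate`, `pi`, `shift`, `quantify-sites`,
`quantify-proteins`, `fdr`, `test`, `annotate`, `run-all`); try
`hiriefquant run-all --simulate --seed 5 --outdir out/`.

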