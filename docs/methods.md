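# Methods

## Isoelectric-point model

Peptide charge is the standard Henderson–Hasselbalch summation over
ionizable groups. Basic groups (free α-amine, lysine ε-amine,
arginine, histidine) contribute `1/(1+10^(pH−pKa))`; acidic groups
(C-terminus, Asp, Glu, Cys, Tyr) contribute `−1/(1+10^(pKa−pH))`.
Each phosphate adds two acidic ionizations. The defaults are the
EMBOSS side-chain pKa set (N-term 8.6, C-term 3.6, D 3.9, E 4.1,
C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5) with phosphate pKas 1.2 and
6.5; every value is overridable through `PKaSet`. Cys and Tyr
ionizations are included because they matter near neutral pI.

TMT reagents label primary amines, so the default charge state
(`tmt_labeled=True`) removes the N-terminal and lysine basic groups —
the state of every peptide in an isobaric-labeling experiment. The
unlabeled state is available for free peptides. A TMT-labeled peptide
with no Arg or His has no basic group, its charge never crosses zero,
and `isoelectric_point` raises; the simulator treats such peptides as
running to the acidic edge of the strip.

The charge is continuous and strictly decreasing in pH, so the pI is
the unique root; bisection on (0, 14) converges to the default
tolerance of 1e-4 pH units in ~47 halvings. Tests verify the root
against a coarse-to-fine grid scan of the charge curve.

Strip geometry is linear: fraction *i* of *n* covers the half-open
interval `[ph_min+(i−1)w, ph_min+iw)` with `w = (ph_max−ph_min)/n`,
the last fraction closed at `ph_max`, numbering from the acidic end.
Presets are the ultra-acidic (2.5–3.7) and wide-range (3–10) strips,
72 fractions each. A pI outside the gradient does not focus; by
default such peptides are excluded from shift tables (a clamp-to-edge
mode exists for completeness, since in practice unfocused material
runs to the strip ends).

The fraction-shift analysis requires each phospho-peptide's unmodified
counterpart, computes `shift = fraction(phospho) − fraction(unmodified)`
on one strip geometry, and groups peptides into four composition
classes. The class boundaries are quartiles of the net-acidity score
`(#D+#E) − (#K+#H+#R)` over the analyzed set — the published analysis
groups by acidity/basicity without stating boundaries, so quantiles
keep the four groups populated for any input population. On random
tryptic-like peptides the model reproduces the expected structure:
all shifts point to the acidic end, basic classes shift 2–5× farther
than acidic ones, and double phosphorylation adds roughly 6–8
fractions over single phosphorylation on the wide-range strip. The
absolute magnitudes depend on the peptide population and the gradient,
so tests assert directions and orderings, not specific fraction
counts.

## Synthetic experiment

The generator emulates the statistical structure the analysis assumes,
not mass spectra. Proteins are i.i.d. sequences at human-like residue
frequencies with gamma-distributed lengths (default mean 450);
digestion is tryptic (cleave after K/R unless before P, ≤2 missed
cleavages, via pyteomics), and only peptides of 6–40 residues are
emitted — a typical detectability window.

Phospho-sites are drawn per residue so that the expected S/T/Y mix is
0.79/0.15/0.06 (the split typical of large-scale human
phosphoproteomes) at an overall rate of 5% of S/T/Y residues. A site
is regulated with probability 0.4; regulated Tyr sites get a
pervanadate log2 fold change of log2(10) (tyrosine-phosphatase
inhibition raises pTyr about ten-fold), regulated Ser/Thr sites get a
mitotic-arrest effect of magnitude uniform in [1.2, 3] with 20%
down-regulated, and a 5% leak rate swaps the responding condition so
the residue–condition association is strong but not absolute.
Unregulated sites have fold change exactly zero, so |log2FC| > 1 iff
regulated. The per-condition effect-size distributions are free
parameters of the generator, not estimates of any real dataset.

Protein-level changes are modeled separately: 10% of proteins change
under mitotic arrest (normal, sd 0.5 log2 units), none under
pervanadate. A phospho-PSM's expected intensity multiplies the protein
change and the phospho-specific change, so protein normalization must
subtract the former to recover the latter — exactly what the pipeline
is supposed to do, and what `recovery_metrics` scores.

For a peptide carrying *k* sites, the generator emits each singly
phosphorylated form plus, for *k* ≥ 2, the fully phosphorylated form
whose fold change is the **sum** of its member sites' fold changes
(co-dependent stoichiometry). This is what makes singly- and
multiply-phosphorylated rollups disagree for sites sharing a peptide
with a regulated neighbor, exercising the discordance analysis with
known direction.

Reporter noise is multiplicative lognormal with mean 1 and
configurable CV (default 0.1) — the standard error model for
reporter-ion intensities; intensities then pass through the reagent
impurity matrix. `ImpurityMatrix.two_isotope` builds a vendor-style
synthetic matrix where each reagent spills a few percent into the
channel two list-positions away (the +1 Da isotope of an N-form
reagent lands in the next N channel), defaults 1%/3%. Ten percent of
phospho-PSMs receive a localization score below 95 and 5% get one
zeroed reporter so the filters have work to do.

What the simulation does **not** model: spectra, retention time,
co-isolation interference, missing channels other than the zeroed
reporter, search-engine score distributions, shared peptides between
proteins, or biological replicate covariance beyond i.i.d. noise.
Passing tests therefore demonstrate correctness of the computational
chain under its stated assumptions, not robustness to every pathology
of real data.

## Quantification chain

Filtering keeps PSMs with all ten reporters strictly positive
(zero-intensity channels are treated as missing, never imputed) and,
for phospho-PSMs only, localization ≥ 95. Ratios divide each channel
by the arithmetic mean of the untreated channels, making the four
control ratios average to exactly 1 per PSM. Site rollups take the
median of supporting PSM ratios (even counts: mean of the central
pair), keyed by protein position so missed-cleavage variants collapse
to one row; restricted rollups over singly or multiply phosphorylated
peptides feed the discordance analysis. Protein rollups are gene-level
medians, median-centered per channel in log2 under the equal-loading
assumption; site normalization subtracts the protein log2 ratio and
drops (and reports) sites whose gene has no protein quantification.
Impurity correction — solving `M·x = observed` and clamping negatives —
is off by default and enabled by a flag, since the benchmark analysis
quantified the impurity effect without correcting it. Picked protein
FDR keeps the better-scoring member of each target/decoy pair (ties go
to the decoy, the conservative choice), ranks by score and converts
decoy/target counts to q-values by a running minimum from the bottom.

## Differential testing

Per condition, an equal-variance two-sample t-test of treated versus
untreated normalized log2 ratios (Welch behind a flag); BH correction
is applied within each condition across all tested sites. Zero-variance
degenerate inputs get p = 1 and a flag rather than NaN. The reported
fold change is the mean of the treated replicates' normalized log2
ratios, and significance requires q < 0.01 and |log2FC| > 1 on the
normalized scale (the quantity analyzed throughout). Clustering uses
scipy's complete-linkage agglomeration on Euclidean distances;
determinism follows from scipy's index-based tie-breaking given a
fixed input order.

## Annotation

Reference matching is exact on (protein accession, 1-based position,
residue); no isoform mapping is attempted, and a position that matches
with a different residue triggers a coordinate-convention warning
rather than a silent mismatch. Functional classes have precedence:
reference-reported function first, then score ≥ 3 (kinase-association
scores are proteome-normalized so 3 marks a confident prediction),
then low-scoring; unpredicted sites are "unscored" and excluded from
class denominators. Class enrichment uses a one-sided Fisher exact
test (enrichment direction; two-sided by flag) after excluding genes
in more than one class. The abundance-bias test runs on log10
precursor areas because areas span orders of magnitude, reporting
medians on the raw scale.

## Problem sizes and numerical choices

Default test and acceptance runs simulate 40–60 proteins (~200–250
quantified sites, ~15,000 PSMs), enough for stable medians and
regulation calls while keeping a full pipeline run under a second.
The pI grid-scan cross-check uses 1,000 random peptides at a 1e-4 pH
grid against the 1e-4 bisection tolerance, asserting agreement within
1e-3. Fraction-boundary arithmetic enforces the half-open interval
definition explicitly to avoid float-rounding misassignment at exact
edges. All randomness flows from a single integer seed per run; two
runs with the same configuration are byte-identical.
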