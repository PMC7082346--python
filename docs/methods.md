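# Methods

## Codon complementarity

All codon statistics are computed over a genome's concatenated annotated
CDS, read in frame from position 0 with stop codons included, so every
vector lives on the full 64-codon basis (fixed alphabetical order
AAA…TTT). Triplets containing ambiguous bases are skipped and tallied;
CDS whose clean length is not a multiple of 3 are used with the trailing
remainder dropped rather than rejected, since real annotations contain
partial and pseudo genes. %GC is computed over whole replicon sequences
(pooled across contigs for multi-replicon hosts), excluding ambiguous
bases from both numerator and denominator.

RSCU for codon *j* in a synonymous family of size *n* with counts *X* is
X_j / ((1/n)·ΣX); unobserved families are marked undefined rather than
0/0. The phage–host distance is the cosine distance D_c between the codon
relative-frequency vectors; the per-codon impact substitutes one phage
entry at a time with the host's value and records |ΔD_c|.

**No renormalization after substitution.** The substituted vector is left
unnormalized deliberately: the substitution is a literal single-entry
replacement, and cosine distance is invariant to overall scale, so the
vector need not sum to one. Renormalizing the remaining 63 entries would
smear the perturbation across all codons and change what the score
attributes to the substituted codon. This is the main genuinely open
design point in the measure; comparison against the published values for
the real genome pairs (the accession-based check) is the adjudicator.

**Group comparisons.** Impact distributions are compared across all
unordered group pairs two-sidedly, with Holm–Bonferroni step-down applied
over the whole family of comparisons. The t test defaults to Welch
(unequal variances) — the safer choice when panel sizes and spreads
differ — with a flag for pooled-variance Student; the rank-based
alternative is the Wilcoxon rank-sum (Mann–Whitney) test.

## Expression processing

FPKM divides fragment counts by gene length (kb) and sequencing depth
(millions of fragments), with **host and phage gene strata normalized
separately**: each stratum's depth in a sample is the summed counts of
its own genes, so phage expression is comparable across samples
regardless of how much host background they carry. A stratum with zero
fragments in a sample (phage genes in uninfected libraries) yields FPKM 0
with a warning; a sample with zero total fragments is an error. The log2
transform uses a +1 pseudocount so zero expression maps to zero;
per-gene z-scores use the sample standard deviation (n−1), with constant
rows set to zero and flagged. Library strandedness is reported as
reverse-strand over total mapped fragments with a strict >95% pass rule.

**Infected-fraction-adjusted fold change.** Only a fraction *f* of cells
in an "infected" culture are true virocells; the observed mean is modeled
as the two-component mixture X_I = f·X_v + (1−f)·X_U. The virocell
signal is deconvolved as X_v = (X_I − (1−f)·X_U)/f, floored at zero
(negative deconvolved expression is measurement noise), and
log2FC = log2((X_v+1)/(X_U+1)). The exact published form of this
adjustment is not printed in the source literature's main text; the
mixture deconvolution is this package's explicit interpretation and the
synthetic generator constructs its data by the same mixture, making the
pair an exactly invertible (and tested) system.

**Temporal clustering.** Genes are clustered on their mean-per-timepoint
profiles with average-linkage hierarchical clustering on the distance
1 − Pearson r, cut at *k* clusters (k = 3 for early/middle/late). The
correlation measure is given; average linkage is this package's choice.
Stability is estimated by reclustering B = 100 random subsets of the
timepoint columns (75% of columns, at least 3, without replacement) and
scoring each gene by how often it lands with the majority of its final
cluster. Subsampling columns rather than genes is deliberate: with few
timepoints, perturbing the time axis is the meaningful robustness probe.
Genes with zero temporal variance carry no signal for a correlation
distance and are excluded with a warning. The whole procedure is
deterministic given its seed.

**Stage labels.** Clusters are ranked by the timepoint of their centroid
maximum (ties broken by which centroid crosses half its range earlier)
and labeled early/middle/late in that order. Indistinguishable centroids
raise an error demanding a manual label — deterministic rules replace the
hand-tuning that interactive analyses apply, so occasional divergence
from hand-curated cluster boundaries on real data is expected.

**DE set algebra.** Per-virocell differentially-expressed gene sets and
their overlaps are computed from externally supplied significance calls
when available; otherwise a stand-in threshold on adjusted |log2FC| ≥ 1
(any timepoint) is used and labeled as such. Proper count-model
significance testing (e.g. edgeR/DESeq2 dispersion modeling) is out of
scope here.

## Global trend models

Per-sample total transcript or protein counts are fit by Gaussian least
squares as `counts ~ treatment + time + time² + treatment:time` with
reference-level treatment coding (uninfected as reference for host
models). Modeling raw counts rather than a count GLM is deliberate
fidelity to how these global time-course summaries are conventionally
analysed; the interaction is treatment × linear time, with
treatment × time² available behind a flag. Effects are tested
sequentially (type-I): treatment, then the linear and quadratic time
terms jointly (2 df), then the interaction, each F using the full-model
mean squared error — the same construction R's `anova(lm)` prints.
Fitted curves carry Bonferroni simultaneous bands: half-width
t(1 − α/(2m), df_resid)·se(x'β) with m defaulting to the number of
grid × treatment points. Tukey pairwise comparisons use the studentized
range on model contrasts: "level" compares fitted means at the average
observed time, "slope" compares linear time trends; with two treatments
the procedure reduces exactly to a t test.

## Synthetic data: what it emulates and what it does not

**Genomes.** Coding sequences are sampled codon-by-codon from a
per-amino-acid codon-usage profile under a typical bacterial amino-acid
composition, 300 CDS of ~300 codons (sd 60) for hosts and 100 CDS for
phages — the scale of a small bacterial chromosome fragment and of a
tailed phage — with alternating strands and 20 nt intergenic spacers.
Phage divergence moves probability mass δ within the synonymous families
of chosen target codons, so amino-acid composition is held fixed and the
divergence is purely synonymous — isolating codon-level from
protein-level complementarity. The default plant (δ = 0.3, six target
codons) takes the least-used codon from each of the six most-used
amino-acid families having ≥ 4 synonymous codons: shifts in rare families
drown in multinomial sampling noise, and in 2-codon families the sibling
codon absorbs exactly the shifted mass, making target and sibling
formally indistinguishable. Generated genomes are written as GenBank and
round-trip through the package's own readers.

**Expression.** Control means follow a lognormal baseline (median 1000
fragments, floored at 500 — deep-sequencing scale, which also keeps the
+1 pseudocount negligible); 30% of host genes are differentially
expressed with peak |log2FC| between 1 and 3 ramping linearly over the
time course; phage genes follow early/middle/late Gaussian bump
templates and are silent in uninfected samples. The observed infected
mean is the f-mixture above with f = 0.95 by default (a high-MOI
infection; at MOI ≈ 5 nearly every cell is infected). Counts are
negative-binomial with dispersion 0.05 (var = μ + 0.05 μ²), a typical
bulk-RNA-seq replicate dispersion; dispersion 0 gives the deterministic
noiseless limit used by the inversion tests. Five timepoints spanning an
hour of infection with biological triplicates mirror a one-step-growth
sampling design; 200 host + 60 phage genes keep the default suite fast —
problem sizes are package defaults, not statements about real genome
sizes.

What passing these tests shows: the implementation inverts its own
generative assumptions exactly and recovers planted structure under
realistic noise. What it does not show: robustness to features the
generator omits — operon structure and correlated genes, rRNA carryover,
batch effects, non-NB overdispersion, partially synchronized infections
(f varying across genes rather than per timepoint), or hand-curated
cluster boundaries.

## Numerical choices

- Canonical codon order alphabetical everywhere (vectors, TSVs).
- Impact-ranking ties broken by codon alphabetical order.
- Translation table 11 by default, overridable per CDS.
- Internal coordinates 0-based half-open; GenBank converts at the file
  boundary only.
- Zero-norm frequency vectors, zero library depth, f = 0, and empty gene
  sets are errors, not silent NaNs; skipped entities (out-of-bounds CDS,
  unparseable pairs) always land in a report.
- Seeds propagate to every random draw; identical config + seed yields
  byte-identical outputs (checksummed in each run report).

## Known limitations

- The published codon distances and %GC for the real
  *Pseudoalteromonas*/PSA-HP1/PSA-HS2 genomes can only be recomputed when
  the deposited GenBank records are present locally
  (`scripts/fetch_genomes.py`); they are not bundled.
- The stability score perturbs timepoints, not genes; it is not a
  reimplementation of any specific published resampling package.
- Raw-count least squares ignores mean–variance coupling; its F tests
  are calibrated under the Gaussian null (verified by simulation) but a
  count GLM would be the orthodox choice for strongly heteroscedastic
  data.
- Differential-expression significance calling is external; the built-in
  |log2FC| threshold is a labeled stand-in.
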