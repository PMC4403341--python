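# Methods

`regland` implements the computational core of a two-state regulatory-landscape
analysis: melanoma cultures (and tumours) occupy either a *proliferative*
(MITF/SOX10-high) or an *invasive* (ZEB1/SOX9-high) transcriptional state, and
the pipeline decodes which transcription factors drive each state from
chromatin activity (H3K27ac, FAIRE), expression counts and a genome-wide
catalog of candidate regulatory regions. Every stage runs on synthetic data
with planted ground truth, so each claim the pipeline makes is testable.

## Candidate-region catalog

Regulatory feature tracks are union-merged (abutting intervals join — the
natural reading of "merge" and the convention of standard interval tools).
Merged regions overlapping insulators by ≥20% or coding exons by ≥80% of the
*region's* length are removed; surviving regions are cut at every blacklist
boundary and the covered pieces dropped; fragments <30 bp are removed; and
regions shorter than 1 kb are extended toward 1 kb where possible — symmetric
first, with any blocked deficit pushed to the open side. Extension never
crosses a blacklist element, a chromosome end or another catalog region, and
always leaves ≥1 bp between regions so that rebuilding the catalog from its
own output is the identity (idempotence is a tested invariant). Overlap
fractions are measured relative to the candidate region because the removal
rule concerns the region's identity and the split rule's "regions containing
the element" only parses region-relatively; the thresholds are configurable.
Coordinates are 0-based half-open throughout; 1-based conversion happens only
at the GFF boundary. Regions get stable `chrom:start-end` IDs after
extension.

Each build stage is verified against a brute-force per-bp boolean-array
oracle on random ≤100 kb genomes.

## Differential activity and signatures

Counts are normalised with median-of-ratios size factors (geometric-mean
pseudo-reference over all-positive rows) and log-transformed as
log2(count/factor + 1). Note that these factors are invariant to a global
rescaling of the matrix and only their *ratios* are equivariant to scaling a
single sample; tests assert the ratio form.

The two-group test is a per-row negative-binomial Wald test — a documented
stand-in for an external caller, with the TSV interfaces accepting externally
produced result tables as drop-ins. Dispersion (Var = μ + αμ²) is a per-row
method-of-moments estimate from within-group residuals, shrunk toward the
matrix-wide mean with weight df/(df + 10); the prior weight of 10
pseudo-observations makes the 11-sample default design borrow roughly half
its dispersion information from the ensemble. Fold changes use shrunken group
means (normalised mean + 0.5) to stay finite; the Wald statistic is referred
to a t distribution with n_A + n_B − 2 degrees of freedom rather than a
normal — with only two samples in one group the normal reference is
anti-conservative, and the t reference keeps the null type-I error at
α = 0.05 inside [0.03, 0.07] in the calibration simulation. All-zero rows
get p = 1 and log2FC = 0. BH adjustment is applied across rows (Bonferroni
is reserved for the motif/track enrichment, where the original analysis used
it).

State-specific regions are called in two stages: adjP ≤ 0.05 and
|log2FC| ≥ 1, then a pooled-count binomial support filter (the stand-in for
independent differential peak calls): pooled state counts are tested against
the size-factor expectation, BH q < 0.05, and the direction must agree with
stage 1; the final sets are the intersection, and q = 1 disables stage 2
exactly. Gene signatures use the same thresholds, with the sign of log2FC
assigning the state.

Methylation evidence is aggregated per region: Welch t-tests per CpG at
α = 1e−10 select significant probes; regions with ≥2 such probes are scored
by a t-test on per-sample medians of their probes' beta values at α = 0.05.

## Motif and track enrichment

Every feature induces one complete ranking of all M catalog regions. Motif
scores are best-single-site log-odds: max over windows and both strands of
Σ log2(p(base)/q(base)), with N contributing the background expectation and
sub-PWM-length sequences scoring −∞. This replaces an HMM/CRM scorer by
design — it is deterministic and oracle-checkable, and the ranking interface
accepts any externally computed per-region score. Track scores are the
maximum score of overlapping peaks (any 1-bp overlap counts; 0 without
overlap). Ties are broken by a seeded uniform shuffle (recorded), because the
recovery statistic is rank-sensitive.

A foreground set is scored per feature by the mean of its cumulative recovery
curve over the top T = ⌈0.0025·M⌉ ranks (ceiling chosen for the desk-scale
case where 0.25% of M is fractional). AUCs are standardised across the
feature collection, NES = (AUC − μ)/σ with population σ by default
(configurable to sample σ). Significance is the hypergeometric upper tail of
the foreground count inside the cutoff, Bonferroni-corrected across features.
A feature's predicted direct targets are the foreground regions inside the
fixed cutoff; the intersection of motif and track targets gives the
high-confidence direct target set.

Rankings from multiple score sources (standing in for multi-species
liftovers) are merged by the uniform-order-statistics Q: for sorted rank
ratios s₁ ≤ … ≤ s_N, Q = N!·V_N with V_k = Σᵢ (−1)^(i−1) V_{k−i}
s_{N−k+1}^i / i!, the joint probability that N iid uniform order statistics
fall below the observed ratios; regions are re-ranked by ascending Q. Q is
validated against Monte-Carlo joint-tail estimates for N ≤ 5.

## Region-to-gene assignment and TF networks

A differential region is linked to a gene when (i) the gene's TSS lies within
the distance window (measured TSS-to-nearest-region-edge; midpoint optional),
(ii) the gene itself is differential (adjusted p ≤ ge_alpha and
|log2FC| ≥ 1 — genes failing this are ignored entirely), and (iii) the
Pearson correlation between the region's activity profile and the gene's
expression profile across the sample panel passes the threshold (absolute or
positive-only). The defaults (1 Mb, 0.1, |r| ≥ 0.3) are the settings used to
build the final networks; the full grid (10 kb–2 Mb; 0.05/0.1/1;
0/0.1/0.3/0.5/0.7) is exposed, and relaxing any threshold can only add links
(a tested invariant). A region may link to several genes and vice versa;
`closest_only` optionally keeps the nearest qualifying gene. Gene strand is
ignored — only the TSS position enters.

A TF's network is the link table restricted to the TF's predicted target
regions. Networks are compared by target-gene overlap (hypergeometric upper
tail) and validated with pre-ranked GSEA: running-sum ES with hit increments
∝ |score|^p (p = 1 default) and miss decrements 1/(N − |S|), null by seeded
gene-set permutation (1,000 default), NES = ES normalised by the mean
same-signed null magnitude and an FDR q from the same-signed null tail. The
co-expression ranking fed to GSEA is plain correlation-derived (a documented
stand-in for tree-ensemble network inference, which is out of scope).
Signature-vs-phenotype analyses use the Pearson correlation of mean signature
expression with the per-sample phenotype.

## State classification

Expression samples are clustered by Frobenius NMF with Lee–Seung
multiplicative updates (own implementation because the tests assert the error
trace is non-increasing at every iteration; an sklearn multiplicative-update
fit is the independent cross-check). Genes are first filtered to sample
standard deviation strictly above 1; input is log2(normalised + 1) without
centering, preserving non-negativity. Defaults: k = 3 (two states plus an
immune-like confounder group), 10 random restarts keeping the best final
error, ≤2,000 iterations or relative-error change <1e−6. Samples take the
cluster of their largest H coefficient. Cluster rankings contrast one cluster
against the rest and score genes by sign(log2FC)·(−log10 adjP), p floored at
1e−300. Rankings from several datasets are combined with the
order-statistics Q over per-dataset rank ratios; genes missing from a dataset
get the worst ratio 1 (conservative).

## Synthetic data: what it emulates and what it does not

The generators emulate the study design at desk scale: a toy genome (default
2 chromosomes; 10 Mb each for catalog/enrichment work, 50 Mb for the linked
network study), a 9-proliferative vs 2-invasive sample panel, NB counts with
shared dispersion 0.1 (Var = μ + αμ²; gamma–Poisson sampling) around a
log-normal baseline of mean 100, planted state-specific regions with a mean
log2 fold change of 2, region sequences at GC 0.41 with one consensus-sampled
motif instance per target region at a recorded offset, and planted
region→gene links whose genes share their region's state effect.

Link geometry is deliberate: link loci are spaced farther apart (2.4 Mb) than
the 1 Mb assignment window plus the maximal gene offset (300 kb), and
unlinked differential genes sit midway between loci. In a two-state design,
any state-responsive gene within the window of a state-responsive region is
statistically indistinguishable from a true link, so without this separation
no method could attain high precision; the layout makes the planted edge set
the unique correct answer and turns edge recovery into a meaningful score.
The planted master-regulator PWM is sharper (95% consensus weight) than the
decoys (85%) so that a single sampled instance stands out against ~0.5–1 kb
of background.

What the generator does **not** model: chromatin-domain structure,
mappability or GC bias, read-level noise, row-dependent dispersion trends,
batch effects, or more than two expression states outside the explicit
confounder group. Passing tests therefore demonstrate the correctness of the
algorithms and their calibration under the stated model, not performance on
real sequencing data.

## Problem sizes and defaults used by the tests and acceptance script

Chosen as representative desk-scale versions of the study design: catalog
oracle on 50–100 random ≤100 kb genomes; enrichment on 10,000 regions × 51
PWMs with 200 planted targets in a 1,000-region foreground; differential
calibration on 2,000 regions at 9 vs 2; the linked network study with 40
planted edges; NMF on 30 samples × 800 genes (three groups); order-statistic
Monte Carlo with 10⁵–10⁶ draws. The bundled demo pipeline config widens the
recovery cutoff to 10% because 0.25% of a few-hundred-region toy catalog
would leave a one-rank window.

## Known limitations

- The NB Wald stand-in is calibrated for the simulated conditions; on real
  data with strong dispersion trends an external caller should be injected
  through the TSV interfaces.
- The binomial support filter pools samples and therefore ignores
  within-state variability; it is a support check, not an independent test.
- Best-site PWM scoring ignores homotypic clustering (CRM effects).
- GSEA's FDR uses a single gene-set null rather than the multi-set
  normalised-ES pooling of the original procedure; for one set at a time the
  two agree in distribution.
- `meta_rank` intersects nothing: it unions gene universes and penalises
  absences with ratio 1, which is conservative for sparsely measured genes.
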