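# Methods

This note documents the models implemented in `clonehist`, the choices made
where the design was genuinely open, and what the bundled simulator does and
does not emulate. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external results.

## Read counts and the admixture model

All inference rests on one generative model for a somatic substitution
observed in a biopsy of purity ρ on a segment of total tumour copy number
CNt. A mutation carried by m chromosomal copies in a fraction CCF of tumour
cells has expected variant allele fraction

    VAF = m · ρ · CCF / (ρ · CNt + 2(1 − ρ)),

the denominator being the average number of chromosome copies per cell in
the sequenced mixture (tumour plus diploid normal). Alt reads are binomial
at this VAF given the local read total. Coverage per chromosome copy,

    ρ / (ρψ + 2(1 − ρ)) · C,

with ψ the subclonality-weighted ploidy and C the mean coverage, gates the
analyses: ≥ 5 for tree building, ≥ 7 for copy-number timing.

## Variant rescue (readfilter)

Hard filters are conjunctive and carry explicit reason codes; the boundary
readings are: alignment score ≥ 140 passes, "mean ≤ 10×" pileup removal is
inclusive, and the unknown/ambiguous-read exclusion requires *strictly* more
ambiguous than variant reads. The panel error model fits a per-site mean
with pseudocounts (0.5, 0.5) — so a perfectly clean panel still has a
non-degenerate tail — and a single method-of-moments overdispersion shared
across sites; per-site overdispersion fits are unstable at panel depths.
Presence testing uses the upper-tail beta-binomial probability P[X ≥ alt]
rather than a likelihood-ratio statistic, because the decision rule in the
original analyses is a thresholded p-value (BH-adjusted, α = 0.001).
BH pooling is across sites × samples within a patient by default; a
per-sample switch exists.

One calibration note: with a 250-sample 30× panel and a true error rate of
10⁻³, a site sees ~7.5 alt reads in total, so the fitted per-site mean has
substantial Poisson scatter; about 93% of sites land within a factor of two
of the truth (the test asserts the exactly derived value, not a rounder
aspiration).

## CCF clustering and the clone tree (clonetree)

Substitutions (autosomal only) are clustered across a patient's biopsies
under a Dirichlet-process binomial mixture. A cluster is a vector of CCFs,
one per biopsy, on a uniform grid (step 0.02 up to 1.2); the
Chinese-restaurant-process Gibbs sampler resamples cluster locations and
assignments, with the concentration fixed at 1.0. Joint n-dimensional
clustering replaces the triplet-merging workaround used historically for
highly multi-sampled tumours: that scheme was a scalability device, not a
statistical requirement. Posterior partitions are summarised by the
maximum-posterior-similarity (Dahl) partition over retained sweeps, ties
broken towards fewer clusters.

Clusters under 20 substitutions or under 1% of the patient total are
removed; "small clusters violating the rest of the tree" are made concrete
as: pigeonhole residual > 0.1 *and* size < 5% of the trunk. The tree nests
each cluster under the smallest-CCF already-placed cluster that dominates it
in every biopsy (tolerance 0.05); presence is CCF > 0.1 (strict). For
patients with in-situ disease, clusters present in both the GCNIS and the
invasive compartment are folded into the trunk. The trunk proportion is

    n_trunk / (n_trunk + Σ_tips dist(trunk→tip) / n_tips),

which double-counts shared internal branches once per tip passing through
them — deliberately, so every subclonal lineage contributes a full
trunk-to-tip length.

## Gain timing and the pre-duplication burden (gaintiming)

Only 2+0, 2+1 and 2+2 segments are timed. The closed-form inversions are
t = 2n₂/(2n₂+n₁) for 2+0/2+2 and t = 3n₂/(2n₂+n₁) for 2+1 (truncated to
[0, 1]); 95% CIs come from 200 multinomial bootstrap resamples of the
(n₁, n₂) split (the exclusion rule — CI width ≥ 0.5 — is prescribed, the CI
construction was not; percentile intervals are the plainest choice).
Segments with higher states (3+2, …) and post-WGD 1+1 equivalents carry no
usable multiplicity signal and are excluded.

The (n₁, n₂) split itself is estimated, per segment, by EM on the
two-component binomial mixture with known component VAFs, not by counting
hard maximum-likelihood assignments. At 30× depth the hard rule misassigns
~5–10% of the dominant multiplicity-1 class into the rare multiplicity-2
class, inflating n₂ by 10–25%; the mixture estimate of the mixing weight is
consistent. Both components are additionally scaled by a clonal-CCF factor
shared across the sample's timeable segments and fitted by profile
likelihood on a grid (0.85–1.05, step 0.005): even "clonal" mutations sit
slightly below CCF 1 in a near-monoclonal microbiopsy, and ignoring that
shifts the decision boundary. Hard assignment remains available
(`soft=False`) and is what the CCF-correction step of the tree stage uses,
where per-mutation integer multiplicities are required.

The copy-number-adjusted burden is

    adjusted = n_pre + n_pre · (n_total[2+1, 2+0] / n_total[2+2, 2+1, 2+0]),

compensating pre-duplication mutations on the minor allele of 2+0/2+1
segments, which are invisible (lost or indistinguishable from multiplicity
1). The correction is exact when segment states are homogeneous and biased
by a few percent (≤ ~6% in the simulated mixtures tested) for mixed
configurations, because the weighting uses total rather than
state-conditional counts; the formula is kept as specified and the residual
bias is covered by the 15% recovery tolerance. Extrapolation to the genome
is by covered length (default denominator: 2,875,001,522 autosomal GRCh37
bases; the simulator's own genome length is used in tests).

WGD is declared when ψ ≥ 2.9 − 2h (h the subclonality-weighted homozygous
fraction), boundary inclusive. Burden converts to primordial-germ-cell
divisions by doubling the 0.5–0.7 substitutions per haploid genome per
division estimate: point = burden / 1.2, range = burden / 1.4 … burden / 1.0.
The burden-vs-age asymptotic regression a + b·e^(c·age) is fitted by
profiling the residual sum of squares over c (linear in a, b for fixed c) on
a log-spaced grid refined by bounded scalar minimisation — deterministic, no
starting-value sensitivity.

## Similarity tests (histosim)

Genetic similarity between two biopsies is the substitution mass of clusters
present in both (CCF > 0.1) over the mean of their present totals;
transcriptomic similarity is the Pearson correlation of log2(TPM + 1)
(pseudocount because log2(TPM) is undefined at zero; monotone, harmless)
over protein-coding genes outside the exclusion sets. The label-swap test
permutes the intra/inter labels of the *pairwise comparisons* (the stated
procedure), not the sample labels; a sample-relabelling variant would induce
different dependence and is intentionally not the default. p-values use the
add-one convention (1 + exceedances)/(n + 1) in sampled mode, with ties
counted as exceedances; when the assignment space C(n_pairs, n_intra) is no
larger than the permutation budget the space is enumerated and
p = (1 + #{alternatives ≥ observed}) / #assignments — for the four-genome,
two-histology configuration that is 15 assignments and 14 alternatives.
Note one consequence of the tie rule: a maximally separated score
configuration does *not* reach the minimal p, because many label swaps tie
the observed median difference exactly.

The chromothripsis variance test compares one tumour's intra-histology
correlation variance against variances of random same-size subsets of the
cohort pool (one-sided, large variance = heterogeneity), enumerating
exhaustively when the pool is small.

## Expression dosage (dosagexpr)

Libraries must express ≥ 1000 features at ≥ 5 reads (strictly fewer than
1000 is removed). TPM uses annotation gene lengths. The differential
expression routine is a declared stand-in for limma-voom — Welch's t on
log2(TPM + 1) with BH correction, log2FC from mean TPM with +1 damping —
because the bespoke content of this module is the permutation and rolling
machinery, not the DE engine; an adapter accepts externally computed DE
tables. With histology blocking, the fold-change is the unweighted mean of
per-histology fold-changes, so a histology with many libraries cannot
dominate the contrast. Significance cut-offs follow |log2FC| > 2 and
adjusted p < 0.01.

The rolling track is a centred 50-gene moving average ordered by start
coordinate (gene rank, not base pairs, is the support). Cytoband enrichment
is a competitive rank-sum of band genes against the rest (bands under five
genes skipped). The dosage permutation compares the mean log2FC of the
target-arm genes retained in the DE table against means of same-size gene
sets drawn without replacement (with-replacement behind a flag) from genes
on segments within ±0.5 of the sample ploidy; genes filtered from the DE
table are excluded from target and pool alike. The pool is used as given —
target genes are not removed from it — so a target drawn from the pool
itself is exactly exchangeable with the null draws and the test is
calibrated by construction. Gene-to-band and gene-to-segment assignment uses
the gene start coordinate.

## Signatures (sigfit)

Spectra use the fixed COSMIC channel order (six pyrimidine-centred
substitution blocks × 16 alphabetical contexts); purine-centred records are
reverse-complemented. Attribution is multinomial-mixture EM with uniform
initialisation (deterministic), monotone log-likelihood, convergence when
the largest exposure change falls below 10⁻⁸. Collinear catalogue pairs
(cosine ≥ 0.999) are reported: their summed exposure is identifiable, the
split is not. Per-patient spectra use unique substitutions across a
patient's biopsies to avoid double counting. The bundled catalogue is
synthetic — five vectors loosely evoking a flat clock-like process, CpG
deamination, oxidative C>A damage, a T>G-rich process and an A[C>G]G-peaked
component — so tests need no external download; real catalogues load from
TSV.

## The simulator (simcohort) and what a green test establishes

The simulator draws arm-level segments from post-WGD states (2+2, 2+1, 2+0,
3+2, 1+1 equivalents; default weights 0.40/0.25/0.15/0.10/0.10), places
truncal mutations before or after the WGD time in proportion to the copies
present (2 before, local CN after), assigns multiplicities per state
(including allele loss on 2+0, where the lost half is retained in the
ground truth but emitted with zero VAF), and samples reads from the same
admixture model the inference inverts, with Poisson totals scaled by local
copy number. Biopsies are near-monoclonal patches (major-clone CCF 0.96,
matching the cohort-level median the study design produces) with subclones
cycling through biopsies; histology labels cycle independently of the clone
assignment, so histology–clone concordance is null unless constructed.
Expression is negative-binomial (gamma–Poisson, dispersion 0.2) around
histology-program means with a multiplicative gain on the dosage arm
(default 12p × 1.8, the arm also forced to a gained copy state so its genes
fall outside the near-baseline pool). Defaults: depth 30× (the cohort's
15–48× range), purity 0.95, ~3000 truncal substitutions per tumour, 150 per
subclone, 2000 genes, 300k-read libraries.

Not emulated: read-level artefacts (the simulator provides clean count
summaries, so the hard filters are exercised on constructed summaries, not
emergent ones), alignment and mapping error, spatial geometry of subclone
patches (patches are labels, not coordinates), structural variants and
real trinucleotide context from a reference genome (channels are sampled
from the signature mix directly). A green recovery test therefore
establishes that the estimators invert the stated statistical model at
realistic depths and scales — not that they are robust to artefacts the
model excludes.

Recovery of the genome-wide pre-duplication burden is tested at WGD times
0.1/0.3/0.6 (within 15% of the planted count in ≥ 80% of 51 seeded runs,
plus a monotone early-vs-late direction check). Very early duplication
(mutation time ≤ 0.01, the postpubertal regime's actual scale) is not
recoverable to 15% at 30× with ~3000 mutations by any estimator — the
information simply is not in the data at desk scale; the direction check is
the honest statement there.

## Known limitations

- The Eq.-3-style minor-allele correction is approximate under mixed
  segment configurations (see above).
- The DP sampler's grid prior caps cluster CCFs at 1.2; heavily
  mis-specified multiplicities can push true CCFs beyond the grid.
- The DE stand-in is not limma-voom; inference on real data should swap in
  an external DE table via the adapter.
- Indel-specific rescue shares the substitution code path with different
  thresholds (panel size is a configuration knob, not a separate model).
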