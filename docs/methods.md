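# Methods

## Recombination model

A TRB rearrangement scenario is specified by a V, (D, J) pair, deletion
counts at the four junctional segment ends, and two insertion sequences.
Its probability is the product
P(V) · P(D,J) · P(delV|V) · P(insVD) · P(delDl,delDr|D) · P(insDJ) · P(delJ|J).
The CDR3 is assembled as trimmed-V + VD-insert + trimmed-D + DJ-insert +
trimmed-J, spanning the conserved V-gene cysteine codon through the
conserved J-gene phenylalanine/tryptophan codon, 5′→3′ on the coding
strand.  Model assumptions and conventions:

* **Insertions** factorize into a length distribution and a first-order
  nucleotide Markov chain (initial distribution + 4×4 transition matrix).
  The DJ insert is generated — and its probability evaluated — in reverse
  (3′→5′) orientation, the convention of the model family this implements.
* **Palindromic (P) nucleotides are not modelled**; deletion counts are
  non-negative.  This keeps the scenario space finite and exactly
  enumerable, which the whole validation strategy depends on.
* **J constrains D**: P(D,J) may contain structural zeros, and sampling at
  fixed (V, J) draws D from P(D | J) = P(D,J)/Σ_D′ P(D′,J).  A J with no
  compatible D is an error ("empty conditional").
* Deletion tables whose support exceeds the segment length, or any factor
  distribution off-normal by more than 1e-6, are rejected at load time.

Parameters are **inputs**, read from plain-text tables (one TSV per
factor, FASTA per segment class); the package does not fit them
(no expectation-maximization inference of recombination statistics).

## Pgen estimation

* `pgen_nt_exact` / `pgen_nt_table` sum scenario probabilities by full
  enumeration.  Enumeration refuses models with more than 10⁷ scenarios:
  it is an oracle for validation, not a production path.
* `pgen_aa` is the two-step Monte-Carlo estimator: for each (V, J) in the
  supplied usage distribution, `n_per_vj` rearrangements are simulated
  with V and J fixed; the match fraction (same-length translation within
  `max_mismatch` substitutions, default 1; non-coding draws count as
  non-matches) is averaged with the usage weights.  The stratified
  standard error is sqrt(Σ w² p̂(1−p̂)/n).  `n_per_vj` defaults to 10⁵ on a
  desktop; production-scale work uses orders of magnitude more.
* **VJ usage** comes from the dataset under study — the relative (V, J)
  frequencies of unique *non-functional* clonotypes — because segment
  usage is distorted by library-preparation bias while insertion/deletion
  profiles are stable across platforms.  The model's own
  P(V,J) = P(V)·P(J) is used when no dataset is given.
* **Mismatch semantics**: substitutions only, equal length, any position
  including germline-encoded flanks.  Restricting mismatches to the
  junctional region is not enforced; with a ≤ 1-substitution allowance,
  germline-flank mismatches are rare in practice.
* **Non-coding correction** divides an estimate by (1 − non-coding
  fraction), where the fraction is a Monte-Carlo estimate of
  P(out-of-frame or stop) under the model's own P(V)·P(D,J).  It is a
  single global (cohort-level) correction, exposed as a flag.
* **Determinism**: a single integer seed fully determines every draw.
  Per-(V, J) substreams are derived from (seed, CRC32(V), CRC32(J)), so
  per-stratum results are independent of evaluation order, and mismatch
  monotonicity (pgen at allowance 1 ≥ allowance 0 at the same seed) holds
  by construction.
* `convergence_probability` returns Σp_n² / (Σp_n)² over the nucleotide
  encodings of an amino-acid variant — the probability that two
  independent rearrangement events producing the variant coincide at the
  nucleotide level.  The Monte-Carlo mode uses the unbiased collision
  estimator Σc(c−1)/(M(M−1)).

## Repertoire handling and annotation

Clonotype tables follow the VDJtools column convention (count, freq,
cdr3nt, cdr3aa, v, d, j); other layouts map through a dialect dict.  The
authoritative functional test is `coding_status` on the nucleotide
sequence (out-of-frame ⇔ length not divisible by 3; stop ⇔ in-frame
TAA/TAG/TGA); amino-acid markers (`*`, `_`) are display conventions only.

Pooling collects unique (nucleotide sequence, donor) pairs keyed by CDR3
amino acid: a variant observed in k donors contributes k unique
rearrangements, because cross-donor recurrence of the same nucleotide
sequence is the signature of convergent recombination.  Counting unique
variants rather than reads makes the measure insensitive to clonal
expansion.

Specificity annotation allows at most one amino-acid substitution and no
indels, and deliberately ignores V/J calls (requiring them discards most
genuine hits; the CDR3 sequence itself pins down J and narrows V).  The
≤ 1-substitution lookup uses a length-bucketed masked-position hash (each
length-L sequence indexed under its L masks); its results are proven equal
to a brute-force Hamming scan by a property test.  Population incidence
uses coding clonotypes only; "public" means incidence ≥ 5% (inclusive),
with incidence bins <5%, 5–9%, 10–14%, 15–19%, 20%+.  HLA alleles are
normalized to gene + first field (e.g. `HLA-A*02`) and compared at that
resolution.

## Cohort statistics

* **Per-epitope summaries**: epitopes with fewer than 30 distinct specific
  CDR3 amino-acid sequences are excluded; ANOVA is computed on log10
  probabilities (here and everywhere).
* **Observed/expected HLA ratios**: for donor allele a and restriction r,
  E(a,r) = (total unique matches to r) × (fraction of donors carrying a),
  the independence construction, isolated in one function.  Donor alleles
  in < 30 samples and restrictions with < 100 database TCRs are dropped by
  default.  Matched (a = r) vs mismatched cells are compared with a
  one-sided Mann–Whitney U (enrichment direction).
* **Per-TCR enrichment**: upper-tail hypergeometric probability that a
  TCR's sample occupancy concentrates in carriers of an allele;
  Benjamini–Hochberg across all (TCR, allele) pairs, flagging adjusted
  p > 0.05.
* **Expansion ratios**: a sample is HLA-matched for a clonotype if the
  donor carries at least one allele equal (at stored resolution) to any
  restriction of its matched records.  The per-clonotype statistic is
  log2(mean read frequency over matched samples where present / mean over
  mismatched samples where present); absence is not treated as zero, and a
  clonotype needs at least one occurrence on each side — this avoids
  pseudocount artifacts at the cost of conditioning on presence, a
  deliberate interpretation since zero-frequency handling is genuinely
  open.  Distributions are compared across serostatus groups by
  two-sample Kolmogorov–Smirnov; directional counts per restriction allele
  get exact Clopper–Pearson 95% CIs, and alleles backed by fewer than 4
  clonotypes are excluded.
* **Group comparisons**: per-sample burden = unique matched coding
  rearrangements / unique coding rearrangements; two-tailed t-test for
  cord blood (UCB) vs PBMC, also restricted to class II-restricted
  records; per-epitope relative abundances use a t-test (2 groups) or
  one-way ANOVA (≥ 3 groups, e.g. ancestry) with Benjamini–Hochberg —
  the per-epitope statistic is this package's choice, as no specific test
  is canonical for that comparison.

## Epitope features and immunogenicity

Peptides are embedded as sums of the ten Kidera factors over residues
(`data/kidera.tsv`, the published standardized 20×10 table; factor 6 is
dominated by partial specific volume, factor 10 by surrounding
hydrophobicity).  Associations with log10 specific-TCR frequency use
Pearson correlation on raw sums and one-way ANOVA over four quantile bins
of the whole observed spectrum, Benjamini–Hochberg adjusted over the 11
tests (length + 10 factors) at α = 0.01.  Quantiles are labelled Q1→Q4
from smallest to largest, with a flag to flip — the opposite orientation
is equally defensible and the choice only affects labels, not p-values.

The **T-score** of an epitope against a labelled panel is a Welch
two-sample t statistic comparing its Euclidean distances to the
non-immunogenic members vs the immunogenic members, signed so positive =
closer to the immunogenic set; it is invariant under rigid motions of
feature space, and defined as 0 when the two mean distances are exactly
equal.  The variance treatment and sign convention are this package's
specification, as only the comparison itself is canonical.

The **EM classifier** is a two-component multivariate-Gaussian mixture
over Kidera-sum space: initialized from the labelled class moments,
refined by EM over pooled labelled + unlabelled data with labelled
responsibilities fixed at their one-hot labels, returning the posterior
probability of the immunogenic component for each unlabelled epitope.
The log-likelihood is asserted non-decreasing each iteration; a singular
class covariance triggers a diagonal-covariance fallback (with a notice);
covariances carry a 1e-6 ridge.  The mixture-family choice and
initialization are this package's design, isolated behind one function so
alternatives can be swapped.

The **linear model** is ordinary least squares of log10 median specific-TCR
frequency on the ten factor sums (+ intercept), requiring ≥ 12 training
epitopes and a full-rank design (rank deficiency is reported with the
collinear factor names); class separation of predictions is tested by
two-sample Kolmogorov–Smirnov.  PCA is centred, two components, with
explained-variance fractions.

## Paired chains

Marginal frequency per epitope and chain = (matching records) /
(database records for that epitope and chain) / (total paired records).
The paired-match frequency is normalized by the *product* of the
per-chain record counts, so that under independent pairing its expectation
equals the product of the marginals; the independence check reports the
Pearson correlation of the log-transformed product vs paired values over
epitopes with ≥ 30 database records per chain, dropping zero-frequency
epitopes with a notice.  Matching counts unique rearrangements (records),
consistent with the unique-variant accounting used throughout.  An α-chain
model is the same machinery with a VJ-only segment library (a single
placeholder D with point-mass zero deletions).

## Synthetic data: what it emulates, and what it does not

The generators are the package's study-design surrogate for real cohorts:

* **Toy models** (fixed A–D and seeded random ones) have point-mass or
  Dirichlet-random tables with scenario spaces small enough for exact
  enumeration, so every Monte-Carlo estimate can be checked against an
  exact value.  Random V suffixes and J prefixes are generated stop-free
  in their own reading frame, as germline CDR3 regions are.
* The **cohort model** (3 V, 2 D, 3 J; up to 4 deletions per side; 1–3
  inserted nucleotides per junction; ≈ 6.8 × 10⁶ scenarios, ≈ 3.1 × 10⁶
  distinct nucleotide products) is the largest exactly enumerable design
  here.  Its maximum nucleotide-level Pgen (≈ 8 × 10⁻⁵) keeps 10⁴-cell
  samples essentially collision-free, so unique-variant frequencies
  estimate Pgen without saturation bias.
* **Cohorts** draw each donor's cells i.i.d. from the model; genotypes are
  two alleles per locus from stated population frequencies; serostatus is
  independent Bernoulli.  Read counts are negative-binomial around the
  per-clonotype mean (dispersion 2, ~10 reads/cell) so frequency ratios
  show realistic overdispersion.  Planted effects: a read-count
  multiplier for database-matching clonotypes in seropositive
  HLA-matched donors (clonal expansion); spiked unique matching variants
  scaling a group's match burden (cord-blood-style excess) or an
  allele-conditioned match excess (positive-selection signal).  Truth
  records store every assignment.
* **Databases** sample model-generated CDR3s into epitopes by exact-Pgen
  strata (defaults: per-epitope quantile bins of the model's spectrum);
  **panels** label random 9-mers by a threshold on the factor-10 sum with
  a 1-SD separation gap between classes — the labelled panels this
  emulates are separated sets in feature space, not a continuum split in
  half — plus optional label noise.

What the synthetic data does **not** emulate: sequencing error profiles
and UMI structure (assumed handled upstream), linkage disequilibrium
between HLA loci, real germline segment sequences, and — most importantly
— the size of the real amino-acid sequence space.  The toy space is so
small (≈ 7.5 × 10⁴ coding variants) that the one-substitution neighborhood
of any variant carries far more probability than the variant itself.  Two
validation designs therefore deviate from the production defaults, for
reasons that are scale artifacts rather than modelling choices: the
cohort recovery study tracks variants by *exact* amino-acid match, and the
expansion study uses a small (45-TCR) specificity set so expanded
clonotypes remain a negligible read share, as pathogen-specific clonotypes
are in real repertoires.  Passing these tests shows the estimators and
statistics are correctly calibrated, not that a 9-mer toy space behaves
like the human TCRβ repertoire.

## Validation experiment sizes

All in `tcrpreimmune.validation`, seeded and deterministic:

* Oracle agreement: 5 random toy models × 4 target CDR3s × 10 Monte-Carlo
  seeds at n_per_vj = 4000, compared within 3 exact standard errors.
* Hypergeometric check: every (S ≤ 12, K, m, x) instance against
  exhaustive subset enumeration (1639 instances); null FDR on 10⁴
  (TCR, allele) pairs with presence independent of genotype.
* Cohort recovery: 100 donors × 10⁴ cells, 30 epitopes × 50 TCRs with
  strata log-spaced over 5 × 10⁻⁷ … 5 × 10⁻⁵ — centred on the Pgen where
  5%-incidence is crossed at this sampling depth, so public fractions
  span 0…1 across epitopes.
* Expansion: effect 4×, 100 donors × 5000 cells, 45 CMV-specific TCRs.
* Burden: effect 1.3×, 20 + 20 donors × 1000 cells (burden CV ≈ 10%),
  100 replicates for power at p < 0.01 and 500 null replicates for the
  type-I error at α = 0.05.
* Immunogenicity: 100 epitopes per class, zero label noise for the EM
  accuracy; a +1 log10 frequency shift planted through factor 10 for the
  KS separation; noise-free linear fits for coefficient recovery.

These sizes run the whole battery in minutes on one CPU while leaving the
statistical margins comfortable (e.g. the recovery Spearman is ≈ 0.98
against a ≥ 0.9 requirement).

## Known limitations

* No palindromic nucleotides and no per-allele deletion profiles beyond
  the tables supplied; real published TRB parameter sets load through the
  same interfaces but are not bundled.
* The non-coding correction is global; a per-(V, J) correction would be
  straightforward but is not what cohort-level estimates need.
* Whether the non-coding fraction should be computed under the model's own
  segment usage or a dataset-reweighted usage is unstated in the source
  material; the model's own usage is the default here.
* The EM classifier assumes Gaussian class-conditional densities in
  Kidera-sum space; heavy-tailed or multi-modal classes would need a
  different mixture family (the interface accepts a drop-in replacement).
* Incidence is computed over coding clonotypes only; if non-functional
  matches were of interest they would need a separate accounting.
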