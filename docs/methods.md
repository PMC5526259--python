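# Methods

## Model and assumptions

A locus is a set of *d* ordered CpG sites covered by *N* reads; each
read is a binary methylation vector with an observed-entry mask. The
generative assumption is a finite mixture of *Q* latent binary patterns
(epialleles): a read copies its generator pattern and each observed CpG
call is flipped independently with probability ε. The single ε per
locus absorbs bisulfite-conversion failure, PCR and sequencing error; it
is shared across sites and patterns, which is adequate when error rates
are small and roughly homogeneous, and is restricted to [0, ½] so that
patterns remain identifiable. Missing entries are ignored everywhere —
they contribute to no product, sum or distance. Priors over the pattern
matrix and the attribution vector are uniform, so MAP estimation
coincides with maximum likelihood.

The per-read attribution wᵢ, the patterns X, and ε all have closed-form
conditional MAP updates: nearest pattern by observed mismatch count,
per-site majority vote among attributed reads, and the global mismatch
fraction α₀/(α₀+α₁). The updates are alternated to convergence of w
(typically two or three iterations; hard cap `max_iterations = 20`),
which is coordinate ascent on the joint likelihood and therefore
monotone — a property asserted by the test suite on every fixture.

## Model selection

The number of epialleles is chosen by minimising

    AIC(Q) = −2 log p(Y, ŵ | X̂, ε̂, Q) + 2Qd,

where the log-likelihood is the joint density of the reads *and their
attributions* under the uniform attribution prior:
log p(Y, ŵ | ·) = Σᵢ log p(yᵢ | x_ŵᵢ, ε̂) − N log Q. The −N log Q term
is essential and deliberate. With the conditional (classification)
likelihood alone, a saturated model that gives every distinct observed
read pattern its own epiallele reaches ε̂ → 0 and log-likelihood → 0, so
its AIC of 2Qd beats any parsimonious fit whenever N is large enough
relative to 2^d for corrupted reads to collide — at d = 6, N = 100,
ε = 0.05 this selects a dozen spurious epialleles at a three-epiallele
locus and halves the attribution success rate. Charging each of the N
attribution variables its log Q description length removes the
pathology: at the same settings the selector recovers Q = 3, returns
Q = 1 on noise-only loci, and reproduces the ~95% benchmark success
rate. At Q = 1 the term vanishes, so single-epiallele AIC values equal
the plain closed form.

Ties in every update are resolved deterministically: argmax ties in
attribution go to the lowest pattern index, exact majority ties (and
empty vote sets) give an unmethylated call, AIC ties prefer smaller Q.
An epiallele left with no attributed reads keeps its previous pattern
and is rescued by reassigning the read with the lowest best-emission
log-likelihood (never emptying another singleton cluster), after which
patterns are recomputed; the rescue is itself monotone in likelihood.
`epsilon_floor = 1e−6` replaces ε̂ = 0 inside logarithms so perfect-fit
loci have finite likelihoods and defined responsibilities. The AIC
search runs Q = 1..min(q_max, N, 2^d) with `q_max = 20` by default;
real loci rarely support more than ~13 epialleles.

## Initialisation

w is initialised by cutting a hierarchical-clustering dendrogram of the
reads into Q groups. The pairwise distance is the masked Hamming
proportion — the fraction of mutually observed CpGs that differ — with
pairs sharing no observed site assigned the uninformative value 0.5.
The linkage is Ward on the square root of these distances: for binary
vectors the squared Euclidean distance equals the Hamming count, so
this is exactly Ward clustering of the read vectors (approximately so
under missingness). The choice matters: average linkage merges true
pattern pairs at Hamming distance 1 into one cluster and the coordinate
ascent cannot subsequently split them, costing roughly seven points of
benchmark success; Ward's variance criterion separates such pairs
reliably (recovering the global optimum on all hard fixtures where
average linkage found it in three of eight). The dendrogram is computed
once per locus and re-cut for every Q in the AIC search.

## Locus assembly and eligibility

Reads on one chromosome sharing CpG coordinates (transitively) form one
locus whose CpG set is the union of member positions; reads are expanded
to the union with missing masks, so partially overlapping reads are
handled by the missing-data machinery rather than discarded. External
coordinates are 1-based inclusive, and round-trip through the TSV
dialect exactly.

Eligibility defaults mirror the validated operating point of the model:
at least 6 CpGs, median per-sample depth ≥ 100 (depth is the locus read
count N_s; cohort samples absent from a locus count as depth 0), at most
25% missing entries, sex chromosomes excluded. To meet the missingness
bound, reads observing fewer than (1 − 0.25)·d of the locus's positions
are dropped one at a time (lowest coverage first) with the CpG union
recomputed after each removal, until the bound holds or the locus is
exhausted. This trimming rule is a documented package choice: it
reproduces the intent of bounding per-locus missingness without
prescribing a specific read layout.

## Profiles, pruning, purity and decontamination

Responsibilities are the leave-one-out marginal posterior of each wᵢ
with everything else at MAP — the softmax of per-pattern emission
log-likelihoods. Per-sample distributions φ^s average responsibility
columns over the sample's reads, so Σ_s N_s φ^s / N equals the pooled
distribution exactly. Epialleles under 5% pooled frequency are
discarded and the survivors renormalised; the threshold is applied to
the pooled (all-sample) frequency so every sample keeps the same
epiallele basis, which the purity algebra requires. Renormalisation
after pruning (and after clipping in decontamination) is asserted
because every downstream quantity — ξ, Euclidean distances, entropy —
treats φ as a probability distribution.

Purity: ξ is computed at every locus where both the tumour sample and
the normal have a profile, the normal profile standing in for **n**. A
Gaussian KDE (Silverman bandwidth) of the ξ values is evaluated on a
512-point grid over [0,1], padded with zeros so boundary modes are
detectable, and ρ̂ is the rightmost local maximum with prominence at
least 5% of the density maximum. Estimates under the detection floor of
0.20 are reported as "<20%" rather than as a numeric purity; at least
200 loci are required by default. A degenerate all-equal ξ sample is
treated as an atom at that value. On simulated mixtures with known ρ
(2,000 loci, 100 reads per sample per locus), ρ̂ lands within ±0.05 of
truth at ρ ∈ {0.25, 0.5, 0.75}; below-detection samples keep their
floor value of ρ for decontamination, a conservative under-correction.

## Entropy and the tree

Per-locus disorder is the Shannon entropy of φ in bits divided by d, so
loci of different sizes are comparable; it can be computed on observed
or decontaminated profiles (both are written by the pipeline). The tree
is built from decontaminated tumour profiles t̂_s plus the normal
sample's own profile: each locus yields a pairwise Euclidean distance
matrix, matrices are averaged entrywise over the loci where both
members of a pair are profiled (a pair sharing no locus is an error),
and the overall matrix is resolved by balanced minimum evolution with
balanced NNI refinement (scikit-bio's `bme`/`nni`, the FastME
approach), with neighbor joining as an alternative; negative branch
lengths are clamped to zero. Both methods reproduce an additive
distance matrix's path lengths to 1e−9.

## Synthetic data

The generator emits data with the model's exact generative structure:
Q distinct patterns drawn uniformly (duplicates rejected, so the
benchmark measures recovery of genuinely distinct epialleles while
still exercising small Hamming separations), multinomial generator
assignment, independent per-CpG flips, independent masking. The cohort
generator adds the contamination structure — the normal tissue
concentrated on one epiallele per locus, the tumour a Dirichlet draw
over the remaining patterns at an altered fraction (default 0.5) of
loci, tumour reads drawn from ρt + (1−ρ)n — which makes altered loci
disjoint in tumour/normal support so the ξ density peaks at ρ. A
cell-line preset mixes all-methylated and all-unmethylated populations
9:1. Seeding is counter-based (one global seed streams per-locus
seeds), so any locus is independently reproducible and identical
scenarios are bit-identical.

What the generator does not emulate: read-length and fragment
geometry, PCR duplicates, coverage heterogeneity, strand effects,
sequence-dependent conversion efficiency, copy-number alterations, and
spatial correlation of methylation along the genome. Passing the
synthetic benchmarks therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness
to every artefact of real libraries.

Benchmark scales: attribution success is averaged over 100 simulated
loci per design point (the scale at which the ~95% reference figure is
quoted); property suites use 200 fixtures for likelihood monotonicity,
200 tiny instances (N ≤ 8, d ≤ 4, Q ≤ 2) for brute-force parity with a
<5% heuristic-shortfall allowance, and 2,000 loci per purity recovery
point. These sizes keep the whole suite in the minutes range on one
core while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

Inference is MAP plus one-coordinate marginalisation, not a full
posterior; uncertainty in X and ε is not propagated. The attribution
prior term in the AIC is a package design choice (see above) rather
than textbook AIC. Purity estimation assumes enough loci with
tumour-specific epialleles to populate the ξ ≈ ρ mode; cohorts where
tumour and normal share most epialleles everywhere will bias ρ̂
downward. The locus trimming rule is one reasonable realisation of the
missing-data bound. Tree branch supports (bootstrap) are out of scope.
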