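# epiallele

Bayesian detection of **epialleles** — the binary DNA-methylation
patterns observed along individual bisulfite sequencing reads — with
downstream estimation of tumour sample purity, decontamination of
tumour epiallele profiles, quantification of epigenetic entropy, and
distance-based phylogenetic reconstruction across multiple regions of
the same tumour.

The package is aimed at cancer epigenomics groups working with
RRBS-style data from multi-region tumour sampling (several tumour
biopsies plus a matched normal), but the epiallele model applies to any
per-read CpG methylation calls.

## The model

At a genomic locus with *d* CpG sites, each of *N* sequencing reads
**y**ᵢ ∈ {0,1}ᵈ (with missing entries masked) is assumed to be a
noise-corrupted copy of one of *Q* latent epiallele patterns
**x**_q ∈ {0,1}ᵈ. Conditional on its generator wᵢ = q, every observed
CpG call disagrees with the pattern independently with probability
ε ∈ [0, ½], which absorbs bisulfite-conversion failures, PCR and
sequencing errors:

    p(yᵢ | x_q, ε) = ∏_μ ε^[yᵢμ ≠ x_qμ] (1 − ε)^[yᵢμ = x_qμ]

Under uniform priors the MAP updates alternate nearest-pattern
attribution (wᵢ* = argmax_q p(yᵢ|x_q, ε)) with per-site majority votes
for the patterns, from a Ward hierarchical-clustering start; ε̂ is the
overall mismatch fraction α₀/(α₀+α₁). The number of epialleles is
selected by minimising

    AIC(Q) = −2 log p(Y, ŵ | X̂, ε̂, Q) + 2Qd

over Q, counting the Qd pattern bits as free parameters. Attribution
uncertainty is retained through responsibilities p(wᵢ = q | ·) and the
per-sample epiallele distribution is their average over the sample's
reads: φ^s_q = (1/N_s) Σ_{i∈I_s} p(wᵢ = q | ·). Reads from all samples
are pooled per locus before fitting, so every sample shares one
epiallele basis.

A tumour sample contaminated with normal tissue observes the convex
mixture φ = ρ**t** + (1−ρ)**n**, where ρ is the purity. The statistic
ξ = ½ Σ_q |φ_q − n_q| is bounded above by ρ, with equality at loci where
tumour and normal share no epialleles, so ρ is estimated as the
rightmost maximum of the kernel density of ξ across loci.
Decontaminated tumour profiles t̂_q = (φ_q − (1−ρ)n_q)/ρ (clipped to
[0,1]) feed locus-wise Euclidean distance matrices, averaged across loci
and resolved into an unrooted tree by balanced minimum evolution (the
FastME approach) or neighbor joining. Per-locus epigenetic disorder is
the normalised Shannon entropy −(1/d) Σ_q φ_q log₂ φ_q.

## Worked example

A synthetic four-sample cohort (matched normal `N` plus three tumour
regions with purities 0.55, 0.75 and 0.30) runs through the full
pipeline in a few seconds:

```sh
printf 'min_median_depth: 50\nmin_loci_for_purity: 100\n' > config.yaml
epiallele simulate --seed 11 --n-loci 300 --n-reads 80 \
    --rho R1=0.55 --rho R2=0.75 --rho R3=0.3 --out-dir sim
epiallele detect sim/reads.tsv   --seed 11 --config config.yaml --out-dir det
epiallele purity det/profiles.tsv --normal-sample N \
                                 --seed 11 --config config.yaml --out-dir pur
epiallele tree pur/decontaminated.tsv --seed 11 --config config.yaml --out-dir tree
```

which prints

```
INFO processed 300 loci: 49% Q=1, 22% Q=2, 29% Q=3
INFO sample R1: purity 49.5% over 300 loci
INFO sample R2: purity 69.5% over 300 loci
INFO sample R3: purity 27.8% over 300 loci
INFO tree over 4 samples written to tree/tree.nwk
```

About half the loci carry a single epiallele (the cohort generator
leaves half of loci epigenetically unaltered), and the purity estimates
track the simulated values to within a few points at this modest locus
count and read depth. The inferred tree places the normal sample on a
long branch away from the three tumour regions:

```
((R1:0.0238,R2:0.0241):0.0260,R3:0.0236,N:0.5791);
```

`det/profiles.tsv` holds the per-sample epiallele distributions, one row
per retained epiallele per locus:

```
locus_id    epiallele_id  pattern  N       R1      R2      R3
chr1:1-51   0             010001   0.9904  0.4857  0.2655  0.7726
chr1:1-51   1             000111   0.0096  0.5143  0.7345  0.2274
```

At this locus the normal tissue is essentially pure `010001` while the
tumour regions carry the `000111` epiallele in proportion to their
purity — the signal that the ξ statistic turns into the purity
estimates above.

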