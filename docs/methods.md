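# Methods

## The inference problem

A recently recombination-arrested ZW pair shows no coverage differentiation:
the W still aligns to the Z/autosomal reference, so female and male read
depth are equal genome-wide. The first detectable signals are instead

1. elevated *female* SNP density in the sex-determination (SD) region —
   fixed Z–W differences appear as heterozygous sites in every female;
2. reduced *male* diversity there — the Z has a smaller effective population
   size than autosomes;
3. short W-limited insertions — scaffolds with coverage only in females;
4. regulatory signals — sex-biased expression of SD genes and, if the W were
   decaying transcriptionally, elevated allele-specific expression (ASE) in
   females.

`zwscan` implements the full chain from per-site nucleotide profiles to
these four readouts, plus a generative model of all of them with recorded
ground truth.

## Generative model (`simdata`)

The genome is `n_chromosomes` (default 19, the willow/poplar karyotype) ×
`scaffolds_per_chromosome` scaffolds of `scaffold_length` bp tiling each
chromosome without gaps, mirroring a fragmented short-read assembly anchored
to a related reference. Each scaffold carries `genes_per_scaffold`
single-CDS genes (default 300 bp, built from sense codons so reading frames
contain no internal stops; alternating strands).

Haplotypes follow an infinite-sites model against a shared reference:

* autosomes (and the pseudoautosomal remainder of the SD chromosome): each
  individual is heterozygous per site with probability `theta_auto`
  (default 0.01);
* SD region, females: a Z/W divergence event with probability `d_zw`
  (default 0.01) **or** Z-level polymorphism with probability `theta_auto`,
  so the female heterozygosity is their union, ≈ `d_zw + theta_auto(1−d_zw)`;
* SD region, males: heterozygous with probability
  `theta_auto × z_diversity_factor` (default 0.75, the expected drop in Z
  effective population size for a ZW system at equal sex ratios);
* `n_w_scaffolds` extra scaffolds exist hemizygously in females only and are
  written as a separate "female assembly".

Each individual's haplotype pair is drawn independently; shared polymorphism
across individuals (a site frequency spectrum) is *not* modeled. This is
adequate for every statistic computed here — all are per-individual rates or
between-allele contrasts — but means the generator cannot be used to study,
e.g., linkage disequilibrium or allele-frequency-based association.

Sequencing: per haplotype, per site, depth ~ Poisson(`depth_mean`/2)
(Poisson thinning of a total `depth_mean`, default 30×, split evenly between
alleles); each read is miscalled uniformly to one of the three other bases
with probability `error_rate` (default 0.002). Multi-allelic profiles
therefore arise only through error, matching the biallelic SNP-calling rule.

Expression: log₂ FPKM of gene *g* in sample *s* is
`mu_g + eps_{g,s}` with `mu_g ~ N(fpkm_log_mean, fpkm_log_sd)` and
`eps ~ N(0, fpkm_log_sd)` (defaults 4.3 and 0.25). The log-scale parameters
are deliberately defined on **log₂** — the scale on which fold changes and
the downstream test operate. Planted male-biased genes (fraction
`frac_masculinized` of SD genes) have male *catkin* FPKM multiplied by
`bias_fold` (default 4). RNA read depth at a heterozygous CDS site is
`round(FPKM × rna_depth_scale)` (scale default 10, giving ≥ 10× for
FPKM ≥ 1 genes so the ASE coverage filter engages); allele counts are
binomial with probability `w_expression_ratio` for the W allele at Z/W
divergent sites in females (0.5 = balanced, the null) and 0.5 elsewhere.

Randomness is organized as one `numpy` Generator per (purpose, individual),
each seeded by `[seed, purpose, index]`, so adding individuals or running
only part of the pipeline never perturbs other draws, and identical configs
give byte-identical outputs.

## Pipeline statistics

**SNP calling.** A site is a SNP iff total depth ≥ 10 and the second most
frequent base is ≥ 30 % of depth (inclusive); the top two bases are
recorded. 50/50 ties take the alphabetically first base as major — the
frequency is unaffected, the output deterministic. Per-scaffold SNP density
is SNPs / eligible (≥ 10×) sites; scaffolds with no eligible site carry no
density. Mean scaffold coverage averages covered sites only and is
normalized by the individual's median scaffold coverage.

**Anchoring.** A scaffold is assigned to the chromosome on which ≥ 70 % of
its transcripts' best hits agree (best = lowest e-value, then highest
bitscore; an exact tie discards the scaffold). Its position is the median
position of the agreeing transcripts — the median is robust to a minority of
discordant hits and the choice only shifts a scaffold within its local
window.

**Scan machinery.** Tracks are log₂ of female over male sex-mean values
(pseudocount 0 by default; zero denominators are dropped with a warning —
this matches ratio tracks where absent units are simply not plotted). The
moving average (window 25 units) is centered and truncated at chromosome
ends, never spanning chromosomes; centering keeps the smoother unbiased near
boundaries. The 95 % band is the 2.5/97.5 percentile of 1,000 means of
random 25-unit sets drawn (without replacement within a set) from autosomal
units only — the whole candidate sex chromosome is excluded so the
background cannot be contaminated by linked signal. The permutation test
compares the SD-region mean against means of 1,000 equally sized random
autosomal subsets, with the +1 correction, so p ≥ 1/1001 and never 0.
Detection reports maximal runs of consecutive units whose moving average
exceeds the band's upper bound.

**π_s.** Synonymous sites are counted per codon by NG86: 1/3 per
amino-acid-preserving single-base change, mutations to stops counted
nonsynonymous (so S_c + N_c = 3 for every sense codon). Per individual, a
CDS site contributes to S when its coverage is ≥ 10×; an allelic difference
contributes to Sd when the SNP passes the triallelic filter (third allele
≤ 10 % of depth) and the minor-allele substitution is synonymous in the
reference codon (strand-aware). Codons holding ≥ 2 heterozygous sites are
skipped entirely — the data are unphased, so the mutational pathway is
undefined — and their sites are removed from S as well, keeping the ratio a
rate over a consistent codon set (the skipped count is logged; at
θ ≈ 0.01–0.02 it is a ≤ 10⁻³ fraction). Within a sex, individuals are pooled
by averaging their Sd/S ratios; 95 % CIs bootstrap over genes (1,000
replicates). No correction is applied for between-sex differences in sample
heterozygosity; with unequal real samples this can bias the Z–W divergence
estimate, which is why the SD-minus-autosome *difference* within females is
the primary estimator of divergence.

**Ka/Ks.** NG86 with pathway averaging (multi-hit codons average the
synonymous/nonsynonymous split over all mutational orders avoiding stop
codons; if every order passes through a stop, all orders are used with stop
steps counted nonsynonymous) and Jukes–Cantor correction
K = −(3/4)·ln(1 − 4p/3), undefined (flagged) at p ≥ 3/4. This counting
estimator is deterministic and fully checkable against enumeration oracles;
it is not a maximum-likelihood codon model, so absolute Ka/Ks values differ
from ML estimates on real data (typically slightly lower Ks at high
divergence). Ortholog filters: alignment > 100 bp, S·Ks ≥ 1 (S = the
alignment's synonymous site count), Ks ≤ 2. The Fast-Z comparison is a
Welch t-test of Ka/Ks between SD and autosomal genes.

**Sex-biased expression.** Genes pass per-tissue filtering when
FPKM > 1 in ≥ 50 % of individuals. Differential expression is a Welch t-test
on log₂(FPKM+1) with BH correction within tissue — a deliberate, simple
stand-in for an assembly-coupled DE pipeline; the downstream definitions
(q < 0.05 and |log₂FC| > 1, fold change on sex means with pseudocount 1) are
what the package commits to. Heatmap ordering is agglomerative clustering on
Euclidean distances with average (UPGMA) linkage; columns are pre-sorted by
label so distance ties resolve deterministically.

**ASE.** Per SNP, the RNA major-allele frequency uses the two DNA-called
alleles only (third-base RNA reads are treated as sequencing error), and
requires ≥ 10 reads on those two alleles. A gene's ASE is the median over
its SNPs; a gene observed monoallelically (ASE exactly 1.0 in count space)
is flagged and removed — such genes overwhelmingly reflect collapsed
paralogs, and their scaffolds are also excluded from the SNP-density scan.
The SD-vs-autosome comparison is a two-sided Mann–Whitney U per individual
and tissue (exact for small tie-free samples, tie-corrected normal
approximation otherwise), Bonferroni-adjusted by the number of tests
actually performed.

**W scaffolds.** On the female-derived assembly, a scaffold is a *supported*
candidate when every male's mean coverage is ≤ `male_max_cov` (default 0,
strictly female-limited) and every female reaches `female_min_cov`
(default 1×); male-free scaffolds with support in only some females fall in
a *weak* tier. **k-mers** are counted canonically (strand-collapsed,
2-bit-packed for k ≤ 31); peak fractions exclude multiplicity-1 k-mers by
default since those are dominated by sequencing error.

## Scales used by the test suite and acceptance script

The DNA-side simulations run at 19 chromosomes × 40 scaffolds × 5 kb with
two individuals per sex at 30× — large enough that the window-25 scan, the
band, and π_s CIs behave as designed. The RNA-side power analyses use a
gene-dense scaled genome (3 chromosomes × 5 scaffolds × 12 genes; the SD
region spans one chromosome, 60 of 180 genes) so that the planted-bias gene
set is large enough for stable sensitivity estimates with n = 3 per sex and
the BH multiplicity burden is commensurate with the planted signal. These
sizes are the package's chosen test conditions, stated here so results can
be reproduced exactly.

A caveat on band coverage at desk scale: the bootstrap band brackets means
of independent 25-unit sets, but a *smoothed track* is a sequence of heavily
overlapping windows, and the SD chromosome's own mean drifts relative to a
band centered on the finite background sample. Marginal coverage of a single
window is ≈ 95 %, but the per-run fraction of windows inside the band is
broadly distributed (measured mean ≈ 0.82, range ≈ 0.4–1.0 for an unbiased
track at the RNA scale above). The tests therefore assert *shifts* (planted
−2 catkin departure vs a leaf track centered at 0) rather than band-coverage
fractions where the latter are uncalibrated.

## Numerical and degenerate-input choices

* Thresholds on count ratios (the 30 % MAF rule) are evaluated as floating
  ratios of small integers; ties at exactly 30 % are inclusive per the rule,
  and the caller agrees exactly with a rational-arithmetic oracle.
* Bootstrap and permutation draws use explicit `numpy` Generators; every
  public sampler takes an `rng` argument and is reproducible under a fixed
  seed.
* Empty regions, backgrounds smaller than a set, zero median coverage, < 2
  replicates per sex, and stop codons passed to site counting all raise
  errors rather than degrade silently; SNPs outside CDSs, scaffolds without
  eligible sites, and genes without eligible ASE SNPs are silently (but
  countedly) excluded, matching how such units simply drop out of the
  corresponding analyses.

## Known limitations

* The generator has no recombination/coalescent structure, no indels, no
  paired-end artifacts, and no mapping bias; read-level effects (reference
  bias in ASE, mismapping into W scaffolds) are out of its scope, so the
  zero-false-positive W recovery here is easier than on real data.
* NG86 counting is not an ML codon model; Fast-Z group means are comparable
  within this package but not numerically to codeml-based analyses.
* The DE stand-in (Welch + BH on log₂ FPKM) ignores count-level dispersion
  modeling; with three replicates per sex its power profile differs from
  negative-binomial DE tools.
* FPKM is consumed as given; no cross-sample renormalization is attempted.
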