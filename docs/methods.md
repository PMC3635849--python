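# Methods

This note documents the models, conventions and design choices behind
ventpop, in the order data flows through the pipeline.

## MLSA typing

Allele equality is exact string identity over the full fragment — a single
mismatch (including a different ambiguity code) creates a new allele, the
standard MLST convention. Allele and ST numbers are assigned contiguously
from 1 by order of first appearance in the input strain order, so labels
depend on input order but the partition of strains into alleles/STs never
does; comparisons against published tables are therefore made on the
partition (the published ST column has gaps in its numbering, which is a
labelling artifact, not data). The default locus order for profiles and
concatenation is *atpA, dnaK, gyrB, metG, napA, tkt* (alphabetical,
matching the published table's column order); it is configurable. A strain
missing from any locus is an error: the scheme types every strain at every
locus.

## Per-locus statistics

* **Identity.** Percent identity per pair = matches / compared sites with
  pairwise deletion (gaps and IUPAC ambiguity codes count as missing
  everywhere in the package). Amino-acid identity translates in frame 1
  with the bacterial code. Means and SDs (ddof = 1) are over all
  n(n−1)/2 pairs.
* **θ̂ and Tajima's D.** η counts (states − 1) per polymorphic column; S
  counts polymorphic columns. θ̂<sub>W</sub> = basis/(a₁ L) per site with
  a₁ = Σ<sub>i<n</sub> 1/i. Tajima's D uses the 1989 variance with the
  chosen basis count substituted for S throughout; the η basis is the
  default (matching the "total number of mutations" variant offered by the
  common desktop tool), the S basis is kept as an option and both are
  reported. A monomorphic alignment raises an "undefined" error rather
  than returning a number.
* **Ka/Ks (Li/PBL).** Codon positions are classed 0-, 2- or 4-fold
  degenerate (3-fold sites count as 2-fold, the usual Li convention);
  stop codons and codons containing missing bases are excluded pairwise.
  When the two sequences of a pair disagree on a site's class, the site —
  and any substitution at it — contributes ½ to each class. Transitions
  and transversions per class get Kimura-2P corrections
  A<sub>i</sub>, B<sub>i</sub> and are combined à la Pamilo–Bianchi–Li:
  Ks = (L₂A₂+L₄A₄)/(L₂+L₄)+B₄, Ka = A₀+(L₀B₀+L₂B₂)/(L₀+L₂). Multi-hit
  codons are counted site-by-site (no pathway enumeration); the
  brute-force oracle in the test suite pins these conventions. Locus-level
  values slide a 90 nt window in 18 nt steps (trailing partial window
  dropped); windows with Ks = 0 or a saturated correction are skipped, and
  pairs with no usable window (identical sequences) are excluded and
  counted.
* **Z-test.** dN and dS are overall averages of pairwise PBL estimates;
  the SE of (dS − dN) is the standard deviation over bootstrap resamples
  of codon columns (default 1000); p is the one-tailed normal upper tail.
  Alignments with fewer than 10 codon columns are refused.
* **PHI.** Parsimony-informative sites are columns with ≥ 2 states each
  carried by ≥ 2 sequences. The refined incompatibility score of a site
  pair is the number of independent cycles (E − V + C) of the bipartite
  state-intersection graph, i.e. the extra mutations forced by the pair;
  Phi is its mean over pairs within 100 nt, and p is the fraction of
  site-order permutations with a mean at most the observed (+1 smoothing
  on both counts). Under clonal evolution incompatibility is independent
  of distance (p large); recombination leaves nearby pairs more compatible
  than shuffled ones (p small).

## Trees

Distances are p or JC69 (−¾ ln(1 − 4p/3); p ≥ 0.75 raises a saturation
error naming the pairs). Neighbor joining uses the Q-criterion with two
determinism rules: Q-ties are broken toward the lexicographically smallest
pair of representative leaf labels, and a negative intermediate branch
length is clamped to 0 with the deficit moved to the sister edge (their
sum is preserved, so additive inputs are still recovered exactly).
Bootstrap support resamples alignment columns and counts bipartition
recovery over (default) 100 replicates. k-group partitions of a tree cut
the k−1 longest internal edges. NJ replaces the likelihood trees of the
original workflow deliberately: the biogeographic claim is topology-level
(two clades by region) and NJ recovers it; ML optimization is out of
scope, and every output records this deviation.

## Differentiation and distance decay

F<sub>ST</sub> is Hudson's π-based estimator
(π<sub>b</sub> − π<sub>w</sub>)/π<sub>b</sub> with π<sub>w</sub> the
unweighted mean of the two within-population means — fully specified,
and able to go slightly negative like published site-pair values.
Significance is a label-permutation test (1000 permutations, observed
configuration included in both counts); the upstream description of
"randomized bootstrap resamplings" is read as this standard device.
Mantel tests correlate upper triangles and permute the second matrix's
row/column order; p is two-sided. Matrices are strain-level, with
geographic distance 0 for co-located strains (haversine, R = 6371.0088 km,
WGS84 coordinates taken as spherical). How pH and temperature were
combined into a single environmental Mantel test upstream is not
specified, so the package emits per-variable tests plus an optional
|Δz|-summed combined matrix, all labelled as such. End-member fluid
compositions come from OLS of species concentration on Mg, reported as
the intercept at Mg = 0 with its SE.

## MALDI fingerprints

Replicate spots merge by 1-D single-linkage grouping within 5 Da
(unweighted mean m/z and intensity; single-replicate peaks are kept but
flagged via a support count) — the matching tolerance across spots is this
package's decision, as is operationalizing "around 2000 m/z" as
m/z ≤ 2100 for the noise cut; both are configurable and logged. The top 15
peaks by intensity (ties toward lower m/z) form the fingerprint with
relative intensities scaled to max = 1. Cross-strain bins form by 1-D
single linkage with gap ≤ 14 Da — deterministic and order-free; a bin
whose span exceeds 28 Da is flagged as chained. Clustering is Ward's
minimum-variance method on the binary presence/absence rows (scipy's
implementation; heights are scipy's Ward criterion and are monotone), and
partitions come from `fcluster` cuts. Genotype–phenotype concordance is
the adjusted Rand index between the tree's 2-cut and the dendrogram's
2-cut.

## Synthetic data generator

The generator reproduces the study design, not any particular dataset:
two regions (5 + 31 strains over 2 + 4 sites), six codon-aligned loci of
810/669/495/882/555/843 nt, deep between-region divergence
(`d_between = 0.05` substitutions/site) over shallow within-region
diversity (`d_within = 0.005`), purifying selection
(`omega_sim = 0.05`, the acceptance probability of a nonsynonymous
proposal — chosen to land locus Ka/Ks well below 1, the regime the loci
were selected for), and modest within-region homologous recombination
(`rho = 0.1` per strain and locus, as recombination was detected in the
real collection).

Mechanics: each region carries **one** Kingman coalescent genealogy
(msprime, haploid, Ne = 1) shared by all loci — a clonal genome — so that
with `rho = 0` the concatenated alignment is tree-compatible and PHI stays
non-significant, while locus replacement (`rho > 0`) discords locus trees
and PHI detects it. Mutations are proposed uniformly over sites with
transition:transversion 2:1, no indels; proposals creating stops are
always rejected and nonsynonymous ones accepted with probability
`omega_sim`. Attempt counts are Poisson with rates divided by the root
sequence's expected acceptance probability, so `d_within` and `d_between`
describe *realized* distances: the expected pairwise within-region
p-distance is ≈ `d_within` and between-region ≈ `d_between` (+
within-region noise). Neutral single-population runs give Tajima's D
centred near 0, as a neutral generator must.

Site coordinates are placeholders (the real ones are unpublished): the two
regions sit ~2300 km apart, intra-region sites within ~50 km. Within a
region, geography does not influence the genealogy — the generator makes
no within-region isolation-by-distance, so Mantel/decay signals come
entirely from the between-region split.

Spectra: each strain/replicate gets every universal peak (default m/z
9678), `n_region_peaks = 5` region-wide peaks, and `n_noise_peaks = 3`
strain-specific peaks (constant centers per strain, re-jittered per
replicate, SD 3 Da), in triplicate, intensities uniform within
2000–55 000 counts (universal peaks in the top 40 % of the range, noise in
the bottom 20 %). Signal centers are kept ≥ 50 Da apart so regional peak
sets are disjoint. What the generator does **not** emulate: continuous
profile spectra, intensity correlations between peaks, peak dropout,
within-region sequence geography, codon-usage bias, and rate variation
among sites — so green tests demonstrate the pipeline's correctness and
sensitivity under the stated design, not robustness to every pathology of
real spectra or genomes.

Mixing series are exact linear seawater/end-member mixes (end-member at
Mg = 0) plus optional Gaussian noise on the species concentration.

## Numerical and reproducibility choices

Permutation p-values use (hits + 1)/(N + 1) with the observed
configuration counted. All stochastic routines take explicit seeds; the
pipeline derives one stream per stage from the master seed and the stage
name (CRC32), so a stage rerun in isolation reproduces its output, and a
fixed configuration reproduces outputs byte-identically. Default problem
sizes — 36 strains, 4254 concatenated sites, 1000 permutations, 100
bootstrap replicates, 1000 Z-test bootstraps — run end-to-end in well
under a minute; the test suite uses the same sizes for acceptance-style
checks and smaller ones (10–12 strains, single loci) for distributional
properties, chosen as the smallest designs at which the checked
asymptotics are stable.

## Known limitations

Exact-match alleles make no allowance for sequencing error; the Li/PBL
implementation counts multi-hit codons site-wise rather than averaging
mutational pathways; PHI's window is nucleotide-based (informative-site
density therefore affects power); Ward heights follow scipy's convention
rather than raw squared-distance increments; and the 16S curation,
ML/Neighbor-Net tree machinery and raw-spectrum processing of the original
workflow are intentionally out of scope.
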