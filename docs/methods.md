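# Methods

This note records what each stage computes, the conventions and defaults
behind it, what the synthetic generators do and do not emulate, and the
design choices made where more than one reasonable convention exists.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates, case and formats

All genomic coordinates are 1-based inclusive (the GFF3 convention)
throughout the library; any half-open arithmetic is confined to the I/O
module. Sequence case is preserved exactly: lowercase letters mean
soft-masked (repeat-derived) sequence and carry information downstream.
FASTA ids are the first whitespace token of the header (the full header
is retained as metadata); gzip input is detected by extension. IUPAC
ambiguity codes are accepted and preserved; they count as "not A/C/G/T"
in GC and CpG counting. Genes are read from GFF3 `gene`/`mRNA`/`CDS`
features (via gffutils); when a gene has several mRNA isoforms the
isoform with the largest total CDS length supplies `cds_parts`, because
the data model requires non-overlapping sorted parts and a union over
isoforms can overlap. Newick trees are handled by dendropy and must
carry branch lengths.

## Assembly statistics

N50 (generally Nx) uses the sorted-cumulative definition: sort lengths
descending, accumulate, return the first length at which the running sum
reaches x% of the total. A *gap* is a maximal run of ≥ `min_gap_run`
consecutive N/n characters. The default threshold is 1; submission
pipelines differ (NCBI sometimes counts only runs ≥ 10), and because no
single convention is universal the threshold is exposed as a parameter
and gap counts should be treated as convention-dependent when comparing
against published tables. The repeat fraction is lowercase characters
over total characters, N included in the denominator by default (the
simplest reproducible convention; an option excludes N). Lowercase
ambiguity characters are lowercase, hence repeats — but never GC.

## Contig decontamination

A single non-iterative pass with strict rule precedence:

1. **Taxonomy keywords.** A contig with ≥ 1 taxonomy-hit description is
   kept iff any description contains a keep keyword, else discarded.
   Matching is case-insensitive substring by default (robust to BLAST
   description formatting); a whole-word option exists. Default keywords:
   `Polistes`, `Vespula`, `wasp`.
2. **Orthogroup rescue.** A contig with no hits is kept if ≥ 1 of its
   predicted genes was assigned to a reference-clade orthogroup
   (precomputed evidence; this module runs no gene prediction or
   orthology inference).
3. **GC band.** Remaining contigs are kept iff their GC fraction lies in
   mean ± m·SD (default m = 2, bounds inclusive) where mean and SD are
   computed once over the rules-1–2 keepers and never updated afterwards.

GC is (G+C)/(A+C+G+T), case-insensitive, ambiguity codes excluded from
both sides, undefined without unambiguous bases (such a contig reaching
rule 3 is discarded with a warning). The SD is the sample SD (ddof = 1);
with a single band-defining contig SD = 0 is used with a warning, and
with none the filter errors and asks for relaxed keywords. Renaming
ranks records by length descending (ties by input order): the first
`n_chromosomes` (default 25) become `Chr<rank>`, the rest
`Scaffold<0001...>` in size order.

## CpG[o/e] and mixture-component selection

Counting is case-insensitive; ambiguity codes and N are excluded, and a
CpG is counted only where C and G are physically adjacent (an ambiguous
base breaks the dinucleotide). Two normalisations are provided. The
default is the length-normalised ratio `n_CpG·L/(n_C·n_G)`, i.e. observed
CpGs over the independence expectation `(n_C/L)(n_G/L)·L`, which is ~1
for i.i.d. sequence and yields the familiar 0–1.5 scale of published
CpG[o/e] histograms. The unnormalised variant `n_CpG/(n_C·n_G)` is
retained behind a flag; it scales as 1/L and is only comparable between
equal-length sequences. The pipeline default for sequence extraction is
coding sequence (`cds`), with `gene_body` available. Undefined values
(no C, no G, or < 2 unambiguous bases) are kept in tables as NaN and
excluded from fitting.

Component number is estimated by EM over univariate Gaussian mixtures in
two families — equal variance ("E") and free variance ("V") — for
k = 1..k_max (default 5), selecting the fit maximising
BIC = 2 log L − p ln n with p = 2k (E) or 3k − 1 (V); exact ties prefer
smaller k, then equal variance. Numerical choices: means initialise at
the (i+0.5)/k data quantiles, with 9 further restarts jittering them by
seeded Gaussian noise (SD = half the data SD); a variance floor of 1e-8
guards against singular components, and a run whose component empties or
pins at the floor is marked collapsed and discarded in favour of the
other restarts; convergence is |Δlog L| < tol·(1+|log L|), tol = 1e-6,
max 500 iterations (a non-converged best run is returned flagged).
Zero-variance input and n < 2k are errors. The inner loop is
numba-compiled; the EM monotonicity guarantee is asserted in tests, and
the implementation is cross-checked against scikit-learn's
GaussianMixture and R mclust (which uses the same maximised-BIC
convention) as independent references.

## Orthogroups and pan/core rarefaction

Presence is gene count ≥ 1; no minimum-gene threshold is applied. Genes
not assigned to any orthogroup are excluded from all sharing counts and
enter only the gene-total denominators of the per-species summary (their
counts are optional; percentages needing them are NaN when absent).
Three-way sharing reports the 7 presence/absence regions restricted to
the chosen species, ignoring presence elsewhere. Rarefaction evaluates
every subset size k = 1..n: exhaustively when C(n,k) ≤ cap (default
1000), otherwise cap distinct subsets sampled uniformly without
replacement (rejection with a seen-set — cheap at this cap even when
C(n,k) is astronomical), deterministic given the seed. The full
per-subset distribution is retained, not just means. A closure gap
(pan(n) − mean pan(n−1)) is reported as a diagnostic; whether a pan
genome is "closed" is an interpretation left to the user.

## Tree scaling

Ultrametricity compares all root-to-tip path lengths: the maximum
deviation from their mean, relative to the mean, must be ≤ rel_tol
(default 1e-6 — relative, because published ultrametric trees carry
rounding noise proportional to depth). Scaling multiplies every branch
by root_age / current root height, preserving topology and all branch
ratios exactly; the input tree is never modified and no rerooting is
attempted. MRCA ages are root height minus node depth; on an ultrametric
tree this equals half the patristic distance between two tips (asserted
as a property).

## Synthetic data

All generators are pure functions of their spec (seed included); derived
streams come from a stable CRC32-keyed seed sequence, so outputs are
byte-identical across processes and platforms. Each generator emits a
truth table sufficient to score its pipeline stage.

- **Assemblies**: host contigs at 32% GC (wasp-like) and contaminants at
  +0.15 GC (far outside any 2-SD host band, so filter scoring is
  unambiguous), log-normal lengths (median 20 kb), soft-mask tracts to an
  18% target, Poisson N-gap runs (mean run 50 bp). Host contigs carry a
  keyword-bearing description except a 10% miss fraction; every host
  contig carries predicted genes in reference-clade orthogroups (the
  rescue table), while contaminants never do and carry a non-matching
  description with probability 0.5, otherwise no hit.
- **CpG gene sets**: i.i.d. uniform-ACGT sequences whose CG occurrences
  are thinned — each gene draws a depletion level from its component
  (Normal truncated to [0,2]) and keeps each CG with probability
  min(depletion, 1); the substituted base is chosen so it cannot re-create
  a CG with a neighbour. Thinning is directly interpretable as a target
  o/e but cannot enrich, so realizable modes lie at or below ~1; the
  default components (means 0.4/0.7/1.0, SD 0.08, equal weights) give a
  realizable trimodal profile.
- **Orthogroup tables**: core (present everywhere), accessory (Bernoulli
  presence per species, redrawn if present in < 2 species so the stratum
  stays distinct from species-specific), and species-specific strata;
  gene counts are 1 + Poisson. The expected core contribution of the
  accessory stratum at subset size k is n_accessory·p^k up to a
  conditioning factor 1/(1−P(<2 presences)), negligible at the p and n
  used in tests.
- **Trees**: coalescent-style random binary topologies with uniform node
  ages and the root pinned at the requested height, exactly ultrametric
  by construction.

What the generators do **not** emulate: repeat-family structure, coverage
or scaffolding artefacts, codon structure and composition heterogeneity
of real coding sequence, gene-tree/species-tree discordance, or
annotation error. Passing tests therefore demonstrate correctness of the
computations under clean statistical structure, not robustness to every
artefact of real data.

## Problem sizes

The test suite and acceptance script run at the sizes the analyses are
designed around: 200 random assemblies for the statistics oracles; 20
replicates of 50 host + 10 contaminant contigs for filter scoring; 200 ×
10 kb genes for the neutral CpG expectation; 40 replicates of n = 3000
values (k_max = 5, both families, 10 restarts) for the mixture
operating characteristics; 10-species tables with 3000 core + 2000
accessory orthogroups for rarefaction; 50 random trees for scaling
properties. The full published-assembly statistics check requires the
three deposited GenBank assemblies (~180 Mb each) on local disk and is
the only part not runnable from generated data.

## Known limitations

Gap counts depend on an unstated run-length convention and should be
compared across tools with care; the decontamination filter trusts its
taxonomy and orthogroup evidence as given; BIC selection on heavily
overlapping mixture components is intrinsically unstable near the
decision boundary (the operating characteristics are quantified only for
well-separated components); and the pan/core sampler's subsets are
distinct within each size class but independent across sizes.
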