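# Methods

This note documents the models, conventions and numerical choices
behind each evokit component, the assumptions they make, and what the
synthetic-data generators do and do not emulate.

## Coalescent simulation (`evokit.demography`, `evokit.coalescent`)

**Model.** Demographic histories are composed from block-like
primitives: populations with relative sizes, piecewise-constant size
changes, backward-in-time merges (at time *t* every lineage of the
source population joins the destination), and per-epoch backward
migration matrices. The simulator runs the structured coalescent
backward from the sampling times: with *k* lineages in a population of
relative size *x*, coalescences occur at total rate *k(k−1)/x*
(pairwise rate 2/*x*), and a lineage in population *i* migrates to *j*
at rate *m[i][j]*. Serially sampled ("ancient") haplotypes enter the
process at their sampling times.

**Units.** Time is measured in units of 4N₀ generations throughout and
θ = 4N₀μ per locus, for compatibility with the classic `ms` ecosystem.
In these units E[T₂] = *x*/2 and a lineage accumulates mutations at
rate θ per unit branch length, which recovers the textbook neutral
expectations E[S] = θ·H₍ₙ₋₁₎ and E[π] = θ. (The two statements are a
package of conventions; changing one without the others breaks the
expectations, so they are fixed together and tested together.)

**Validation.** A model is rejected unless it "closes": after the last
merge, either one population remains or the survivors are connected by
positive final-epoch migration, so all lineages coalesce with
probability 1. Sampling from a population at or after the time it was
merged away is an error. Validation returns a report rather than
raising, so a model builder can show all problems at once.

**Mutations.** Infinite sites: each branch receives a
Poisson(θ·length) number of mutations, each at a unique Uniform(0,1)
position; carriers are the leaves below the branch. Mutations above
the root cannot exist, so every emitted column is segregating.

**Reproducibility.** Replicate *r* of a run with master seed *s* uses
the numpy stream seeded with the pair (*s*, *r*); any single replicate
can be regenerated in isolation. Identical seeds give bitwise-identical
output.

**Scope.** One non-recombining locus per replicate; no recombination,
no selection, no exponential growth (sizes are piecewise constant), no
finite-sites mutation models. Migration rates change only at declared
epoch boundaries.

## Summary statistics (`evokit.sumstats`)

Watterson's θ_W = S/a₁, π as the mean pairwise difference (computed
from the site-frequency identity π = Σ 2i(n−i)/(n(n−1))), Tajima's D
with the 1989 variance constants, and Fu & Li's D (polarized; derived
singletons = external-branch mutations) and D* (outgroup-free;
singletons counted on either allele) with the corrected variance
constants. Constants are computed fresh per *n* and memoized; no
tables.

Statistics that are undefined — S = 0, or a degenerate variance (e.g.
Tajima's D at n ≤ 3, where the variance constants vanish) — return
`None` rather than raising, so replicate pipelines keep running; the
empirical-distribution summaries report how many replicates were
excluded. Polarized Fu & Li's D is used for simulator output (0 is the
ancestral allele by construction); VCF-derived data defaults to the
unpolarized D*, because without an ancestral-allele annotation the
external-branch count is not identifiable.

## Distances and trees (`evokit.tree`)

Distances: p (mismatch fraction), JC69 = −(3/4)ln(1−4p/3) and K2P =
−(1/2)ln(1−2P−Q) − (1/4)ln(1−2Q) from the transition/transversion
fractions P and Q. Gap/N columns are removed per pair (pairwise
deletion), preserving signal in sparse alignments; a pair with no
comparable site, or a saturated correction (log argument ≤ 0), raises
an error naming the pair.

Tree building is canonical neighbor-joining in the Studier–Keppler
O(n³) form: join the pair minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) −
Σd(j,·), with branch lengths from the rate-corrected split formula.
Ties are broken by the lexicographically smallest pair of cluster
labels (a cluster is labelled by its smallest leaf), so runs are
reproducible across platforms. Negative branch lengths are kept —
faithful to the algorithm. NJ is consistent on additive matrices; the
`random_additive_tree` generator (random topology, branch lengths
U[0.05, 1], matrix = path lengths) exercises exactly that guarantee.

Bootstrap support resamples alignment columns with replacement B
times, rebuilds the tree, and counts the replicates containing each
bipartition of the original tree; replicates with saturated distances
are skipped and counted. Newick I/O writes supports as internal-node
labels, quotes labels containing metacharacters, collapses redundant
unary nestings on parse, and reports the character position of parse
errors.

## VCF statistics (`evokit.vcfstats`)

Reading goes through pysam; all records are kept with a class label
(biallelic SNP / indel / multiallelic / other), and only biallelic
SNPs feed the statistics. **Coordinates, stated once:** VCF positions
are 1-based; windows and BED output are 0-based half-open; the
conversion is pos − 1, so the variant at position *p* belongs to every
window covering *p* − 1.

The snapshot reports class counts, the transition/transversion ratio,
per-sample missingness, and the folded site-frequency spectrum
(complete-call sites only, so the bins sum to a knowable count).

Sliding windows tile [0, max position) per chromosome. Missing
genotypes are handled by site-wise deletion: each site contributes
with its own called-allele count, π as 2i(nₛ−i)/(nₛ(nₛ−1)) and θ_W as
1/a₁(nₛ). With complete data this reduces exactly to the matrix
statistics of `sumstats` (tested to 1e-12). Tajima's D per window uses
the nominal haploid count with the deletion-adjusted π and S — an
approximation under missingness, exact without it.

Fst is Hudson's estimator in the Bhatia et al. form, chosen over
Weir–Cockerham for its robustness to unequal sample sizes; windows
aggregate as the ratio of summed numerators over summed denominators,
and a site where both populations are monomorphic for the same allele
is undefined (skipped in the window sum). "Selection" scans are the
frequency-spectrum statistics above; no LD-based methods.

The `synth_vcf` generator plants per-site allele frequencies
(uniform or U-shaped beta), draws diploid genotypes binomially and
knocks out calls at a given missing rate. It emulates allele-frequency
structure and missingness only — no LD, no population structure, no
sequencing error — so tests against it validate bookkeeping and the
estimators' algebra, not robustness to real-data artifacts.

## MAF indexing and ortholog resolution (`evokit.mafindex`)

The index is a versioned, sorted TSV interval table per chromosome of
the chosen query genome: one row per MAF block containing that genome,
with the block's byte offset and length. Minus-strand rows are
normalized to forward coordinates at index time (fwd_start = srcSize −
start − size, per the MAF convention that minus-strand starts are
relative to the reverse complement). Queries are forward-strand,
0-based half-open; lookup bisects the start-sorted table and fetches
blocks by offset, never scanning the file. The block scanner is
hand-written because the index needs byte offsets, which alignment
parsers do not expose.

Merging chains blocks that are adjacent on the query genome (gap ≤
`max_gap`, default 0 = pure adjacency, exposed because "neighboring"
admits degrees). Gene duplication can map one query interval into
several competing chains; following the synteny argument that a longer
query-genome segment is the likelier ortholog, the chain with the
greatest total query coverage wins, ties going to the smaller start.
JSON output mirrors Ensembl-REST field naming; `slice` trims alignment
columns to the query interval by walking the query row's ungapped
coordinates. The `synth_maf` generator plants paralogous blocks at
less than half the true chain's coverage, so the ≥2× margin cases the
resolver must win are all represented in its truth ledger.

## Sample-specific networks (`evokit.ssn`)

For each gene pair, the reference Pearson correlation r over the n
cohort samples is compared with the correlation over n+1 samples after
appending the query sample: Δr = r₍ₙ₊₁₎ − rₙ. Following the SSN
method, Z = Δr / ((1−r²)/(n−1)) with a two-sided standard-normal p
value. The normal null is an asymptotic approximation: the exact null
of Δr is heavier-tailed (product-normal-like), so at α = 0.05 the
empirical rejection rate under a Gaussian null sits near 0.065–0.07
rather than 0.05 — measured, not corrected, since the inherited method
defines the statistic. Edges with |r| = 1 have zero null variance and
are reported unscored. Benjamini–Hochberg q values accompany raw p
(thousands of edges per sample make this the sensible default report),
and edges are ranked by |Z| with lexicographic tie-breaks. All-pairs
computation is capped at 2×10⁶ pairs; beyond that an explicit gene
subset is required. `synth_expression` draws block-equicorrelated
multivariate normals with a per-pair truth ledger.

## Command line and plug-ins (`evokit.cli`, `evokit.plugins`)

The CLI is a thin click layer over the library: `simulate`, `sumstats`,
`dist`, `nj`, `boot`, `vcf snapshot|windows`, `fst`, `maf index|query`,
`ssn`, `convert`. Any invocation can append a JSONL run-log entry
(timestamp, command, parameters, version) with `--log` — a portable,
machine-readable history. Plug-ins are YAML/JSON descriptor files
(name, version, attribution, subcommand, `module:function` entry)
discovered from `--plugins` directories or the `EVOKIT_PLUGINS` path;
attribution is mandatory and echoed in the subcommand's help, and name
collisions with built-ins or earlier plug-ins are rejected with a
logged warning. Format conversion covers fasta↔phylip (relaxed PHYLIP,
full names kept), ms→fasta (0/1 as A/T) and ms→vcf-lite (minimal VCF
4.2 with haploid GT calls; positions in (0,1) scale to ⌊p·L⌋+1,
collisions nudged right with a warning).

## Problem sizes used in the checks

The calibration run uses n = 20 haplotypes, θ = 5 and 2000 replicates
(enough for 3-standard-error bands of ±0.5 on E[S] and ±0.18 on E[π]);
the split bound and NJ consistency use 2000 genealogies and 200
8-taxon matrices; window and MAF oracles check 1000 random
configurations/queries; the SSN null calibration averages 150
independent cohort+sample draws of ~2016 edges each. These sizes make
the Monte-Carlo error small relative to every tolerance tested while
keeping the whole suite comfortably fast on one CPU.

## Known limitations

- No recombination or growth curves in the simulator; piecewise-
  constant sizes only.
- Window Tajima's D under missing data mixes a nominal n with
  deletion-adjusted π and S (documented approximation).
- The SSN normal null over-rejects slightly by construction (see
  above); q values inherit that approximation.
- The MAF resolver assumes chains compete only through query-interval
  overlap; rearrangements that interleave without overlapping are kept
  as separate segments.
- NJ is O(n³) and the all-pairs SSN is O(genes²·samples): desk scale,
  not genome scale.
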