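# Methods

## Problem and scope

`taxogenome` implements a taxogenomic workflow for prokaryotes: pairwise
whole-genome and core-genome similarity metrics, level-wise summary
statistics, data-driven species/genus rank boundaries, and threshold-based
clustering and classification of strains.  The workflow targets the
situation exemplified by heterogeneous actinobacterial genera such as
*Rhodococcus*: strains nested in species nested in species-groups, where the
species-groups are as distant from one another as recognized genera are, and
where conventional criteria leave many strains misclassified.  Because the
package is validated on simulated clades rather than public assemblies, a
simulator with exact ground truth is a first-class component.

## Similarity metrics

Four metrics, all on a 0-100 scale; identity always counts gap columns in
its denominator (matches / alignment columns) so the definition is uniform
across metrics.

* **ANIb-G** — the query genome is cut into non-overlapping 1020 bp
  fragments; each fragment's best local alignment against the target is
  retained when identity > 30% and at least 70% of the fragment is inside
  the alignment; ANIb-G(query→target) is the mean identity of retained
  fragments.  Undefined (NA, never 0) when nothing passes the filters —
  a 0 would corrupt level means.
* **FBS** (fragmented BLAST similarity) — 500 bp non-overlapping fragments;
  each fragment contributes its best local score divided by its self-score
  (fragment length x match reward), scaled by 100; fragments without a hit
  contribute 0.  FBS saturates toward 0 for unrelated genomes without ever
  being undefined.
* **ANIb-C** — mean pairwise nucleotide identity over single-copy core gene
  families, one global alignment per family.
* **AAI** — the same average over the translated core genes (bacterial
  code, stop codon excluded).

ANIb-G and FBS are directed (query fragmentation breaks symmetry); both
directions are computed and the symmetrized view S'(i,j) = mean(S(i,j),
S(j,i)) feeds all downstream statistics, with directed values preserved on
disk next to a JSON sidecar recording the `directed` flag.

## The local alignment engine

FBS and ANIb need a BLAST-like local search, implemented in-repo as
seed-and-extend: exact k-mer seeds (k = 15) from a sorted k-mer index of
the target, grouped into diagonal clusters, each cluster extended by
banded affine-gap Smith–Waterman (numba-compiled), band 32 columns and
widened whenever the optimal traceback touches a band edge.  Both strands
are searched by reverse-complementing the fragment.  Scoring: match +1,
mismatch −2, gap open −4 for the first gap column and −1 for each
additional column (the Biopython `PairwiseAligner` convention, which the
test oracle shares).  Ties break by higher score, then lower target
coordinate, then forward strand.

Two sensitivity details matter at the divergences the metrics operate in
(70–100% identity):

* When no 15-mer seed exists, seeding is retried once at k = 8.  At 28%
  divergence roughly one fragment in ten has no exact 15-mer match; without
  the fallback those fragments would be silently dropped and the
  between-genus ANIb band biased upward.
* There is no E-value model.  A minimum score floor of 2k suppresses random
  seed hits; the metric-level identity/coverage filters do the real
  filtering, which is adequate at these fragment sizes.

A single scoring scheme serves both FBS and ANIb rather than emulating two
BLAST parameterizations: the metrics consume identity and normalized
score, not bit scores, so the simplification does not affect the
quantities reported.

## Core genome

Orthology is inferred by reciprocal best hits over CDS translations with
global alignment (match +1 / mismatch −1 / gap −2; identity ≥ 40%, mutual
coverage ≥ 70%), tie-inclusive so identical within-genome duplicates join
one family and violate the single-copy requirement rather than slipping
through as separate families.  Families are connected components of the
RBH graph; the core is the set of single-copy families covering every
genome.  Thresholds are deliberately transparent and exposed in
`RBHParams`; they are a surrogate for score-ratio methods whose exact
cutoffs are not reproducible.

The concatenated core alignment aligns translations per family
(column-for-column when genes are equal length, the invariant case for
simulated data; `mafft` otherwise), back-threads codons, removes the start
and stop codon of every gene, and strips any codon column containing a gap
or N in any genome.  The result is missing-data-free and divisible by 3 by
construction.

## Level statistics and rank boundaries

Pairwise similarities (symmetrized, self-pairs excluded, NA pairs dropped
with a logged count) are pooled into three levels: within species, within
species-group excluding same-species pairs, and between groups.  Each
level is summarized as mean and population SD (divisor n; the convention
is not derivable from published pooled figures and is fixed here once).

The rank boundary between adjacent levels is

    threshold = [ (upper.mean − upper.sd) + (lower.mean + lower.sd) ] / 2

with the open interval between the two one-SD bounds as the *buffer zone*.
This midpoint-of-1SD-bounds rule reproduces all six published *Rhodococcus*
boundaries from their published level statistics — 66.75 and 6.9 (FBS
species/genus), ~94 and 74.8 (ANIb-G), 96.88 (ANIb-C species), 98.41 (AAI
species) — and is therefore adopted as the boundary rule; it is a
reverse-engineered convention, not a published formula.  Rounding happens
only at report time (2 decimals for species, 1 for genus boundaries).

Clustering is single-linkage at a threshold: connected components of the
graph with an edge wherever the symmetrized similarity meets the
threshold.  This mirrors the shared-pairwise-cutoff reading of group
membership and makes borderline cross-group similarities visible as
flagged edges rather than silent merges.  Classification flags:
MISCLASSIFIED (declared conspecifics exist but best similarity to them is
below the species threshold), NOVEL_SPECIES (singleton species cluster
inside a populated group), NOVEL_GENUS (below the genus threshold to every
named group) and BUFFER_ZONE (a decisive similarity inside a buffer
interval).  Note that in clades with very tight within-species bands the
buffer's upper bound sits just below the within-species mean, so
BUFFER_ZONE marks ordinary uncertainty, not error.

## The simulator

`simulate_clade` evolves a random ancestor (uniform composition at a GC
target, default 0.62 as typical for the actinobacteria the workflow
targets) along a fixed star-within-star topology: genus ancestors, species
ancestors, leaf strains.  Substitutions are Jukes–Cantor-style (uniform
target base among the three alternatives) and compose along a lineage as
c(a,b) = a + b − (4/3)ab, so per-branch probabilities are solved so the
*pairwise* divergence at each level hits the configured targets exactly in
expectation; `expected_identity` exposes the closed form used as the test
oracle.  Defaults: 3 genera x 2 species x 3 strains, 20 kb ancestors with
12 genes of 600 bp, pairwise divergence 0.02 / 0.15 / 0.28 (≈ 98 / 85 / 72%
identity — the bands separating species and genera in the target taxa),
indel rate 2e-4/site with geometric lengths (mean 3), and per-species gene
loss probability 0.1.  20 kb is a desk-scale choice: every property being
tested (band separation, threshold recovery, core-genome structure) is
scale-free above a few hundred fragments.

Constraints that keep downstream stages well-defined: genes are laid out
non-overlapping on the forward strand (ATG ... TAA, no internal stops);
substitutions that would create a premature stop are re-targeted to a
non-stop base (a negligible rate bias at tested divergences); indels never
fall inside a CDS, so frames survive and codon-stripping logic is testable
independently of frameshift repair; whole-gene loss operates per species
lineage.  Realized pairwise divergence is recorded from the true site
homology map (ancestral coordinates), not estimated.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data:

* **No selection.**  Substitutions are neutral, so amino-acid identity
  falls *below* nucleotide identity (only ~24% of single-nucleotide
  changes are synonymous).  In real genomes purifying selection inverts
  this: AAI typically exceeds ANIb-C, and core genes are more conserved
  than the genome average.  Tests therefore check the synonymous-site
  mechanism directly (synonymous-only changes give AAI 100 with ANIb-C
  < 100) rather than asserting the empirical AAI > ANIb-C ordering.
* No rearrangements, horizontal transfer, mobile elements or codon-usage
  realism; substitution rates are uniform across sites.
* The star topology has no internal structure within a level, so
  within-level similarity bands are tighter than in real clades.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout.  Ambiguity codes beyond N
are coerced to N on ingestion (logged), and N never matches in alignment.
Matrices round-trip through TSV at 4 decimals; undefined cells are NA.
All-N genomes have undefined GC content.  Single-linkage clustering treats
NA as below threshold (logged).  NJ trees (inspection plumbing, via
scikit-bio) use distance = 100 − similarity and clamp negative branch
lengths to zero.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces byte-
identical artifacts, including FASTA output.

## Problem sizes used in validation

Unit and property tests run on 8–18-genome clades of 6–20 kb.  The
alignment engine is checked for exact score equality against full
Smith–Waterman (Biopython's C implementation, both strands) on 200 random
fragment/target instances up to 2 kb at up to 20% divergence.  ANIb
calibration uses indel-free 100 kb pairs at divergence 0.01/0.05/0.1, ten
seeds each (tolerance ±0.5 of 100·(1−p)).  Partition recovery uses twenty
default-configuration clades (18 genomes each); thresholds are derived
from each clade's own level statistics and must reproduce the true species
and genus partitions with adjusted Rand index 1.0 in at least 19 of 20
runs.

## Known limitations

* RBH orthology assumes mostly 1:1 gene content; heavy paralogy would
  shrink the core below what score-ratio methods report.
* The banded extension is exact only because the band widens on edge
  contact; pathological tandem-repeat targets could make widening costly.
* Identity definitions differ subtly between tools (BLAST counts gapped
  columns too, but other ANI implementations may not); comparisons against
  external ANI values should expect sub-percent definitional offsets.
* The boundary rule presumes the finer level's mean exceeds the coarser
  level's; overlapping level distributions collapse the buffer to a point
  and are flagged rather than resolved.
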