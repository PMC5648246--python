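# Methods

This note records the models, parameter choices and numerical conventions
behind `barcodekit`, and what the synthetic-data experiments do and do not
demonstrate.

## Quality control

A record passes the default filter when it has at least 500 unambiguous
(A/C/G/T) positions and an ambiguous-call fraction below 1%. "Ambiguous"
counts every non-ACGT, non-gap symbol over the non-gap positions;
leading/trailing gaps (short reads placed inside the alignment) count
toward the length shortfall instead. A whitelist retains named records
regardless — the convention for a species whose only available sequence
narrowly fails the filter. Reading-frame checks translate with the
invertebrate mitochondrial code (NCBI table 5, the correct code for insect
COI); a gap run whose length is a multiple of three is reported as a
codon-sized deletion but not flagged, since it preserves the frame.

## Distances

All divergences use pairwise deletion: a site enters a pair's comparison
only when both sequences carry an unambiguous base there. Partial IUPAC
codes (R, Y, ...) are excluded outright rather than fractionally matched,
matching the convention of the distance tools barcoding studies typically
use. The K2P distance is d = −½ ln(1−2P−Q) − ¼ ln(1−2Q); when an argument
of a logarithm is non-positive (saturation) or a pair has no comparable
sites, the distance is recorded as missing (NaN) with a warning, and
excluded from summaries — never silently zeroed. Empirical COI divergences
in regional libraries top out well below saturation (~15%), so missing
pairs arise only from degenerate inputs. Distances are stored as
fractions; reports print percentages.

## Barcode gap and thresholds

The per-sequence profile records the furthest conspecific and the nearest
non-conspecific (nearest neighbor). A species with n ≥ 2 has a barcode gap
when every member's NN distance strictly exceeds that member's maximum
conspecific distance; "barcode sharing" means distance zero under pairwise
deletion, not string equality. Unlabeled records are excluded from every
pool and from NN consideration because they can neither be scored nor
confer a name.

Percentile thresholds (95th of intraspecific, 5th of congeneric) use
linear interpolation between closest ranks (numpy's default). The rule is
fixed and used everywhere; alternative percentile conventions shift the
thresholds by less than the spacing between adjacent pooled values.

## Identification simulation

Queries are the members of species with ≥ 2 sequences, each removed from
its own candidate set; singletons remain as potential matches, unlabeled
records never match. "Within the threshold" is inclusive (d ≤ t). Ties at
the closest distance are recognized with a tiny relative tolerance (1e-9)
so that equal distances computed through different floating-point paths
still tie; a tie spanning two or more species is ambiguous, a tie among
conspecifics only is correct.

The cumulative-error threshold counts, per candidate t, queries whose
nearest conspecific lies beyond t (false negatives) and queries with at
least one non-conspecific within t (false positives). The error curve is
piecewise constant between observed distances, so the grid is the observed
distinct values plus midpoints; the reported optimum is the midpoint of
the minimizing band. Note the zero-error band is bounded below by the
largest *nearest*-conspecific distance over queries, which can sit below
the largest intraspecific distance — single-linkage-style chains keep a
diverse species identifiable at thresholds smaller than its diameter.

The density threshold fits a Gaussian KDE (Scott bandwidth, 512-point grid
on [0, max distance]) to all pairwise distances and returns the interior
local minimum with the smallest density. On a genuinely bimodal pool this
is the intra/inter transition. On sparse multimodal pools (few species,
several divergence levels) the deepest valley can lie between
*interspecific* modes instead; callers are expected to inspect the value,
and the pipeline falls back to a configured default when no interior
minimum exists. This is a property of the rule itself, not of the
implementation.

## MOTU delimitation

**Gap partitioner (ABGD-style).** All pairwise distances are sorted and
deduplicated; a gap between consecutive distinct values is a candidate
when its upper edge exceeds the prior intraspecific divergence P, and
significant when its width exceeds X times the local slope — the mean
spacing of the preceding `slope_window` (default 10) distinct values, with
the global mean spacing as fallback. Sequences are then partitioned into
connected components of the graph linking pairs at or below the gap's
lower edge. The recursive variant re-applies detection inside each group
(on that group's own sub-distribution) until nothing splits; groups below
3 members are never re-split. With no significant gap the partition is a
single MOTU carrying a `no_gap` flag. Defaults P = 1%, X = 1.5 (capture
only large gaps). Because the gap must lie above P, MOTU counts are
non-increasing in P on fixed data. As with the original formulation, very
small priors admit candidate gaps inside the intraspecific distribution
and over-split; reliable recovery of a clean species partition needs P
between the intraspecific maximum and the interspecific minimum.

**Statistical parsimony.** Haplotypes are linked when their absolute
difference count (over mutually comparable sites) does not exceed the
connection limit J; MOTUs are connected components, so clusters chain
through intermediate haplotypes. J is the largest j whose probability of
parsimony meets the chosen confidence. That probability is computed under
a uniform-rates finite-sites model: j substitutions placed independently
on m sites are parsimonious when they all strike distinct sites,
P(j) = Π_{i=1}^{j−1} (1 − i/m). For m = 658 this gives J = 8 at the 95%
limit and J = 12 at 90%. P(j) is decreasing in j, so J is non-increasing
in the confidence limit. Pairs compared over few sites (heavy ambiguity)
connect more easily; linked pairs whose comparable-site count falls below
75% of the alignment are reported as caveats.

**Refined single linkage (simplified).** Stage 1 forms single-linkage
components at a 2.2% seed threshold. Stage 2 scans candidate split
thresholds inside [0.7%, 2.2%) — the lower bound plus every observed
within-component distance in the window, which covers all achievable
sub-partitions — and scores each sub-partition by mean silhouette over the
component's distance submatrix. The best split is accepted only when its
silhouette is positive (an unsplit component scores zero by convention),
so uniform components never split. The production algorithm behind
public barcode-cluster identifiers additionally refines against a global
database with Markov clustering; that context-dependent behaviour is out
of scope, and cluster counts from this variant are comparable only in
order of magnitude.

**Concordance.** A species spanning one pure MOTU is a MATCH; k ≥ 2 pure
MOTUs a SPLIT(k); one shared MOTU a MERGE; ≥ 2 MOTUs with at least one
shared a MIXTURE(k). The categories are exhaustive and mutually exclusive
over labeled species, and singletons are classifiable (MATCH alone,
MERGE when sharing).

## Trees

NJ construction delegates to scikit-bio's Saitou–Nei implementation with
negative branch-length estimates clamped to zero (the library does not
transfer the deficit to the adjacent branch; on barcode-like data the
negative estimates are numerically tiny). Bootstrap replicates resample
alignment columns with replacement, codon-agnostic, rebuild the distance
matrix and tree, and score each internal bipartition of the original tree
by the percentage of replicates containing it; bipartitions are
canonicalized by the side not containing a fixed reference tip, so
rerooting cannot change supports. Replicates with inestimable distances
cannot vote. Missing distances are disallowed in tree mode — such pairs
must be filtered first.

A singleton species is distinguishable when its barcode is unshared and
some tree edge other than its own tip edge separates it from every member
of its nearest-neighbor species; equivalently, after pruning the singleton
its attachment node sees that species in a single direction. This local
criterion behaves sensibly even when the neighbor species is itself
non-monophyletic.

## Geography

Great-circle distances use the haversine formula with R = 6371 km (one
degree of latitude = 111.195 km). The Mantel statistic is the Pearson
correlation of the off-diagonal upper triangles; significance comes from
simultaneous row/column permutations of the genetic matrix with the
observed statistic included in the reference set, p = (1 + #{r* ≥ r}) /
(1 + n_perm), one-sided for positive association by default (999
permutations). Zero-variance matrices yield an undefined result rather
than an error; identical sampling coordinates are retained, not jittered.
The screen tests species with ≥ 10 individuals spanning ≥ 275 km, and
spawns per-species RNG streams from the global seed in sorted species
order so results do not depend on which other species are present.

## Synthetic libraries

The generator emulates a regional COI barcode campaign. Sequences evolve
from a root haplotype through genus ancestors (mean inter-genus divergence
15%) and species ancestors (mean congeneric divergence 7%) down to
individuals (mean intraspecific divergence 0.3%), by Poisson numbers of
substitutions at uniform sites with transition:transversion rate ratio
κ = 3 (transition probability κ/(κ+2) per event). Multiple hits are
allowed; a branch expected to contribute divergence t receives Poisson(tL)
events, and the K2P estimator is what recovers t, so calibration is exact
in the model's own currency at these depths (the ±30% acceptance band on
realized means reflects Monte-Carlo error, not bias). Species- and
genus-branch depths are Gamma-distributed (shape 3 by default), spreading
interspecific divergences into the broad overlapping range (~3–15%+) real
libraries show; `branch_rate_shape` large gives near-clock depths and a
cleanly bimodal pool, and `min_interspecific_divergence` enforces a
barcode-gap margin for clean-gap experiments. About 27% of species are
singletons; multi-member species have 2 + Poisson(4) individuals (mean 6).
Ambiguity is injected as N at rate 5e-4 per site.

Anomaly injections reproduce the failure modes of interest: a *split*
gives half a species a lineage a chosen depth away (deep intraspecific
divergence); a *merge* re-derives one species' ancestor a small residual
from a congener's (shallow interspecific divergence, down to shared
barcodes). Isolation by distance places a species' individuals along an
800-km transect with a serial lineage chain, so genetic distance grows
with geographic separation at a tunable total depth.

What the generator does **not** emulate: coalescent genealogies within
species (individuals are independent draws from the species ancestor),
rate variation among sites, indels, NUMTs/contamination, and uneven
geographic sampling. Tests passing on this generator therefore validate
the analysis chain's logic and calibration, not its robustness to every
artifact of real chromatogram-derived data.

The worked 8-sequence toy (two genera, three species, one singleton, one
cross-species shared haplotype) is built from hand-placed substitutions at
disjoint alignment positions, so every pairwise transition/transversion
count — and hence every K2P distance — is known exactly and serves as an
oracle across modules.

## Problem sizes and determinism

Default experiments run at desk scale: libraries of 12–50 species
(~60–240 sequences), 1,000 bootstrap replicates, 999 Mantel permutations,
100-replicate threshold studies and 500-replicate calibration of the
Mantel type-I error. A single seed drives everything; per-stage and
per-species streams are spawned deterministically (stage-name hashing,
sorted-species spawning), so repeated runs are bit-identical.

## Known limitations

- The gap partitioner is a faithful re-statement of the ranked-distance
  gap idea, not a line-by-line port of any reference binary; constants
  (slope window, recursion minimum of 3) are exposed in its parameters.
- The parsimony connection limit uses the uniform-rates probability above;
  estimators that model rate heterogeneity give somewhat larger limits at
  the same confidence.
- The refined-single-linkage variant is local-data only (see above).
- The density-minimum threshold is only meaningful on bimodal pools; on
  multimodal pools it reports the globally deepest valley, wherever that
  lies.
- NJ negative branch lengths are clamped without deficit transfer.
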