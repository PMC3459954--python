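# Methods

This note documents the statistical conventions, parameter defaults, and
design choices behind `hapresolve`, and what the synthetic-data generator
does and does not emulate.

## Haplotype identity

Within one aligned marker, two specimens carry the same haplotype iff
their sequences are identical in every analyzed column. Three conventions
follow from how such data are scored in practice:

- **Gaps separate haplotypes.** The gap character `-` is a first-class
  fifth state: a single gap difference is as diagnostic as a substitution.
  Runs of gaps are *not* collapsed into single indel events — each
  differing column separates haplotypes. Two taxa gapped differently
  within the same indel region therefore receive different haplotypes,
  which is the desired behavior.
- **Ambiguity codes compare literally** (`R ≠ A`). The supported workflow
  is to mask known-ambiguous columns before collapsing (see Masking), not
  to fold ambiguity semantics into identity.
- **Code numbering is arbitrary.** Codes are assigned 1..n by first
  occurrence in input order, making runs deterministic; every downstream
  statistic is invariant under relabeling (property-tested).

Combination haplotypes are joint identity across markers — equality of
the per-marker code tuple. Because mitochondrial markers are inherited as
one locus, the combination is the natural unit; it refines every
single-marker partition, so haplotype counts and resolved-species sets
can only grow as markers are added (also property-tested). Combinations
are built only over specimens that have *all* requested markers; the
pipeline drops (and logs) specimens missing any.

## Masking

Masks are user-supplied 1-based inclusive column intervals with a reason
(`unalignable`, `ambiguous`, `trim`). They are configuration, not
hard-coded: which columns of a given alignment are unalignable is a
judgment made by whoever built the alignment, so the package takes
intervals and removes those columns before collapsing (overlapping
intervals are merged). The post-mask column count is reported as the
analyzed sequence length.

## Resolution scoring

A species *S* is **fully resolved** by a marker subset iff every
haplotype observed in *S* occurs in no specimen outside *S*.

- **Uniqueness scope is the entire dataset** by default, not the focal
  genus: in low-variation marker systems, haplotypes demonstrably cross
  genus boundaries, and such sharing must block resolution. A
  `uniqueness_scope="genus"` flag provides the restricted variant for
  sensitivity analysis; it can only resolve more species, never fewer.
- **Unidentified specimens** (never examined morphologically) are
  excluded from the species list — they contribute no morphotype and
  cannot enter the denominator. By default their haplotypes also do not
  count against other species' exclusivity, because nothing is known
  about their conspecificity; `include_unidentified=True` makes each one
  a pseudo-taxon that blocks resolution.
- **Percentages** are integer-rounded half-up (2/12 → 17).

Diagnostic characters are the "pure" kind only: columns where all
specimens of a species share one state (gap included) and no other
specimen carries that state. Compound (multi-column private combination)
diagnostics are out of scope.

## Distances

Uncorrected p-distance under **pairwise deletion**: for each pair, only
columns where both sequences carry an unambiguous base (A/C/G/T) are
compared; `p = differing / compared`. The reported "bp changes" are the
integer differing-site counts under the same rule. Note the deliberate
asymmetry with haplotype identity: a gap *separates haplotypes* but is
*excluded from distances*. A pair with zero comparable columns gets
p = 0 with a warning.

Pairs of identified specimens are classified as intraspecific (same final
morphotype label), interspecific (same genus, different species), or
intergeneric, and each level is summarized as min–max of p and of the raw
count. A level with no eligible pairs is reported absent, not zero.
Distance summaries for marker combinations use the concatenated masked
alignments.

**Cryptic-species screen:** a species is flagged when its maximum
intraspecific p strictly exceeds the threshold (default 0.005, i.e. the
conventional 0.5% criterion). The inequality is strict: a species at
exactly 0.5% is not flagged.

## Depth and geographic ranges

Depth strings are messy field data: `parse_depth` is total, mapping any
string to exactly one observation. A single number is exact; two numbers
(hyphen, en-dash, or slash separated; prime marks stripped) collapse to
the midpoint of their extremes, flagged `range_midpoint`; a trailing `?`
flags the value uncertain; anything else is missing. Non-positive values
are treated as missing.

Depth-bin occupancy uses half-open bins `[lower, lower + width)` with a
100 m default width — edge handling is a convention, chosen as the
standard half-open form and documented here. Columns (haplotypes) are
sorted by minimum observed depth, ties broken by code. Cells containing
midpoint-derived or uncertain depths are counted separately so they can
be rendered distinctly. Total placed counts are invariant to bin width
(tested).

Geographic span per haplotype is the maximum pairwise great-circle
distance (haversine, Earth radius 6371 km) among its occurrence sites
with coordinates; it is undefined — not zero — when fewer than two sites
have coordinates. Coordinates are optional metadata throughout.

Refinement makes range inflation measurable: every combination
haplotype's depth interval, site set, and region set nest inside those of
the single-marker class containing it (tested on the reference dataset),
so coarser markers can only widen apparent ranges.

## Reference dataset

The packaged table (`data/north_pacific_primnoids.tsv`) encodes 54
primnoid octocoral colonies from North Pacific seamounts: 39 *Narella*
colonies spanning 12 identified morphospecies, and 15 colonies of five
other genera (*Callogorgia*, *Parastenella*, *Primnoa*, *Calyptrophora*,
*Paracalyptrophora*), with per-marker integer haplotype codes for NCR1,
ND6, ND2, COI+ and MutS, plus site, region and depth strings. Six
colonies were never examined morphologically and are encoded
`unidentified`; one colony's label reflects its re-examined, final
morphotype. Colonies without unique catalog numbers carry synthetic IDs
(`unnumbered-N`, suffix letters) so that specimen IDs are unique. The
table contains codes, not sequences, so the pipeline runs it in `codes`
mode; sequence-level statistics (analyzed lengths, distances) require
the alignments themselves.

## Synthetic-data generator

The generator emulates the data-generating process the analysis assumes:

- a root sequence per marker; genus backbones at `inter_genus_diffs`
  substitutions (default 8 per marker);
- congeneric species at `inter_species_diffs` substitutions from the
  backbone (default 1–12 per marker, drawn uniformly);
- within species, 1–2 variants separated from the species base by
  `intra_species_diffs` substitutions (default range 1–4), with the
  per-marker draw capped at `max(1, floor(intra_ceiling · length))`
  (default ceiling 0.5%): intraspecific variation stays below the
  cryptic-species criterion wherever marker length permits, matching the
  structure of real multi-marker surveys in which several within-species
  substitutions occur only on the longer markers. On markers shorter than
  `1/intra_ceiling` columns the one mandatory difference can still exceed
  the criterion;
- **haplotype sharing** as verbatim copying: with probability
  `share_prob` a species inherits a congener's base haplotype across all
  markers at once — an incomplete-lineage-sorting phenocopy. Copying is
  exact rather than low-divergence because unresolvable cases in real
  data are exact identity, and it makes ground truth sharp: the
  unresolved species are exactly the copiers and their donors (tested);
- substitution positions drawn uniformly without replacement; all draws
  from one seeded generator, so output is byte-reproducible;
- optional clade-specific indel blocks (gap runs written into one genus)
  and per-column ambiguity injection; both are absent from the clean
  sequences recorded in the ground truth;
- per-species depth bands (default 400 m width inside a 400–4600 m
  range) and a default seven-site pool with coordinates in three regions.

Distinctness of all planted species/variant sequences is enforced on the
cross-marker concatenation with bounded retries; configurations whose
sequence space cannot accommodate the requested diversity raise
`InfeasibleConfig`.

What the generator does **not** emulate: coalescent genealogies, rate
heterogeneity across sites or lineages, selection, alignment error, and
sequencing error. Passing recovery tests therefore demonstrates that the
pipeline's bookkeeping is correct (partitions, counts, planted distances,
sharing → unresolved mapping), not that real data meet the generator's
assumptions.

## Problem sizes and numerical choices

Tests run at desk scale by choice: oracle-equivalence checks use ≤200
synthetic sequences of 120–200 columns against independent brute-force
loops; the sharing-monotonicity check averages 22 fixed seeds per sharing
level on a 2-genus × 4-species configuration; reference-table checks are
exact integer computations over 54 rows. The distance path is vectorized
(numpy byte comparison) while every oracle is a deliberate per-column
Python loop, keeping the two routes independent.

## Known limitations

- Resolution is a presence/absence criterion; it does not weight by
  sampling depth, so a species sampled once is "resolved" more easily
  than a well-sampled one. Interpret alongside specimen counts from the
  incidence matrix.
- Masks must be supplied by the user; the package does not detect
  unalignable regions.
- Depth midpoints treat a dive's depth range as symmetric; occupancy
  marks such cells but does not spread them across bins.
- `codes` mode cannot compute distances or diagnostic characters — those
  need sequences.
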