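# Methods

## Substitution geometry

A genetic code fixes, for every unordered pair of canonical amino acids, the
minimum number of nucleotide substitutions needed to convert one into the
other: the minimum Hamming distance over all codon pairs, one codon per amino
acid. Distances are computed from the code table alone, never from observed
nucleotide sequences, and each amino acid is treated as a single codon set
(serine's two disjoint codon blocks are pooled — the minimum over all codons
is what the definition asks for). Stop codons never participate. Codon tables
accept both T and U and are normalized internally to RNA. Under the standard
code 115 of the 190 pairs are multi-step (distance ≥ 2); the vertebrate
mitochondrial code, which reassigns UGA→W, AUA→M and AGA/AGG→stop, shifts
seven pair distances, all involving I, M or R.

## Site classification

The three CAM criteria are evaluated per column: ≥ 2 distinct amino acids;
each present amino acid in ≥ 2 taxa; all distinct-residue pairs multi-step
(CAM) or all single-step (non-CAM). No ancestral state is assumed — the
"in ≥ 2 taxa" requirement replaces it. With more than two residue groups the
column is classified only when all pairs agree in class; mixed columns are
"other".

Non-canonical symbols (gaps, X, B, Z, stops) are missing data by default:
criteria apply to the canonical residues only. A strict mode instead
disqualifies any column containing them; both behaviours are exposed because
how the original site-listing scripts treated gapped columns is not
documented. A classified column with exactly two residue groups that cover
the full taxon set induces a bipartition; a two-group column whose groups do
not cover all taxa (possible only via missing data) gets no bipartition and
is excluded from support tables, since a partial split cannot be tallied
against full-taxon-set splits.

Column indices are 0-based in the API and 1-based in CLI tables.

## Parsimony and homoplasy

Parsimony lengths use the Fitch algorithm for unordered states, rooting the
unrooted tree on an arbitrary edge (the count is root-invariant; tests verify
this against exhaustive enumeration of internal-state assignments). Missing
leaves are wildcards: they adopt whatever state set reaches them and never
force a change — the standard parsimony treatment of missing data. The
minimum length of a column over *all* topologies is the number of distinct
observed states minus one; tests confirm this equals the minimum over every
enumerated topology.

The homoplasy index is HI = 1 − CI with CI = min_length / length_on_tree
(constant columns are defined to have HI = 0). This is the standard
consistency-index orientation; it is the only orientation under which an
informative two-state five-taxon site takes exactly the values 0
(tree-supporting) or 0.5 (tree-conflicting).

Tree search is exhaustive over the (2n−5)!! binary unrooted topologies,
capped at 8 taxa (10,395 trees); heuristic search is out of scope. All
co-optimal trees are returned. Bootstrap resamples columns with replacement
(multinomially over collapsed column patterns, which makes replicates cheap)
and by default counts a reference bipartition as recovered only when it is in
*every* co-optimal tree of the replicate; an "any" semantics is available,
since how co-optimal trees should be credited is a genuine convention choice.

## Internode certainty

IC for a focal bipartition uses the focal count and the single most prevalent
conflicting count, IC = 1 + Σ pᵢ log₂ pᵢ. Two splits conflict iff all four
pairwise block intersections are non-empty (the pairwise compatibility test).
ICA includes every conflicting bipartition whose support exceeds a prevalence
threshold — default 5% of the total site count, configurable — with fallback
to the single most prevalent conflict when none qualifies, and uses log base
equal to the number of included bipartitions. This inclusion rule is the one
under which all published two-decimal IC/ICA values for the yeast data
(0.66/0.66, 0.36/0.36, 0.44/0.40, 0.22/0.17) are reproduced simultaneously;
the threshold is therefore a first-class parameter rather than a constant.

TC and TCA are sums of IC and ICA over the reference tree's internodes,
reported at full precision. Note one display artifact: for the CAM profile
the full-precision internode values 0.6644 + 0.4414 sum to 1.106, which
rounds to 1.11, while summing the display-rounded values gives 1.10; both
conventions appear in the wild. ICA is not globally monotone in added
conflicting support (the log base grows with the number of included
bipartitions); it is monotone decreasing in the dominant-focal regime that
real support profiles occupy.

## Statistics

Fisher's exact test on the 2×2 (site class × HI value) table is two-sided in
the conventional sense: the total hypergeometric mass of tables at the
observed margins with point probability ≤ the observed one (tests verify the
implementation against direct enumeration).

The binning procedure assigns sites to disjoint equal-size bins uniformly at
random without replacement (leftover sites unused — e.g. 2,647 sites into 52
bins of 50 uses 2,600 and leaves 47) and compares the two classes' bin-mean
HI values with a two-sided Wilcoxon rank-sum test. Midranks handle ties. For
combined n ≤ 20 an exact p-value is available by enumerating all rank
assignments; the default is the normal approximation with tie correction and
a 0.5 continuity correction, appropriate for the 52-bin samples. Unequal bin
counts per class are supported (52 CAM bins can be compared against all
available non-CAM bins). A single user-set seed drives binning through
spawned child generators, so reports regenerate bit-identically. Under the
null (both classes at the same conflict rate) the measured type-I error of
the whole procedure at α = 0.05 is 0.05 over 1,000 seeded replicates.

## Synthetic data

The generator plants informative columns directly at the amino-acid level: a
planted column draws an unordered residue pair uniformly from the requested
class (multi-step for CAM, single-step for non-CAM) and assigns one residue
to one block of the requested bipartition, the other residue to the rest.
Constant filler columns draw one residue uniformly from the 20. Column order
is shuffled by the seed. This is the minimal construction that exercises
classification, support counting, homoplasy, certainty and the statistics
with exactly known ground truth; it deliberately omits codon-level evolution,
rate heterogeneity, site-wise missing data and indels. Consequently, passing
tests demonstrate the correctness of the measurement pipeline on clean
informative sites, not robustness to alignment error or compositional bias in
real proteomes.

`sensu_stricto_scenario` instantiates the published yeast-clade study
conditions: 2,647 CAM sites and 100,887 non-CAM sites distributed over the
ten possible five-taxon bipartitions exactly according to the published
support profile (CAM: kb 1,180, cp 937, bm 177, km 141, cb 62, cm 42, pm 42,
bp 29, ck 26, kp 11; non-CAM: 31,791 / 25,625 / 9,520 / 8,756 / 5,008 /
4,934 / 4,817 / 3,623 / 3,736 / 3,077). Because every downstream headline
number (support percentages, mean HI, IC/ICA/TC/TCA, parsimony tree length
(n−m) + 2m) is a deterministic function of this profile, the scenario
recovers them exactly regardless of seed; the seed only varies which residue
pairs realize each site. The scenario builds the two site-set alignments in
about two seconds.

## Numerical and interface conventions

- Bipartitions are canonicalized to their smaller block (ties to the block
  containing the alphabetically first taxon); display names are the sorted
  block members, and inputs accept members in any order.
- All TSV outputs carry full-precision values; rounding to two decimals
  happens only in display paths and never feeds downstream computation.
- Every stochastic function takes an explicit seed or generator; nothing
  touches global RNG state.
- Degenerate inputs: constant columns score HI = 0; an internode with zero
  focal support scores IC = ICA = 0; a support table may be empty; extracting
  a class with no hits yields a zero-length alignment.
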