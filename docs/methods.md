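# Methods

This note documents the models, conventions and numerical choices behind
`brcarray`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Coordinates and containers

All internal coordinates are 0-based with half-open intervals; reports and
the CLI convert to 1-based inclusive at the boundary. Gap characters are
legal only inside alignment rows (`Msa`); an unaligned `BioSequence` rejects
them. Inputs are pre-spliced CDS or protein; exon stitching is out of scope.
Translation uses the standard genetic code (via Biopython's codon table):
one trailing stop is dropped silently, internal stops render as `*` and are
flagged, codons containing `N` give `X`, and a trailing partial codon is
dropped with a warning.

## Repeat model

The BRC motif is modelled as an **ungapped** position-specific log-odds
profile. Column frequencies are `(count + q) / (n_observed + 20 q)` with
pseudocount `q = 0.1` by default (any positive value is accepted; gap
characters are excluded from column counts, and an all-gap column is an
error). Scores are summed per-column log₂(frequency / background) in bits,
with a uniform 1/20 background by default; residues outside the 20-letter
alphabet score 0. An ungapped profile is adequate because the profile's only
job is to *locate* motif cores: the large indel that separates repeat
classes lies in the linker-extended unit, outside the core, so insert/delete
states would buy nothing at this scale.

Tunable parameters:

| parameter | default | meaning |
|---|---|---|
| pseudocount | 0.1 | additive smoothing per column count |
| threshold_fraction | 0.6 | hit threshold as a fraction of the consensus self-score |
| tie_margin | 0.02 | p-distance margin below which class assignment is a tie |
| min_support | 2 | informative characters required per chimera segment |
| min_block | 3 | minimum indel-block width in columns |

The 0.6 threshold separates true units from background comfortably: in
seeded null scans of background-composition proteins the best window scores
far below it, while single units mutated at 5% per site essentially always
clear it. Delineation resolves overlapping hits greedily by descending
score (ties to the leftmost start), then extends unit boundaries from the
cores to the midpoints of inter-hit linkers; the outermost flanks extend by
half the mean inner linker, clipped at the protein ends. Where exactly unit
boundaries should fall beyond the motif core is a convention, not a fact
about the data; the report carries both core and extended coordinates so
downstream users can tell which is which.

Class assignment gives a unit the label of the reference core at minimal
uncorrected p-distance; if the best and runner-up distances differ by less
than the tie margin the unit is `unassigned` and is routed to the chimera
analysis instead of being forced into a class.

## Diagnostic characters and the fixation filter

A column is diagnostic for classes A vs B when (i) the two references
differ there, (ii) the column carries no gap or `X` in any panel row, and
(iii) it is monomorphic for the reference state within *both* class panels.
Columns failing (iii) are reported as `excluded_not_fixed` rather than
silently dropped, since the exclusion itself is informative. Monomorphism
is required symmetrically in both panels (the conservative generalisation
of filtering against one sequenced panel). With empty panels the filter is
vacuous and the set is flagged `reference_only`.

Indel blocks are maximal runs of ≥ `min_block` columns with residues in one
class and gaps in the other, fixed in the panels; each block is **one**
diagnostic character regardless of width (weighting it by its 18 columns
would let alignment length dominate the parsimony). `min_block = 3` guards
against single-column alignment jitter.

## Chimera calling and homoplasy

A query unit in the reference frame becomes an ordered state vector: per
substitution site A/B/other by direct residue comparison; per block,
present/absent by whether at least half its columns carry residues. Because
segments must be homogeneous, the minimal-switch segmentation of the
informative entries is exactly the sequence of maximal same-state runs —
verified against exhaustive enumeration of all cut patterns in the tests.
`other` entries never open or close a segment.

Verdicts: one segment → pure; two or more → chimeric; any segment with
support below `min_support = 2` → ambiguous. The support rule means a
single discordant character — which could equally be a convergent point
change or a small gene-conversion tract — never creates a chimera call on
its own.

Breakpoints are *intervals*, never points: from the column after the left
segment's last informative character through the right segment's first,
half-open. Diagnostic-character spacing limits resolution and the interval
representation makes that explicit. Two chimeric alleles are consistent
with identity-by-descent only when they have the same number of
breakpoints, every interval overlaps its counterpart (overlap, not
equality — IBD alleles share a true breakpoint but not necessarily the same
flanking characters), and indel-block states agree. Anything else is
homoplasy.

## Population genetics

Gap handling defaults to complete deletion (any column with `-` or `N` in
any row is removed before all counting), matching the default of the
standard desktop tools for these statistics; pairwise deletion is available
for π. S counts retained columns with ≥ 2 observed states, with no
minor-allele threshold. Tajima's D uses the exact 1989 constants; D is
undefined (NaN with a reason) when S = 0 or the variance term vanishes, and
is printed to 5 decimals. Published per-species comparison ranges
(*D. yakuba* mean −0.34, range [−1.03, 1.05]; *D. santomea* mean −0.29,
range [−1.27, 1.03], from loci in regions of similarly reduced crossing
over) are stored as constants and classification treats the interval as
closed.

## Phylogenetics

p-distances use pairwise deletion of `-` plus `X` (protein) or `N`
(nucleotide); a pair with zero comparable sites is an error naming the
pair. Neighbor joining is the standard Saitou–Nei agglomeration; two
choices make runs reproducible: Q-ties (within 1e−12) are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf id), and negative branch-length estimates are clamped to
zero with the deficit logged. The final three clusters are joined by the
three-point closed form; the tree is unrooted until `root_with_outgroup`
places the root at the midpoint of the outgroup's pendant edge. Trees are
dendropy objects; Newick IO and Robinson–Foulds comparisons go through
dendropy.

## The simulator

`evolve_on_tree` walks a newick tree from the root, applying per-site
substitutions on each branch with probability `1 − exp(−rate × length)`
(uniform replacement over the 19 alternatives — a Jukes–Cantor-like
simplification chosen for transparency over realism) and then any events
scheduled on that branch, in order. Events are explicit — unequal
crossover, block deletion, unit divergence, relabel — rather than
rate-sampled, so every fixture is exactly reproducible; a seed is
mandatory. Identical configurations produce byte-identical FASTA and truth
JSON.

`unequal_crossover` pairs unit *l* of one array with unit *r* of the other
and recombines at a column breakpoint. The product inheriting the left
array's 5′ flank takes the left unit's columns before the breakpoint and
the right unit's columns after it; the reciprocal swaps the roles. Unit
counts are conserved (|long| + |short| = |left| + |right|); the junction
unit records its breakpoint and contributing classes. The orientation
convention (5′ portion from the 5′-flank chromatid) is fixed arbitrarily
and documented here.

The bundled `expansion_contraction_scenario` encodes the study system's
inferred history: a 3-unit ancestral array (classes diverged ~18% from a
common base), an expansion pairing unit 3 with unit 1 (junction class 3|1),
relabelling to classes 1–5, an 18-column block deletion in the duplicated
class-4 unit plus ~17% divergence from its class-2 sibling with guaranteed
differences at nine columns flanking the block, and two independent 5→3
contractions pairing unit 4 with unit 2 at distinct breakpoints (one 3′ of
the block, one near the 5′ end). Unit frames are 73 columns: 10-column 5′
tail, 35-column motif core, 18-column block region, 10-column 3′ tail;
linkers are 20 residues; terminal branches accumulate ~1% substitutions.
These values are the scenario's study conditions and are not adjusted per
run.

What the generator does **not** emulate: intragenic gene conversion (which
can mimic chimeric patterns and is deliberately excluded — the crossover
model is the only generator of chimeras here), selection, insertion/deletion
noise other than the planted block, alignment error (simulated units share
an exact frame; real data must be aligned first and projection of real
units into the reference frame uses a local pairwise alignment), diploidy,
and recombination within the coalescent. Passing tests on simulated data
therefore demonstrate correctness of the inference machinery under the
crossover model, not robustness to conversion-driven homoplasy or to
alignment artefacts in real sequence.

The coalescent sampler is the classic n-lineage process: exponential
waiting times at rate C(k,2) (time in 2N units), Poisson(θ/2 × branch
length) infinite-sites mutations, binary states emitted as A/T. It exists
to give the site-frequency statistics a null with known expectations
(E[S] = θ·a₁, E[D] ≈ 0).

## Validation problem sizes

The test suite and acceptance script validate: Tajima's D against a direct
independent formula evaluation on 50 random alignments (n = 4–12, agreement
to 1e−10); the neutral null at n = 10, θ = 5 with 10,000 replicates (mean S
within 2% of θ·a₁, mean D within 0.1 of zero); exact NJ recovery (RF = 0,
path lengths to 1e−9) of 100 random additive trees with 5–10 leaves;
segmentation against brute-force enumeration on 1,000 random state vectors
of length ≤ 12; and breakpoint-interval recovery on 1,000 simulated
contractions at 2% per-site noise with at least two informative characters
per true segment (observed recovery ≈ 99%, against a 95% requirement).
These sizes were chosen to give stable Monte-Carlo estimates at desk scale.

## Known limitations

* Real sequence data must arrive aligned (or alignable by the built-in
  pairwise projection); there is no multiple-alignment step.
* The profile has no insert/delete states and no E-value calibration;
  the hit threshold is a fraction of the consensus self-score, not a
  statistical significance level.
* Chimera calls carry no significance test (no permutation analysis à la
  recombination-detection software); `min_support` is a heuristic guard.
* The homoplasy test is conservative by construction: an `ambiguous` call
  (any segment with a single supporting character) is never compared, so
  borderline alleles yield no verdict rather than a wrong one.
* With the published genome and strain sequences as input, the pipeline
  reproduces the study-scale analyses (5- vs 3-repeat delineation, the
  Dya2/Dya4 diagnostics, per-species D); those sequences are not bundled,
  so the packaged validation rests on the simulator's ground truth.
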