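# brcarray

Tools for studying the evolution of tandem **BRC-repeat arrays** — the
~35-amino-acid RAD51-binding motifs of *BRCA2* homologs — in the *Drosophila
melanogaster* species group, where the *D. yakuba* homolog (*dmbrca2*)
carries an expanded five-repeat array while most relatives, and some
*D. yakuba* / *D. santomea* strains, carry three.

The package is written for molecular-evolution researchers who want to ask,
from sequence alone: how many repeat units does each allele carry, which
repeat class does each unit belong to, is a unit a **chimera** (the junction
footprint of unequal crossing over), did two contracted alleles arise once or
independently (**homoplasy**), and is the site-frequency spectrum of the
locus consistent with neutrality?

## What it computes

* **Repeat delineation** — an ungapped position-specific log-odds profile
  over the motif columns scores every window of a protein; non-overlapping
  hits are resolved greedily by score, extended to linker midpoints, and
  numbered 1..k from the 5′ end.
* **Diagnostic sites** — alignment columns where two repeat-class references
  differ *and* are fixed within per-class strain panels (the fixation
  filter); a contiguous run gapped in exactly one class is an indel block,
  treated as a single diagnostic character.
* **Chimera calls** — each query unit becomes a vector of A/B/other states
  over the diagnostic characters; the minimal-switch segmentation of the
  informative states yields a verdict (`pure_A`, `pure_B`, `chimeric`,
  `ambiguous`) and breakpoint *intervals* between flanking informative
  characters. Two chimeric alleles are `consistent_with_IBD` only if every
  breakpoint interval overlaps its counterpart and indel-block states agree;
  otherwise they are `homoplasious`.
* **Population genetics** — segregating sites S, nucleotide diversity
  π, Watterson's θ_W = S/(a₁·L), and Tajima's

  D = (π̂ − S/a₁) / √(e₁S + e₂S(S−1)),

  with the standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of
  sample size, plus classification of D against published per-species
  reference ranges.
* **Phylogenetics** — uncorrected p-distances (pairwise deletion) and
  Saitou–Nei neighbor joining, minimising
  Q(i,j) = (r−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k),
  with deterministic tie-breaking, outgroup rooting, and Newick output.
* **Simulation** — a seeded forward simulator evolving a repeat array on a
  species tree with per-site substitutions and scheduled unequal-crossover
  expansions/contractions, emitting ground truth (classes, junction
  breakpoints, event log) for every leaf; plus a neutral coalescent sampler
  (infinite sites) as the popgen null.

## Worked example

Simulate the canonical study system — an ancestral three-unit array expands
to five on the stem lineage, then two descendant lineages independently
contract back to three — and run the full pipeline on the resulting leaf
proteins:

```bash
brcarray simulate --seed 7 --out-dir demo
brcarray pipeline --in demo/leaves.fasta --refs refs.fasta \
    --core-columns 10:45 --out-dir demo/out
```

(`refs.fasta` holds the aligned reference units of a five-repeat strain,
ids ending in the class digit 1..5; the demo's ground-truth file
`demo/truth.json` contains exactly such sequences.)

The report (`demo/out/report.json`) then shows:

```
counts:  long1 5, long2 5, long3 5, shortA 3, shortB 3
chimera: shortA_u2  chimeric  AAAAAAAAAAABBBB  breakpoints [[64, 66]]
         shortB_u2  chimeric  AABBBBBBBBBBBBB  breakpoints [[9, 14]]
homoplasy: shortA_u2 vs shortB_u2 -> homoplasious (same_breakpoint: false)
diagnostics: 14 substitution columns + one 18-column indel block (46-63)
```

Reading it: the three long strains delineate to the full five repeats; both
short strains delineate to three, and their second repeat is chimeric —
class-2-like 5′ of the junction, class-4-like 3′ of it. `shortA_u2` keeps
the 18-residue block and switches state only over the last four diagnostic
characters (1-based breakpoint interval columns 64–66); `shortB_u2` lacks
the block and switches after the second character (columns 9–14). Because
the breakpoint intervals do not overlap and the indel-block states differ,
the two contractions cannot be identical-by-descent: the short form arose
twice. A neighbor-joining tree of all units against the references is
written alongside (`demo/out/tree.nwk`).

The same stages are available as library calls (`brcarray.delineate_array`,
`find_diagnostic_sites`, `call_chimera`, `compare_alleles`, `tajimas_d`,
`neighbor_joining`, …) and as individual subcommands (`delineate`,
`diagnose`, `chimera`, `popgen`, `njtree`).

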