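"""Forward simulation of repeat-array evolution and a neutral coalescent null.

The forward simulator evolves an array of aligned repeat units along a
species tree: per-site substitutions accumulate on each branch (probability
``1 - exp(-rate * branch_length)``, uniform replacement — Jukes-Cantor-like),
and explicitly scheduled unequal-crossing-over events expand or contract the
array. An unequal crossover between misaligned arrays produces one expanded
and one contracted product, both carrying a chimeric junction unit whose 5'
portion comes from the 5'-flank chromatid and whose 3' portion comes from
the other; the junction breakpoint is recorded in the ground truth. Unit
counts are conserved: |long| + |short| = |left| + |right|, always.

Everything is seeded; identical configurations produce byte-identical
output. Events are scheduled, not rate-sampled, so fixtures are exactly
reproducible.

The coalescent sampler is the standard neutral n-lineage process
(exponential waiting times with rate C(k,2), infinite-sites mutations at
Poisson(theta/2 x branch length)) emitted as an A/T alignment — the null
model for the site-frequency statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .repeat_model import AMINO_ACIDS
from .seq_io import BioSequence, Msa, NUCLEOTIDE, PROTEIN


# ---------------------------------------------------------------------------
# point mutation


def mutate(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Independently replace each residue with probability ``p_sub``.

    Replacements are uniform over the 19 alternative amino acids; gap
    characters are never touched.
    """
    if not 0 <= p_sub <= 1:
        raise ValueError("p_sub must lie in [0, 1]")
    out = list(seq)
    for i, ch in enumerate(out):
        if ch == "-":
            continue
        if rng.random() < p_sub:
            alternatives = AMINO_ACIDS.replace(ch, "")
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


# ---------------------------------------------------------------------------
# unequal crossing over


@dataclass(frozen=True)
class Unit:
    """One aligned repeat unit: fixed-width columns, gaps allowed."""

    seq: str
    cls: str
    breakpoint: int | None = None  # junction column if this unit is chimeric
    junction_of: tuple[str, str] | None = None  # (5' class, 3' class)


@dataclass(frozen=True)
class CrossoverTruth:
    left_index: int
    right_index: int
    breakpoint: int
    long_junction: tuple[str, str]  # classes contributing 5', 3' of the long product's junction
    short_junction: tuple[str, str]
    left_parent_seq: str
    right_parent_seq: str


def unequal_crossover(
    array_left: list[Unit],
    array_right: list[Unit],
    left_index: int,
    right_index: int,
    breakpoint: int,
) -> tuple[list[Unit], list[Unit], CrossoverTruth]:
    """Recombine two arrays misaligned so unit ``left_index`` pairs with
    ``right_index`` (1-based), crossing over at ``breakpoint`` columns into
    the paired unit.

    The product inheriting the left array's 5' flank is
    ``left[1..li-1] + junction(left[li][:bp] + right[ri][bp:]) + right[ri+1..]``;
    the reciprocal swaps the roles. ``left_index > right_index`` yields an
    expansion and its reciprocal contraction; equal indices reproduce the
    parental counts (an equal crossover). Returned as (longer, shorter).
    """
    n_l, n_r = len(array_left), len(array_right)
    if not (1 <= left_index <= n_l and 1 <= right_index <= n_r):
        raise ValueError("crossover unit indices out of range")
    ul = array_left[left_index - 1]
    ur = array_right[right_index - 1]
    if len(ul.seq) != len(ur.seq):
        raise ValueError("paired units must share an alignment frame")
    if not 0 < breakpoint < len(ul.seq):
        raise ValueError("breakpoint must fall strictly inside the unit columns")

    junction_a = Unit(
        seq=ul.seq[:breakpoint] + ur.seq[breakpoint:],
        cls=f"{ul.cls}|{ur.cls}",
        breakpoint=breakpoint,
        junction_of=(ul.cls, ur.cls),
    )
    junction_b = Unit(
        seq=ur.seq[:breakpoint] + ul.seq[breakpoint:],
        cls=f"{ur.cls}|{ul.cls}",
        breakpoint=breakpoint,
        junction_of=(ur.cls, ul.cls),
    )
    product_a = list(array_left[: left_index - 1]) + [junction_a] + list(array_right[right_index:])
    product_b = list(array_right[: right_index - 1]) + [junction_b] + list(array_left[left_index:])
    assert len(product_a) + len(product_b) == n_l + n_r
    if len(product_a) >= len(product_b):
        long_, short = product_a, product_b
        long_j, short_j = junction_a.junction_of, junction_b.junction_of
    else:
        long_, short = product_b, product_a
        long_j, short_j = junction_b.junction_of, junction_a.junction_of
    truth = CrossoverTruth(
        left_index, right_index, breakpoint, long_j, short_j, ul.seq, ur.seq
    )
    return long_, short, truth


# ---------------------------------------------------------------------------
# evolution on a tree


@dataclass(frozen=True)
class CrossoverEvent:
    branch: str  # label of the child node the branch leads to
    left_index: int
    right_index: int
    breakpoint: int
    keep: str  # "expanded" | "contracted"


@dataclass(frozen=True)
class BlockDeletionEvent:
    """Delete (gap out) a column run from one unit — plants an indel block."""

    branch: str
    unit_index: int  # 1-based
    start: int
    length: int


@dataclass(frozen=True)
class RelabelEvent:
    """Reassign the positional class labels of the current array."""

    branch: str
    labels: tuple[str, ...]


@dataclass(frozen=True)
class UnitDivergenceEvent:
    """Extra substitutions on one unit — lets a duplicated unit diverge into
    its own class, optionally with guaranteed differences at chosen columns."""

    branch: str
    unit_index: int  # 1-based
    p_sub: float
    forced_columns: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimConfig:
    ancestral_units: tuple[tuple[str, str], ...]  # (class label, aligned seq)
    tree_newick: str  # branch lengths required; internal nodes labelled
    subst_rate: float  # per site per unit branch length
    events: tuple = ()
    linker_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        widths = {len(s) for _, s in self.ancestral_units}
        if len(widths) > 1:
            raise ValueError("ancestral units must share one alignment width")


@dataclass
class LeafTruth:
    name: str
    classes: list[str]
    breakpoints: list[int | None]
    unit_seqs: list[str]  # aligned (gapped) unit sequences


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated leaves."""

    config: SimConfig
    leaves: dict[str, LeafTruth]
    event_log: list[dict]
    root_classes: dict[str, str]  # class label -> ancestral aligned seq
    linker: str

    def diagnostic_columns(self, class_a: str, class_b: str) -> list[int]:
        """Columns where the two ancestral class sequences differ (residue
        vs residue; planted indel columns are excluded)."""
        a = self.root_classes[class_a]
        b = self.root_classes[class_b]
        return [
            j for j, (x, y) in enumerate(zip(a, b)) if x != y and "-" not in (x, y)
        ]

    def homoplasious_leaf_pairs(self) -> list[tuple[str, str]]:
        """Leaf pairs whose contractions were independent events with
        distinct breakpoints — homoplasious short forms."""
        contractions = [
            e for e in self.event_log if e["kind"] == "crossover" and e["keep"] == "contracted"
        ]
        pairs = []
        for i in range(len(contractions)):
            for j in range(i + 1, len(contractions)):
                e1, e2 = contractions[i], contractions[j]
                if e1["branch"] != e2["branch"] and e1["breakpoint"] != e2["breakpoint"]:
                    pairs.append((e1["branch"], e2["branch"]))
        return pairs

    def to_json(self) -> str:
        payload = {
            "seed": self.config.seed,
            "linker": self.linker,
            "root_classes": self.root_classes,
            "event_log": self.event_log,
            "leaves": {
                name: {
                    "classes": lt.classes,
                    "breakpoints": lt.breakpoints,
                    "unit_seqs": lt.unit_seqs,
                }
                for name, lt in self.leaves.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def evolve_on_tree(config: SimConfig) -> tuple[list[BioSequence], SimTruth]:
    """Evolve the ancestral array along the tree, applying scheduled events.

    Returns the leaf proteins (ungapped unit sequences joined by the linker)
    and the full ground truth. Branch substitution probability is
    ``1 - exp(-subst_rate * branch_length)``. Events attached to a branch are
    applied after that branch's substitutions, in their scheduled order.
    """
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree_newick, schema="newick")
    linker = _random_protein(config.linker_length, rng)
    known_branches = {
        (nd.taxon.label if nd.taxon else nd.label)
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    }
    for ev in config.events:
        if ev.branch not in known_branches:
            raise ValueError(f"event references unknown branch {ev.branch!r}")

    by_branch: dict[str, list] = {}
    for ev in config.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    root_array = [Unit(seq=s, cls=c) for c, s in config.ancestral_units]
    event_log: list[dict] = []
    leaves: dict[str, LeafTruth] = {}
    records: list[BioSequence] = []

    def node_name(nd) -> str:
        return nd.taxon.label if nd.taxon else (nd.label or "<unnamed>")

    def descend(nd, array: list[Unit]) -> None:
        if nd.parent_node is not None:
            blen = nd.edge.length or 0.0
            p_sub = 1.0 - math.exp(-config.subst_rate * blen)
            array = [replace(u, seq=mutate(u.seq, p_sub, rng)) for u in array]
            for ev in by_branch.get(node_name(nd), []):
                array = _apply_event(ev, array, event_log, rng)
        if nd.is_leaf():
            name = node_name(nd)
            leaves[name] = LeafTruth(
                name=name,
                classes=[u.cls for u in array],
                breakpoints=[u.breakpoint for u in array],
                unit_seqs=[u.seq for u in array],
            )
            protein = linker.join(u.seq.replace("-", "") for u in array)
            records.append(BioSequence(id=name, residues=protein, alphabet=PROTEIN))
        else:
            for child in nd.child_nodes():
                descend(child, array)

    descend(tree.seed_node, root_array)
    truth = SimTruth(
        config=config,
        leaves=leaves,
        event_log=event_log,
        root_classes={c: s for c, s in config.ancestral_units},
        linker=linker,
    )
    return records, truth


def _apply_event(
    ev, array: list[Unit], log: list[dict], rng: np.random.Generator
) -> list[Unit]:
    if isinstance(ev, CrossoverEvent):
        long_, short, truth = unequal_crossover(
            array, array, ev.left_index, ev.right_index, ev.breakpoint
        )
        kept = long_ if ev.keep == "expanded" else short
        log.append(
            {
                "kind": "crossover",
                "branch": ev.branch,
                "left_index": ev.left_index,
                "right_index": ev.right_index,
                "breakpoint": ev.breakpoint,
                "keep": ev.keep,
                "junction": list(
                    truth.long_junction if ev.keep == "expanded" else truth.short_junction
                ),
                "left_parent_seq": truth.left_parent_seq,
                "right_parent_seq": truth.right_parent_seq,
                "result_classes": [u.cls for u in kept],
            }
        )
        return kept
    if isinstance(ev, BlockDeletionEvent):
        u = array[ev.unit_index - 1]
        s = list(u.seq)
        for c in range(ev.start, ev.start + ev.length):
            s[c] = "-"
        log.append(
            {
                "kind": "block_deletion",
                "branch": ev.branch,
                "unit_index": ev.unit_index,
                "start": ev.start,
                "length": ev.length,
            }
        )
        return array[: ev.unit_index - 1] + [replace(u, seq="".join(s))] + array[ev.unit_index :]
    if isinstance(ev, RelabelEvent):
        if len(ev.labels) != len(array):
            raise ValueError("relabel length must match array length")
        log.append({"kind": "relabel", "branch": ev.branch, "labels": list(ev.labels)})
        return [replace(u, cls=lab) for u, lab in zip(array, ev.labels)]
    if isinstance(ev, UnitDivergenceEvent):
        u = array[ev.unit_index - 1]
        s = list(mutate(u.seq, ev.p_sub, rng))
        for c in ev.forced_columns:
            if s[c] == "-":
                continue
            alternatives = AMINO_ACIDS.replace(u.seq[c], "")
            s[c] = alternatives[rng.integers(len(alternatives))]
        log.append(
            {
                "kind": "unit_divergence",
                "branch": ev.branch,
                "unit_index": ev.unit_index,
                "p_sub": ev.p_sub,
                "forced_columns": list(ev.forced_columns),
            }
        )
        return (
            array[: ev.unit_index - 1] + [replace(u, seq="".join(s))] + array[ev.unit_index :]
        )
    raise TypeError(f"unknown event type {type(ev).__name__}")


# ---------------------------------------------------------------------------
# the expansion/contraction study scenario


# Unit alignment frame used by the study scenario. The motif core sits mid-
# unit so that linker-midpoint delineation recovers the flanking diagnostic
# regions; the indel block lies between the core and the 3' tail.
SCENARIO_UNIT_WIDTH = 73
SCENARIO_CORE = (10, 45)  # profile columns (half-open)
SCENARIO_BLOCK = (45, 18)  # start, length
# columns forced to differ between the duplicated classes 2 and 4: five 5'
# of the block (two before column 12 for the early-breakpoint contraction)
# and four in the 3' tail
SCENARIO_FORCED_DIAGNOSTICS = (3, 7, 20, 30, 40, 65, 67, 69, 71)


def expansion_contraction_scenario(
    seed: int,
    unit_width: int = SCENARIO_UNIT_WIDTH,
    block: tuple[int, int] = SCENARIO_BLOCK,
    interclass_divergence: float = 0.18,
    class24_divergence: float = 0.17,
    subst_rate: float = 0.2,
    expansion_breakpoint: int = 36,
    contraction_breakpoints: tuple[int, int] = (64, 12),
) -> SimConfig:
    """Configuration emulating the study system's inferred history.

    An ancestral 3-unit array expands to 5 units on the stem lineage via an
    unequal crossover pairing unit 3 with unit 1 (the junction unit is
    class-3 at its 5' end, class-1 at its 3' end). The duplicated
    second-class unit (position 4) then loses an 18-residue block and
    diverges ~17% from its class-2 sibling, with guaranteed differences at
    nine columns flanking the block — fixing the class-2 / class-4
    distinction. Two descendant lineages independently contract back to 3
    units via crossovers pairing unit 4 with unit 2 at distinct breakpoints:
    one 3' of the block (junction keeps the block, switching to class 4 over
    the four 3'-tail diagnostics) and one 5' of almost everything (junction
    lacks the block and is class-4-like over most of its length). The short
    forms are therefore homoplasious. Three other lineages retain the
    5-unit form and serve as the strain panel.
    """
    rng = np.random.default_rng(seed)
    base = _random_protein(unit_width, rng)
    classes = []
    for label in ("1", "2", "3"):
        classes.append((label, mutate(base, interclass_divergence, rng)))
    tree = (
        "((long1:0.05,long2:0.05,long3:0.05,shortA:0.05,shortB:0.05)crown:0.05)root;"
    )
    bp1, bp2 = contraction_breakpoints
    block_start, block_length = block
    events = (
        CrossoverEvent(branch="crown", left_index=3, right_index=1,
                       breakpoint=expansion_breakpoint, keep="expanded"),
        RelabelEvent(branch="crown", labels=("1", "2", "3", "4", "5")),
        BlockDeletionEvent(branch="crown", unit_index=4, start=block_start,
                           length=block_length),
        UnitDivergenceEvent(branch="crown", unit_index=4, p_sub=class24_divergence,
                            forced_columns=SCENARIO_FORCED_DIAGNOSTICS),
        CrossoverEvent(branch="shortA", left_index=4, right_index=2,
                       breakpoint=bp1, keep="contracted"),
        CrossoverEvent(branch="shortB", left_index=4, right_index=2,
                       breakpoint=bp2, keep="contracted"),
    )
    return SimConfig(
        ancestral_units=tuple(classes),
        tree_newick=tree,
        subst_rate=subst_rate,
        events=events,
        linker_length=20,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# neutral coalescent null


def coalescent_sample(n_sample: int, theta: float, rng: np.random.Generator) -> Msa:
    """One neutral coalescent sample under the infinite-sites model.

    Waiting times while k lineages remain are exponential with rate C(k,2)
    (time in units of 2N generations); each branch receives
    Poisson(theta/2 x length) mutations, each creating a new segregating
    column with the derived allele ``T`` in the branch's descendants and
    ``A`` elsewhere.
    """
    if n_sample < 2:
        raise ValueError("need at least 2 samples")
    if theta <= 0:
        raise ValueError("theta must be positive")
    lineages = [frozenset([i]) for i in range(n_sample)]
    birth = {ls: 0.0 for ls in lineages}
    branches: list[tuple[frozenset, float]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        merged = a | b
        branches.append((a, t - birth[a]))
        branches.append((b, t - birth[b]))
        lineages = [ls for ls in lineages if ls not in (a, b)] + [merged]
        birth[merged] = t
    columns: list[frozenset] = []
    for carriers, length in branches:
        for _ in range(rng.poisson(theta / 2.0 * length)):
            columns.append(carriers)
    rows = []
    for i in range(n_sample):
        residues = "".join("T" if i in carriers else "A" for carriers in columns)
        rows.append(
            BioSequence(
                id=f"sample_{i + 1}",
                residues=residues,
                alphabet=NUCLEOTIDE,
                aligned=True,
            )
        )
    return Msa(tuple(rows))


# ---------------------------------------------------------------------------
# replicate generator for breakpoint-recovery experiments


@dataclass(frozen=True)
class ContractionReplicate:
    ref_a: str  # class-2-like reference, block present
    ref_b: str  # class-4-like reference, block absent
    panel_a: Msa
    panel_b: Msa
    query: str  # the chimeric junction unit
    true_breakpoint: int


def simulate_contraction_replicate(
    rng: np.random.Generator,
    unit_width: int = 53,
    block_start: int = 35,
    block_length: int = 18,
    n_diag: int = 8,
    p_sub: float = 0.02,
    panel_size: int = 3,
) -> ContractionReplicate:
    """One 5->3 contraction with a planted junction breakpoint.

    Two repeat-class references differ at ``n_diag`` planted substitution
    columns plus an indel block absent from class B. The breakpoint is drawn
    so that at least two planted diagnostic characters flank it on each side
    (the indel block counts as one character on whichever side it falls).
    Panels of ``panel_size`` strains per class and the chimeric query each
    accumulate noise at ``p_sub`` per site.
    """
    core = block_start  # substitution diagnostics live 5' of the block
    base = _random_protein(unit_width, rng)
    diag_cols = sorted(rng.choice(core, size=n_diag, replace=False).tolist())
    ref_a = list(base)
    ref_b = list(base)
    for c in diag_cols:
        alternatives = AMINO_ACIDS.replace(ref_a[c], "")
        ref_b[c] = alternatives[rng.integers(len(alternatives))]
    for c in range(block_start, block_start + block_length):
        ref_b[c] = "-"
    ref_a = "".join(ref_a)
    ref_b = "".join(ref_b)

    # breakpoint with >=2 informative characters per side; the block sits 3'
    # so the 3' side has the block plus any diagnostics past the breakpoint
    lo = diag_cols[1] + 1  # at least 2 substitution sites 5'
    hi = diag_cols[-1]  # leaves >=1 substitution site + block 3'
    if hi <= lo:
        lo, hi = diag_cols[1] + 1, diag_cols[1] + 2
    bp = int(rng.integers(lo, hi + 1))

    def noisy(seq: str) -> str:
        return mutate(seq, p_sub, rng)

    panel_a = Msa(
        tuple(
            BioSequence(f"a{i}", noisy(ref_a), PROTEIN, aligned=True)
            for i in range(1, panel_size + 1)
        )
    )
    panel_b = Msa(
        tuple(
            BioSequence(f"b{i}", noisy(ref_b), PROTEIN, aligned=True)
            for i in range(1, panel_size + 1)
        )
    )
    class2 = [Unit(seq=noisy(ref_a), cls="2")]
    class4 = [Unit(seq=noisy(ref_b), cls="4")]
    # contraction junction: 5' from the class-2 side, 3' from the class-4 side
    product_a, _, _ = unequal_crossover(class2, class4, 1, 1, bp)
    query = noisy(product_a[0].seq)
    return ContractionReplicate(ref_a, ref_b, panel_a, panel_b, query, bp)
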