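"""Chimeric-repeat calling from diagnostic-site state vectors.

A query repeat unit is reduced to an ordered vector of states over the
diagnostic characters of a :class:`~brcarray.diagnostic.DiagnosticSet`: ``A``
when it matches class A's state, ``B`` for class B, ``other`` for anything
else. An indel block contributes exactly one entry (present vs absent decided
by majority of its columns), so a wide indel carries the same parsimony
weight as a single substitution.

The minimal-switch segmentation of the informative (A/B) entries decides the
verdict: one segment is a pure unit, two or more is a chimera — the footprint
of an unequal-crossover junction — and any segment supported by fewer than
``min_support`` informative entries renders the call ambiguous (a lone
discordant site could equally be a convergent point change). Breakpoints are
reported as half-open column intervals between the flanking informative
characters, never as points: diagnostic-site spacing limits resolution.

Two chimeric alleles are consistent with identity-by-descent only when every
breakpoint interval overlaps its counterpart and their indel-block states
agree; otherwise the pair is homoplasious — the same short form arose twice.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostic import DiagnosticSet, DiagnosticSite, IndelBlock

STATE_A = "A"
STATE_B = "B"
STATE_OTHER = "other"


@dataclass(frozen=True)
class SiteState:
    """State of one diagnostic character in a query unit."""

    character: DiagnosticSite | IndelBlock
    state: str  # A | B | other

    @property
    def order_column(self) -> int:
        c = self.character
        return c.column if isinstance(c, DiagnosticSite) else c.start

    @property
    def first_column(self) -> int:
        return self.order_column

    @property
    def last_column(self) -> int:
        c = self.character
        return c.column if isinstance(c, DiagnosticSite) else c.end - 1

    @property
    def is_informative(self) -> bool:
        return self.state in (STATE_A, STATE_B)


@dataclass(frozen=True)
class SiteStateVector:
    source_id: str
    entries: tuple[SiteState, ...]
    dset: DiagnosticSet

    def __post_init__(self) -> None:
        cols = [e.order_column for e in self.entries]
        if cols != sorted(cols):
            raise ValueError("entries must follow alignment-column order")

    @property
    def states(self) -> str:
        """Compact state string, 'o' for uninformative entries."""
        return "".join(e.state if e.is_informative else "o" for e in self.entries)


@dataclass(frozen=True)
class Segment:
    state: str  # A or B
    first_entry: int  # indices into the vector's entry tuple
    last_entry: int
    support: int


@dataclass(frozen=True)
class ChimeraCall:
    source_id: str
    verdict: str  # pure_A | pure_B | chimeric | ambiguous
    segments: tuple[Segment, ...]
    breakpoints: tuple[tuple[int, int], ...]  # half-open alignment-column intervals
    vector: SiteStateVector

    def __post_init__(self) -> None:
        for s1, s2 in zip(self.segments, self.segments[1:]):
            if s1.state == s2.state:
                raise ValueError("adjacent segments must alternate in state")
        if len(self.breakpoints) != max(len(self.segments) - 1, 0):
            raise ValueError("breakpoint count must be segments - 1")

    @property
    def n_switches(self) -> int:
        return len(self.segments) - 1

    def block_states(self) -> tuple[str, ...]:
        """States of the indel-block entries, in column order."""
        return tuple(
            e.state
            for e in self.vector.entries
            if isinstance(e.character, IndelBlock)
        )


@dataclass(frozen=True)
class HomoplasyVerdict:
    allele_pair: tuple[str, str]
    same_breakpoint: bool
    verdict: str  # consistent_with_IBD | homoplasious


def classify_sites(query: str, dset: DiagnosticSet, source_id: str = "query") -> SiteStateVector:
    """State of each diagnostic character in an aligned query unit.

    Substitution sites compare the residue against the two class states; an
    indel block is called present (the residue-bearing class's state) when at
    least half of its columns carry residues, absent otherwise.
    """
    if dset.n_characters == 0:
        raise ValueError("empty DiagnosticSet: nothing to classify against")
    query = query.upper()
    entries: list[SiteState] = []
    for site in dset.sites:
        q = query[site.column]
        if q == site.state_a:
            st = STATE_A
        elif q == site.state_b:
            st = STATE_B
        else:
            st = STATE_OTHER
        entries.append(SiteState(site, st))
    for block in dset.blocks:
        residues = sum(1 for c in range(block.start, block.end) if query[c] != "-")
        present = residues >= block.width / 2
        present_state = STATE_A if block.present_in == "a" else STATE_B
        absent_state = STATE_B if block.present_in == "a" else STATE_A
        entries.append(SiteState(block, present_state if present else absent_state))
    entries.sort(key=lambda e: e.order_column)
    return SiteStateVector(source_id, tuple(entries), dset)


def segment_min_switches(vector: SiteStateVector, min_support: int = 2) -> ChimeraCall:
    """Minimal-switch segmentation of the informative entries.

    Because segments must be homogeneous in state, the unique minimal
    segmentation is the sequence of maximal same-state runs; "other" entries
    are skipped and never open a segment. Each breakpoint interval runs from
    the column after the left segment's final informative character through
    the first informative character of the right segment (half-open).
    """
    informative = [
        (idx, e) for idx, e in enumerate(vector.entries) if e.is_informative
    ]
    if not informative:
        raise ValueError(f"{vector.source_id}: no informative diagnostic states")
    segments: list[Segment] = []
    run_start = 0
    for k in range(1, len(informative) + 1):
        if k == len(informative) or informative[k][1].state != informative[run_start][1].state:
            first_idx = informative[run_start][0]
            last_idx = informative[k - 1][0]
            segments.append(
                Segment(
                    state=informative[run_start][1].state,
                    first_entry=first_idx,
                    last_entry=last_idx,
                    support=k - run_start,
                )
            )
            run_start = k
    breakpoints = []
    for left, right in zip(segments, segments[1:]):
        lo = vector.entries[left.last_entry].last_column + 1
        hi = vector.entries[right.first_entry].first_column + 1
        breakpoints.append((lo, hi))
    if len(segments) == 1:
        verdict = f"pure_{segments[0].state}"
    elif any(s.support < min_support for s in segments):
        verdict = "ambiguous"
    else:
        verdict = "chimeric"
    return ChimeraCall(
        source_id=vector.source_id,
        verdict=verdict,
        segments=tuple(segments),
        breakpoints=tuple(breakpoints),
        vector=vector,
    )


def call_chimera(
    query: str,
    dset: DiagnosticSet,
    source_id: str = "query",
    min_support: int = 2,
) -> ChimeraCall:
    """classify_sites followed by segment_min_switches."""
    return segment_min_switches(classify_sites(query, dset, source_id), min_support)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def compare_alleles(call_1: ChimeraCall, call_2: ChimeraCall) -> HomoplasyVerdict:
    """Identity-by-descent test for two chimeric alleles.

    Consistent with IBD iff the calls have the same number of breakpoints,
    every breakpoint interval of one overlaps its counterpart in the other,
    and the indel-block states agree. Anything else is homoplasy: the two
    contractions happened independently.
    """
    for call in (call_1, call_2):
        if call.verdict != "chimeric":
            raise ValueError(f"{call.source_id}: homoplasy test needs a chimeric call")
    if call_1.vector.dset != call_2.vector.dset:
        raise ValueError("calls were made against different DiagnosticSets")
    same = len(call_1.breakpoints) == len(call_2.breakpoints) and all(
        _overlap(b1, b2) for b1, b2 in zip(call_1.breakpoints, call_2.breakpoints)
    )
    same = same and call_1.block_states() == call_2.block_states()
    return HomoplasyVerdict(
        allele_pair=(call_1.source_id, call_2.source_id),
        same_breakpoint=same,
        verdict="consistent_with_IBD" if same else "homoplasious",
    )
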