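"""Diagnostic alignment columns discriminating two repeat classes.

A column is diagnostic for classes A vs B when the two reference units differ
there AND the column is fixed (monomorphic) for the reference state within
each class's strain panel — the fixation filter. Columns that differ between
references but are polymorphic in a panel are reported separately as
"excluded (not fixed)". A contiguous run of columns present in one class and
gapped in the other is an indel block, treated as a single diagnostic
character regardless of its width.

Columns containing a gap or ``X`` in any panel row are ineligible as
substitution diagnostics (the manual procedure this formalises implies clean
columns); gaps are of course the substance of indel blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import Msa

_UNCLEAN = frozenset("-X")


@dataclass(frozen=True)
class DiagnosticSite:
    column: int  # 0-based alignment column
    state_a: str
    state_b: str
    kind: str = "substitution"

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise ValueError("diagnostic states must differ")


@dataclass(frozen=True)
class IndelBlock:
    """Half-open column run present (residues) in one class, gapped in the other."""

    start: int
    end: int
    present_in: str  # "a" or "b"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty block")
        if self.present_in not in ("a", "b"):
            raise ValueError("present_in must be 'a' or 'b'")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DiagnosticSet:
    class_a: str
    class_b: str
    sites: tuple[DiagnosticSite, ...]
    blocks: tuple[IndelBlock, ...]
    excluded_not_fixed: tuple[int, ...] = ()
    panel_size: int = 0
    reference_only: bool = False  # True when panels were empty (weak diagnosis)

    def __post_init__(self) -> None:
        cols = [s.column for s in self.sites]
        if cols != sorted(cols):
            raise ValueError("sites must be sorted by column")
        for s in self.sites:
            for b in self.blocks:
                if b.start <= s.column < b.end:
                    raise ValueError(f"site {s.column} lies inside block {b.start}:{b.end}")

    @property
    def n_characters(self) -> int:
        return len(self.sites) + len(self.blocks)

    def to_rows(self) -> list[dict]:
        """Report rows with 1-based columns for human consumption."""
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "column": s.column + 1,
                    "state_a": s.state_a,
                    "state_b": s.state_b,
                    "kind": "substitution",
                    "status": "diagnostic",
                }
            )
        for b in self.blocks:
            rows.append(
                {
                    "column": f"{b.start + 1}-{b.end}",
                    "state_a": "present" if b.present_in == "a" else "gap",
                    "state_b": "present" if b.present_in == "b" else "gap",
                    "kind": "indel_block",
                    "status": "diagnostic",
                }
            )
        for c in self.excluded_not_fixed:
            rows.append(
                {
                    "column": c + 1,
                    "state_a": "",
                    "state_b": "",
                    "kind": "substitution",
                    "status": "excluded_not_fixed",
                }
            )
        return rows


def _monomorphic_for(panel: Msa | None, column: int, state: str) -> bool:
    """True when every panel row carries `state` at `column` (vacuously true
    for an empty panel)."""
    if panel is None or panel.n_rows == 0:
        return True
    return all(r.residues[column] == state for r in panel.rows)


def _column_clean(panel: Msa | None, column: int) -> bool:
    if panel is None or panel.n_rows == 0:
        return True
    return not any(r.residues[column] in _UNCLEAN for r in panel.rows)


def find_indel_blocks(
    ref_a: str,
    ref_b: str,
    panel_a: Msa | None = None,
    panel_b: Msa | None = None,
    min_block: int = 3,
) -> tuple[IndelBlock, ...]:
    """Maximal runs of >= `min_block` columns gapped in exactly one class.

    A run only qualifies when the presence/absence pattern is fixed in both
    panels (every panel row of the residue-bearing class has residues across
    the run; every row of the gapped class is gapped).
    """
    if len(ref_a) != len(ref_b):
        raise ValueError("references must share one alignment frame")
    blocks: list[IndelBlock] = []
    j = 0
    L = len(ref_a)
    while j < L:
        if ref_a[j] != "-" and ref_b[j] == "-":
            orient = "a"
        elif ref_a[j] == "-" and ref_b[j] != "-":
            orient = "b"
        else:
            j += 1
            continue
        start = j
        while j < L and (
            (ref_a[j] != "-" and ref_b[j] == "-")
            if orient == "a"
            else (ref_a[j] == "-" and ref_b[j] != "-")
        ):
            j += 1
        if j - start >= min_block:
            present_panel = panel_a if orient == "a" else panel_b
            gap_panel = panel_b if orient == "a" else panel_a
            fixed = True
            for c in range(start, j):
                if present_panel is not None and present_panel.n_rows:
                    fixed &= all(r.residues[c] != "-" for r in present_panel.rows)
                if gap_panel is not None and gap_panel.n_rows:
                    fixed &= all(r.residues[c] == "-" for r in gap_panel.rows)
            if fixed:
                blocks.append(IndelBlock(start, j, orient))
    return tuple(blocks)


def find_diagnostic_sites(
    ref_a: str,
    ref_b: str,
    panel_a: Msa | None = None,
    panel_b: Msa | None = None,
    class_a: str = "A",
    class_b: str = "B",
    min_block: int = 3,
) -> DiagnosticSet:
    """Diagnostic substitution columns plus indel blocks for classes A vs B.

    With empty panels the fixation filter is vacuous and the set is flagged
    ``reference_only`` (a prominent warning to downstream consumers).
    """
    ref_a = ref_a.upper()
    ref_b = ref_b.upper()
    if len(ref_a) != len(ref_b):
        raise ValueError("references must share one alignment frame")
    for panel, ref in ((panel_a, ref_a), (panel_b, ref_b)):
        if panel is not None and panel.n_rows and panel.n_columns != len(ref):
            raise ValueError("panel alignment frame does not match references")

    blocks = find_indel_blocks(ref_a, ref_b, panel_a, panel_b, min_block)
    in_block = set()
    for b in blocks:
        in_block.update(range(b.start, b.end))

    sites: list[DiagnosticSite] = []
    excluded: list[int] = []
    for j, (x, y) in enumerate(zip(ref_a, ref_b)):
        if j in in_block or x == y:
            continue
        if x in _UNCLEAN or y in _UNCLEAN or "-" in (x, y):
            continue  # sub-threshold indel or ambiguity: not a clean substitution column
        if not (_column_clean(panel_a, j) and _column_clean(panel_b, j)):
            excluded.append(j)
            continue
        if _monomorphic_for(panel_a, j, x) and _monomorphic_for(panel_b, j, y):
            sites.append(DiagnosticSite(j, x, y))
        else:
            excluded.append(j)

    panel_size = (panel_a.n_rows if panel_a else 0) + (panel_b.n_rows if panel_b else 0)
    return DiagnosticSet(
        class_a=class_a,
        class_b=class_b,
        sites=tuple(sites),
        blocks=blocks,
        excluded_not_fixed=tuple(excluded),
        panel_size=panel_size,
        reference_only=panel_size == 0,
    )
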