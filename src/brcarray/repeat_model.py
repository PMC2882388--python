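"""BRC-motif profile scanning and repeat-array delineation.

The RAD51-binding BRC motif is modelled as an ungapped position-specific
log-odds profile over a fixed number of columns (35 by default, the width of
the canonical motif model). An ungapped profile suffices here because it is
used only to locate motif cores; the large indel separating repeat classes
lies in the linker-extended unit, outside the core.

Scanning scores every window of a protein as the summed per-column log-odds
(bits) of its residues against a background composition; windows at or above
the score threshold are motif hits. Delineation resolves overlaps greedily by
descending score, extends unit boundaries from the cores to the midpoints of
the inter-hit linkers, and numbers the units 1..k from the amino (5') end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import BioSequence, Msa

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_THRESHOLD_FRACTION = 0.6  # of the consensus self-score
CLASS_TIE_MARGIN = 0.02  # p-distance margin below which assignment is a tie


@dataclass(frozen=True)
class RepeatProfile:
    """Ungapped position-specific scoring profile for the repeat motif."""

    col_freqs: np.ndarray  # (length, 20), rows sum to 1
    background: np.ndarray  # (20,), sums to 1
    score_threshold: float

    def __post_init__(self) -> None:
        cf = np.asarray(self.col_freqs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "col_freqs", cf)
        object.__setattr__(self, "background", bg)
        if cf.ndim != 2 or cf.shape[1] != 20 or cf.shape[0] < 1:
            raise ValueError("col_freqs must be (length, 20) with length >= 1")
        if not np.allclose(cf.sum(axis=1), 1.0):
            raise ValueError("column frequencies must sum to 1")
        if not np.isfinite(self.score_threshold):
            raise ValueError("threshold must be finite")

    @property
    def length(self) -> int:
        return self.col_freqs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.col_freqs / self.background)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))

    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        """Summed log-odds in bits; residues outside the 20-letter alphabet
        (X, gaps) score 0."""
        lo = self.log_odds
        total = 0.0
        for j, aa in enumerate(window):
            i = _AA_INDEX.get(aa)
            if i is not None:
                total += lo[j, i]
        return float(total)

    def to_tsv(self) -> str:
        lines = ["column\t" + "\t".join(AMINO_ACIDS)]
        for j, row in enumerate(self.col_freqs, start=1):
            lines.append(str(j) + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def build_profile(
    instances: Msa,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> RepeatProfile:
    """Profile from aligned motif instances.

    Per column, frequency of amino acid ``a`` is
    ``(count_a + pseudocount) / (n_observed + 20 * pseudocount)`` where
    ``n_observed`` excludes gap rows. Needs at least two instances; a column
    of all gaps is an error. The default threshold is a fixed fraction of the
    consensus self-score.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if instances.n_rows < 2:
        raise ValueError("need at least 2 motif instances")
    L = instances.n_columns
    counts = np.zeros((L, 20))
    for row in instances.rows:
        for j, aa in enumerate(row.residues):
            i = _AA_INDEX.get(aa)
            if i is not None:
                counts[j, i] += 1
    n_obs = counts.sum(axis=1)
    if (n_obs == 0).any():
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"column {bad} contains only gaps/ambiguities")
    freqs = (counts + pseudocount) / (n_obs[:, None] + 20 * pseudocount)
    bg = np.full(20, 0.05) if background is None else np.asarray(background, float)
    prof = RepeatProfile(freqs, bg, score_threshold=0.0)
    return replace(prof, score_threshold=threshold_fraction * prof.consensus_score())


@dataclass(frozen=True)
class MotifHit:
    start: int  # half-open protein coordinates of the profile-length core
    end: int
    score: float


def scan_sequence(protein: BioSequence | str, profile: RepeatProfile) -> list[MotifHit]:
    """All windows scoring at or above the profile threshold, sorted by start."""
    seq = protein.residues if isinstance(protein, BioSequence) else protein
    L = profile.length
    if len(seq) < L:
        warnings.warn("protein shorter than profile; no windows scanned", stacklevel=2)
        return []
    hits = []
    for s in range(len(seq) - L + 1):
        score = profile.score_window(seq[s : s + L])
        if score >= profile.score_threshold:
            hits.append(MotifHit(s, s + L, score))
    return hits


@dataclass(frozen=True)
class RepeatUnit:
    seq_id: str
    start: int  # half-open protein coordinates of the full (linker-extended) unit
    end: int
    core_start: int
    core_end: int
    score: float
    index: int  # 1-based ordinal from the 5' end
    residues: str
    class_label: str | None = None  # "1".."5", "chimeric", "unassigned"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("unit start must precede end")

    @property
    def core_residues(self) -> str:
        return self.residues[self.core_start - self.start : self.core_end - self.start]


@dataclass(frozen=True)
class RepeatArray:
    seq_id: str
    units: tuple[RepeatUnit, ...]

    def __post_init__(self) -> None:
        for u1, u2 in zip(self.units, self.units[1:]):
            if u1.end > u2.start:
                raise ValueError("units must be non-overlapping and sorted")
        for k, u in enumerate(self.units, start=1):
            if u.index != k:
                raise ValueError("unit indices must run 1..k in order")

    @property
    def count(self) -> int:
        return len(self.units)


def delineate_array(protein: BioSequence, profile: RepeatProfile) -> RepeatArray:
    """Non-overlapping motif hits resolved greedily, extended to linker midpoints.

    Hits are accepted in order of descending score (ties by leftmost start);
    an accepted hit rejects any later hit overlapping its core. Unit
    boundaries then grow from each core to the midpoint of the linker to the
    neighbouring core; the outermost flanks extend by half the mean inner
    linker, clipped at the protein ends. Zero hits yield a valid empty array.
    """
    hits = scan_sequence(protein, profile)
    chosen: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start)):
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    if not chosen:
        return RepeatArray(protein.id, ())

    linkers = [b.start - a.end for a, b in zip(chosen, chosen[1:])]
    flank = round(sum(linkers) / len(linkers) / 2) if linkers else 0
    units = []
    for k, h in enumerate(chosen):
        if k == 0:
            start = max(0, h.start - flank)
        else:
            start = (chosen[k - 1].end + h.start) // 2
        if k == len(chosen) - 1:
            end = min(len(protein.residues), h.end + flank)
        else:
            end = (h.end + chosen[k + 1].start) // 2
        units.append(
            RepeatUnit(
                seq_id=protein.id,
                start=start,
                end=end,
                core_start=h.start,
                core_end=h.end,
                score=h.score,
                index=k + 1,
                residues=protein.residues[start:end],
            )
        )
    return RepeatArray(protein.id, tuple(units))


def _core_p_distance(a: str, b: str) -> float:
    used = diffs = 0
    for x, y in zip(a, b):
        if x in "-X" or y in "-X":
            continue
        used += 1
        diffs += x != y
    if used == 0:
        raise ValueError("no comparable positions between unit and reference")
    return diffs / used


def assign_repeat_class(
    unit: RepeatUnit,
    references: list[tuple[str, str]],
    tie_margin: float = CLASS_TIE_MARGIN,
) -> str:
    """Label of the reference core at minimal uncorrected p-distance.

    ``references`` are (label, core_residues) pairs in the profile frame.
    When the best and runner-up distances differ by less than ``tie_margin``
    the unit is ``"unassigned"`` and belongs in the chimera analysis.
    """
    if not references:
        raise ValueError("no reference units supplied")
    scored = sorted(
        (( _core_p_distance(unit.core_residues, core), label) for label, core in references),
    )
    if len(scored) > 1 and scored[1][0] - scored[0][0] < tie_margin:
        return "unassigned"
    return scored[0][1]


_aligner = Align.PairwiseAligner()
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
# affine penalties kept mild so a biological multi-residue deletion (the
# class-distinguishing block) is preferred over mis-stacking linker residues
_aligner.open_gap_score = -10
_aligner.extend_gap_score = -0.5
# local mode soft-clips flanking linker residues instead of forcing them
# into deleted regions of the reference frame
_aligner.mode = "local"


def project_onto_frame(query: str, frame_seq: str) -> str:
    """Render a query unit in a reference alignment frame.

    ``frame_seq`` is the aligned reference (may contain gaps) defining the
    column frame; the query is locally aligned to the reference's ungapped
    residues and its characters are placed in the corresponding frame
    columns. Columns the query lacks become gaps; query residues outside the
    aligned region (e.g. linker flanks) are dropped, as are insertions
    relative to the reference (the frame has no columns for them).
    """
    ref = frame_seq.replace("-", "")
    if not ref:
        raise ValueError("empty reference frame")
    aln = _aligner.align(ref, query.replace("-", ""))[0]
    per_ref = ["-"] * len(ref)
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for off in range(re_ - rs):
            per_ref[rs + off] = aln.query[qs + off]
    out = []
    i = 0
    for ch in frame_seq:
        if ch == "-":
            out.append("-")
        else:
            out.append(per_ref[i])
            i += 1
    return "".join(out)
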