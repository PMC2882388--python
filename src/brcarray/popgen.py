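"""Site-frequency statistics: segregating sites, pi, Watterson's theta, Tajima's D.

All quantities are computed from first principles on a nucleotide alignment.
Gap handling defaults to complete deletion: any column containing a gap or an
``N`` in any row is removed before counting (configurable to pairwise
deletion for the diversity estimate). Tajima's D uses the standard 1989
normalisation:

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1))

with the constants a1, a2, b1, b2, c1, c2, e1, e2 functions of the sample
size n only. D is undefined when S = 0 (reported as NaN with a reason).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .seq_io import Msa

_MISSING = frozenset("-N")


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Sample-size constants of the D statistic (n >= 2)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass(frozen=True)
class PopGenSummary:
    """Summary statistics for one alignment.

    ``tajima_d`` is NaN when undefined; ``d_undefined_reason`` then says why.
    """

    n: int
    sites_used: int
    S: int
    pi: float
    theta_w: float
    tajima_d: float
    constants: TajimaConstants
    d_undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sites_used": self.sites_used,
            "S": self.S,
            "pi": self.pi,
            "theta_w": self.theta_w,
            "tajima_d": None if math.isnan(self.tajima_d) else round(self.tajima_d, 5),
            "d_undefined_reason": self.d_undefined_reason,
        }


def _retained_columns(msa: Msa) -> list[int]:
    return [
        j for j in range(msa.n_columns) if not (_MISSING & set(msa.column(j)))
    ]


def segregating_sites(msa: Msa) -> tuple[int, int]:
    """(S, sites_used) under complete deletion of gap/N columns."""
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    cols = _retained_columns(msa)
    S = sum(1 for j in cols if len(set(msa.column(j))) >= 2)
    return S, len(cols)


def nucleotide_diversity(msa: Msa, deletion: str = "complete") -> float:
    """Mean pairwise differences per site (pi).

    ``deletion="complete"`` removes gap/N columns once for all pairs;
    ``"pairwise"`` removes them per pair.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    if deletion not in ("complete", "pairwise"):
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    total = 0.0
    npairs = 0
    if deletion == "complete":
        cols = _retained_columns(msa)
        if not cols:
            return 0.0
        for r1, r2 in combinations(msa.rows, 2):
            diffs = sum(1 for j in cols if r1.residues[j] != r2.residues[j])
            total += diffs / len(cols)
            npairs += 1
    else:
        for r1, r2 in combinations(msa.rows, 2):
            used = diffs = 0
            for x, y in zip(r1.residues, r2.residues):
                if x in _MISSING or y in _MISSING:
                    continue
                used += 1
                diffs += x != y
            if used == 0:
                raise ValueError(f"no comparable sites between {r1.id} and {r2.id}")
            total += diffs / used
            npairs += 1
    return total / npairs


def tajimas_d(msa: Msa) -> PopGenSummary:
    """Full summary including Tajima's D (NaN with reason when undefined)."""
    n = msa.n_rows
    S, sites_used = segregating_sites(msa)
    pi = nucleotide_diversity(msa, deletion="complete")
    const = tajima_constants(n)
    theta_w = S / (const.a1 * sites_used) if sites_used else 0.0
    reason = None
    if S == 0:
        d = float("nan")
        reason = "no segregating sites"
    else:
        var = const.e1 * S + const.e2 * S * (S - 1)
        if var <= 0:
            d = float("nan")
            reason = "zero variance term"
        else:
            pi_total = pi * sites_used
            d = (pi_total - S / const.a1) / math.sqrt(var)
    return PopGenSummary(n, sites_used, S, pi, theta_w, d, const, reason)


@dataclass(frozen=True)
class ReferenceRange:
    """A published Tajima's-D range for comparable loci in one species."""

    species: str
    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.mean <= self.high:
            raise ValueError("require low <= mean <= high")


# Published Tajima's D for D. yakuba / D. santomea loci in regions of reduced
# crossing over (Llopart et al.), used as the neutrality yardstick.
YAKUBA_RANGE = ReferenceRange("D. yakuba", mean=-0.34, low=-1.03, high=1.05)
SANTOMEA_RANGE = ReferenceRange("D. santomea", mean=-0.29, low=-1.27, high=1.03)


def compare_to_reference(d: float, ref: ReferenceRange) -> str:
    """Classify a D value against a closed published interval.

    Returns ``"within"``, ``"below"`` or ``"above"``.
    """
    if math.isnan(d):
        raise ValueError("cannot classify an undefined D")
    if d < ref.low:
        return "below"
    if d > ref.high:
        return "above"
    return "within"
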