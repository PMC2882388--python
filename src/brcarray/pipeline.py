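"""End-to-end orchestration: delineate -> classify -> diagnose -> chimera ->
homoplasy -> popgen -> NJ tree, with a machine-readable report.

Inputs are strain proteins (FASTA), an aligned reference-unit alignment whose
row ids end in the class digit (e.g. ``Dya1`` .. ``Dya5``), and optionally a
nucleotide strain alignment for the site-frequency statistics. The reference
alignment frame carries the indel block distinguishing the two focal classes;
the profile is built from a configurable core column range of that frame.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

from . import __version__
from .chimera import ChimeraCall, call_chimera, compare_alleles
from .diagnostic import DiagnosticSet, find_diagnostic_sites
from .phylo import neighbor_joining, p_distance_matrix, root_with_outgroup, write_newick
from .popgen import SANTOMEA_RANGE, YAKUBA_RANGE, compare_to_reference, tajimas_d
from .repeat_model import (
    RepeatArray,
    assign_repeat_class,
    build_profile,
    delineate_array,
    project_onto_frame,
)
from .seq_io import BioSequence, Msa, PROTEIN

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    focal_classes: tuple[str, str] = ("2", "4")
    core_columns: tuple[int, int] = (0, 35)  # half-open columns of the ref frame
    pseudocount: float = 0.1
    threshold_fraction: float = 0.6
    min_support: int = 2
    tie_margin: float = 0.02
    min_block: int = 3
    outgroup: str | None = None

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    schema_version: int
    config_digest: str
    version: str
    strains: dict  # per-strain unit counts, classes, coordinates
    diagnostics: list[dict]
    chimera_calls: list[dict]
    homoplasy: list[dict]
    popgen: dict | None
    newick: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _ref_class(label: str) -> str:
    return label[-1]


def _unit_record(u) -> dict:
    # report coordinates are 1-based inclusive
    return {
        "index": u.index,
        "start": u.start + 1,
        "end": u.end,
        "core_start": u.core_start + 1,
        "core_end": u.core_end,
        "score": round(u.score, 3),
        "class": u.class_label,
    }


def run_pipeline(
    strains: list[BioSequence],
    references: Msa,
    config: PipelineConfig = PipelineConfig(),
    nucleotide_msa: Msa | None = None,
) -> PipelineReport:
    """Run every analysis stage and assemble the report.

    ``references`` must contain rows for classes 1..5 (ids ending in the
    class digit); the two focal classes drive the diagnostic/chimera stages.
    """
    if not strains:
        raise ValueError("no strain sequences supplied")
    ref_by_class = {_ref_class(r.id): r for r in references.rows}
    ca, cb = config.focal_classes
    for c in (ca, cb):
        if c not in ref_by_class:
            raise ValueError(f"references lack a class-{c} row")

    s, e = config.core_columns
    core_rows = tuple(
        BioSequence(r.id, r.residues[s:e], PROTEIN, aligned=True) for r in references.rows
    )
    profile = build_profile(
        Msa(core_rows),
        pseudocount=config.pseudocount,
        threshold_fraction=config.threshold_fraction,
    )
    ref_cores = [(_ref_class(r.id), r.residues[s:e]) for r in references.rows]

    arrays: dict[str, RepeatArray] = {}
    strain_report: dict[str, dict] = {}
    for prot in strains:
        arr = delineate_array(prot, profile)
        labelled = []
        for u in arr.units:
            label = assign_repeat_class(u, ref_cores, tie_margin=config.tie_margin)
            labelled.append(replace(u, class_label=label))
        arr = RepeatArray(arr.seq_id, tuple(labelled))
        arrays[prot.id] = arr
        strain_report[prot.id] = {
            "count": arr.count,
            "units": [_unit_record(u) for u in arr.units],
        }

    ref_a = ref_by_class[ca].residues
    ref_b = ref_by_class[cb].residues
    max_count = max(a.count for a in arrays.values())
    panel_a_rows, panel_b_rows = [], []
    for sid, arr in arrays.items():
        if arr.count != max_count:
            continue
        for u in arr.units:
            if u.class_label == ca:
                panel_a_rows.append(
                    BioSequence(f"{sid}_u{u.index}", project_onto_frame(u.residues, ref_a),
                                PROTEIN, aligned=True)
                )
            elif u.class_label == cb:
                panel_b_rows.append(
                    BioSequence(f"{sid}_u{u.index}", project_onto_frame(u.residues, ref_b),
                                PROTEIN, aligned=True)
                )
    dset = find_diagnostic_sites(
        ref_a,
        ref_b,
        Msa(tuple(panel_a_rows)) if panel_a_rows else None,
        Msa(tuple(panel_b_rows)) if panel_b_rows else None,
        class_a=ca,
        class_b=cb,
        min_block=config.min_block,
    )

    calls: list[ChimeraCall] = []
    call_rows: list[dict] = []
    for sid, arr in arrays.items():
        for u in arr.units:
            if not (u.class_label == "unassigned" or (arr.count < max_count and u.class_label in (ca, cb))):
                continue
            framed = project_onto_frame(u.residues, ref_a)
            call = call_chimera(framed, dset, source_id=f"{sid}_u{u.index}",
                                min_support=config.min_support)
            calls.append(call)
            call_rows.append(
                {
                    "unit": call.source_id,
                    "verdict": call.verdict,
                    "states": call.vector.states,
                    "segments": [
                        {"state": sg.state, "support": sg.support} for sg in call.segments
                    ],
                    "breakpoints": [[lo + 1, hi] for lo, hi in call.breakpoints],
                }
            )

    homoplasy_rows = []
    chimeric = [c for c in calls if c.verdict == "chimeric"]
    for i in range(len(chimeric)):
        for j in range(i + 1, len(chimeric)):
            v = compare_alleles(chimeric[i], chimeric[j])
            homoplasy_rows.append(
                {
                    "pair": list(v.allele_pair),
                    "same_breakpoint": v.same_breakpoint,
                    "verdict": v.verdict,
                }
            )

    popgen_report = None
    if nucleotide_msa is not None:
        summary = tajimas_d(nucleotide_msa)
        popgen_report = summary.to_dict()
        if summary.d_undefined_reason is None:
            popgen_report["vs_yakuba_range"] = compare_to_reference(
                summary.tajima_d, YAKUBA_RANGE
            )
            popgen_report["vs_santomea_range"] = compare_to_reference(
                summary.tajima_d, SANTOMEA_RANGE
            )

    tree_rows = list(core_rows)
    for sid, arr in arrays.items():
        for u in arr.units:
            core = project_onto_frame(u.core_residues, ref_a[s:e])
            tree_rows.append(
                BioSequence(f"{sid}_u{u.index}", core, PROTEIN, aligned=True)
            )
    newick = ""
    if len(tree_rows) >= 3:
        tree = neighbor_joining(p_distance_matrix(Msa(tuple(tree_rows))))
        if config.outgroup:
            tree = root_with_outgroup(tree, config.outgroup)
        newick = write_newick(tree)

    return PipelineReport(
        schema_version=REPORT_SCHEMA_VERSION,
        config_digest=config.digest(),
        version=__version__,
        strains=strain_report,
        diagnostics=dset.to_rows(),
        chimera_calls=call_rows,
        homoplasy=homoplasy_rows,
        popgen=popgen_report,
        newick=newick,
    )
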