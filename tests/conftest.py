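import pytest

from brcarray.pipeline import PipelineConfig, run_pipeline
from brcarray.seq_io import BioSequence, Msa, PROTEIN
from brcarray.simulate import (
    SCENARIO_CORE,
    evolve_on_tree,
    expansion_contraction_scenario,
)

SCENARIO_SEED = 7


@pytest.fixture(scope="session")
def scenario():
    """Simulated expansion/contraction study system: (records, truth)."""
    config = expansion_contraction_scenario(seed=SCENARIO_SEED)
    return evolve_on_tree(config)


@pytest.fixture(scope="session")
def scenario_refs(scenario):
    """Reference-unit alignment taken from one 5-repeat leaf, classed 1..5."""
    _, truth = scenario
    return Msa(
        tuple(
            BioSequence(f"ref{i + 1}", seq, PROTEIN, aligned=True)
            for i, seq in enumerate(truth.leaves["long1"].unit_seqs)
        )
    )


@pytest.fixture(scope="session")
def scenario_report(scenario, scenario_refs):
    records, _ = scenario
    return run_pipeline(
        records, scenario_refs, PipelineConfig(core_columns=SCENARIO_CORE)
    )
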