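import pytest

from casassay import (
    PamDepletionModel,
    RecognitionModel,
    SimulationPlan,
    default_design,
    extract_pams,
    simulate_pam_library_reads,
)

FIVE_SAMPLES = (
    ("untreated", "untreated"),
    ("nt1", "non_targeting"),
    ("nt2", "non_targeting"),
    ("nt3", "non_targeting"),
    ("targeting", "targeting"),
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def library(design):
    return design.library_spec()


def run_depletion_experiment(
    model: RecognitionModel,
    seed: int,
    reads_per_sample: int,
    library_spec,
    design=None,
    **fit_kwargs,
):
    """Simulate a five-sample experiment and fit the depletion model."""
    plan_kwargs = {} if design is None else {"design": design}
    plan = SimulationPlan(
        model=model,
        reads_per_sample=reads_per_sample,
        samples=FIVE_SAMPLES,
        seed=seed,
        **plan_kwargs,
    )
    sims = simulate_pam_library_reads(plan)
    tables = [
        extract_pams(s.reads, library_spec, sample_id=sid, sample_role=s.sample_role)
        for sid, s in sims.items()
    ]
    return PamDepletionModel(tables, library_spec).fit(**fit_kwargs)
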