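import numpy as np
import pytest

from gep_panel import ExpressionStudy, SimulationSpec, simulate_study, table2_profile


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """6 probes x 8 samples, two groups, two batches, fixed values."""
    rng = np.random.default_rng(42)
    matrix = rng.normal(7.0, 1.0, size=(6, 8))
    return ExpressionStudy(
        matrix=matrix,
        probe_ids=[f"P{i}" for i in range(6)],
        gene_symbols=["G1", "G1", "G2", "G3", "G4", "G5"],
        sample_ids=[f"S{i}" for i in range(8)],
        group=["A"] * 4 + ["B"] * 4,
        batch=["X", "Y"] * 4,
    )


@pytest.fixture(scope="session")
def default_sim():
    """Discovery-sized cohort (19/28/108, sd 0.5) with the 27-gene profile."""
    return simulate_study(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def panel_study(default_sim):
    """The 27 first-probe rows of the default simulated cohort."""
    from gep_panel import subset_probes

    study, _ = default_sim
    probes = [f"{g}.p1" for g in table2_profile().index]
    return subset_probes(study, probes)


def two_class_truth(study) -> np.ndarray:
    """GBM vs DA+AA indicator for a simulated study."""
    return np.array([1 if g == "GBM" else 0 for g in study.group])
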