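import numpy as np
import pytest

from cfpromoter import genome_regions as gr
from cfpromoter import promoter_coverage as pc
from cfpromoter import synthetic_cfdna as sim


@pytest.fixture(scope="session")
def small_genome():
    return sim.simulate_genome(n_genes=50, spacing=5000, seed=11)


@pytest.fixture(scope="session")
def strong_cohort(small_genome):
    """A deep, strong-effect cohort where the planted signal is unmistakable."""
    return sim.simulate_cohort(
        small_genome,
        n_cases=20,
        n_controls=20,
        n_planted=10,
        effect=0.6,
        base_depletion=0.2,
        depth=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def strong_norm(strong_cohort, small_genome):
    regions = gr.regions_from_genome(small_genome)
    coverage = pc.build_coverage_matrix(strong_cohort.fragments, regions)
    return pc.normalize_ptss(coverage)


@pytest.fixture(scope="session")
def strong_labels(strong_cohort, strong_norm):
    return (
        strong_cohort.design.set_index("sample_id")
        .loc[strong_norm.samples, "label"]
        .to_numpy()
    )


def brute_force_auc(scores, labels01) -> float:
    """Pair-counting AUC oracle: ties between a case and a control count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels01 = np.asarray(labels01)
    cases = scores[labels01 == 1]
    controls = scores[labels01 == 0]
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(cases) * len(controls))
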