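import math

import pytest

from evescan.config import RunConfig
from evescan.pipeline import evaluate_recovery, run_scan
from evescan.scoring import ScoringScheme
from evescan.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def clean_scan():
    """A small genome with undegraded plants, scanned end to end."""
    cfg = SimConfig(
        n_scaffolds=6,
        scaffold_len_distribution=(math.log(60_000), 0.2),
        n_plants=12,
        substitution_rate=0.0,
        indel_rate=0.0,
        premature_stop_prob=0.0,
        seed=11,
    )
    data = simulate_dataset(cfg)
    result = run_scan(data.genome, data.viral, data.viral + data.decoys, RunConfig())
    return data, result


@pytest.fixture(scope="session")
def stop_scan():
    """Plants carrying premature stops with probability 0.35, scanned."""
    q = 0.35
    cfg = SimConfig(
        n_scaffolds=10,
        scaffold_len_distribution=(math.log(150_000), 0.1),
        n_plants=100,
        plant_len_aa=(80, 200),
        substitution_rate=0.0,
        indel_rate=0.0,
        premature_stop_prob=q,
        plant_min_separation=1_500,
        seed=12,
    )
    data = simulate_dataset(cfg)
    result = run_scan(data.genome, data.viral, data.viral + data.decoys, RunConfig())
    recovery = evaluate_recovery(result.calls, data.truth)
    return data, result, recovery, q
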