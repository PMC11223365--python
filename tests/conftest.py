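import numpy as np
import pytest

from abostroke.phasing import HAPLOTYPES
from abostroke.simulate import SimConfig, draw_truth, simulate_calls


def haplotype_pairs_from_freqs(freqs, n, seed):
    """Draw per-sample two-locus alt-dosage pairs from haplotype frequencies."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=(n, 2), p=np.asarray(freqs))
    return [
        (HAPLOTYPES[a][0] + HAPLOTYPES[b][0], HAPLOTYPES[a][1] + HAPLOTYPES[b][1])
        for a, b in idx
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample simulated cohort: (config, truth frame, raw calls)."""
    cfg = SimConfig(n_samples=300, seed=42)
    truth = draw_truth(cfg)
    calls = simulate_calls(truth, cfg)
    return cfg, truth, calls
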