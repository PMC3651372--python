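import numpy as np
import pytest

from snpsurv import GenotypeMatrix, SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_survival(rng, n, censor=0.3):
    """Null survival data with roughly the requested censoring fraction."""
    t = rng.exponential(size=n)
    c = rng.exponential(scale=(1.0 - censor) / censor if censor > 0 else np.inf,
                        size=n)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return SurvivalData(times, events)


def random_genotypes(rng, n, m, freqs=(1 / 3, 1 / 3, 1 / 3), prefix="SNP"):
    g = rng.choice(3, size=(n, m), p=list(freqs)).astype(np.int8)
    return GenotypeMatrix(g, [f"S{i}" for i in range(n)],
                          [f"{prefix}{j}" for j in range(m)])


@pytest.fixture
def small_signal_dataset():
    """A compact dataset with six strong prognostic SNPs, for pipeline tests."""
    from snpsurv import SimulationConfig, generate_dataset

    config = SimulationConfig(m=120, n=150, n_prognostic=6, beta=1.2,
                              censoring=0.3, seed=2601)
    geno, surv = generate_dataset(config)
    return config, geno, surv
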