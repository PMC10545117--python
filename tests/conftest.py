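import numpy as np
import pytest

from surfload.pipeline import analyze, bundle_from_simulation
from surfload.simulate import ExpansionConfig, simulate_expansion

N_SURFING_REPLICATES = 20
SURFING_BASE_SEED = 0


def small_config(seed: int = 5, **kw) -> ExpansionConfig:
    """A minutes-scale-down of the default expansion used by module tests."""
    defaults = dict(
        n_demes=4,
        deme_size=60,
        founder_size=6,
        generations_between_founding=15,
        generations_after_last_founding=10,
        burn_in_generations=40,
        n_genes=30,
        codons_per_gene=20,
        sample_per_deme=6,
        seed=seed,
    )
    defaults.update(kw)
    return ExpansionConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_expansion(small_config())


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    return bundle_from_simulation(small_dataset)


@pytest.fixture(scope="session")
def surfing_replicates():
    """Replicates of the default 10-deme serial-founder expansion, each run
    through the full analysis pipeline.  Shared by the allele-surfing and
    recombination-load acceptance tests and by simulation-based property
    tests (one expensive computation, many consumers)."""
    rng = np.random.default_rng(SURFING_BASE_SEED)
    out = []
    for _ in range(N_SURFING_REPLICATES):
        seed = int(rng.integers(2**31 - 1))
        ds = simulate_expansion(ExpansionConfig(seed=seed))
        bundle = bundle_from_simulation(ds)
        res = analyze(bundle, seed=seed)
        out.append(
            {
                "seed": seed,
                "bundle": bundle,
                "metrics": res.metrics.sort_index(),
                "gene_counts_by_pop": res.gene_counts_by_pop,
                "recomb_class": dict(
                    zip([g.gene_id for g in ds.gene_models], ds.genome.recomb_class)
                ),
                "truth_sites": ds.truth_sites,
            }
        )
    return out
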