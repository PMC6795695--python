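import numpy as np
import pytest

from tillcall import CallerConfig, SimConfig, simulate_population, simulate_reference
from tillcall.simulate import sample_names


@pytest.fixture(scope="session")
def small_sim():
    """A compact deep-coverage population shared by caller/reporting tests."""
    cfg = SimConfig(
        n_contigs=10,
        contig_length_bp=2_000,
        n_lines=12,
        mutant_depth_mean=30.0,
        mutation_rate_per_mbp=200.0,  # dense so the small genome has signal
        seed=7,
    )
    rng = np.random.default_rng(cfg.seed)
    reference = simulate_reference(cfg, rng)
    truth = simulate_population(reference, cfg, rng)
    return cfg, reference, truth, rng.bit_generator.state


@pytest.fixture()
def small_caller_cfg():
    return CallerConfig(min_mut_support=3, min_informative_samples=6)


def random_column(rng, samples, contig="ctg000001", pos=1, ref="G",
                  p_alt_spike=0.3, base_depth=10.0):
    """A random pileup column: mostly reference with occasional alt spikes."""
    from tillcall.core_io import ALLELES, PileupColumn

    counts = {}
    ref_idx = 5 if ref == "N" else ALLELES.index(ref)
    for s in samples:
        c = [0, 0, 0, 0, 0, 0]
        depth = int(rng.poisson(base_depth))
        c[ref_idx] = depth
        if rng.random() < p_alt_spike and depth > 0:
            ai = int(rng.integers(0, 5))
            moved = int(rng.integers(0, depth + 1))
            c[ref_idx] -= moved
            c[ai] += moved
        if rng.random() < 0.05:
            c[5] = int(rng.integers(0, 3))
        counts[s] = tuple(c)
    return PileupColumn(contig_id=contig, pos=pos, ref_base=ref, counts=counts)
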