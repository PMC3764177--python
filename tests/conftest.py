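import numpy as np
import pytest

import finescale as fs


@pytest.fixture(scope="session")
def unstructured_plot():
    """120 individuals from one panmictic pool, coordinates random."""
    rng = np.random.default_rng(11)
    g, _ = fs.sample_island_model(1, 120, 0.0, rng=rng)
    return g


@pytest.fixture(scope="session")
def two_pop_theta10():
    """Two subpopulations of 60 at differentiation ~0.10 (planted truth)."""
    rng = np.random.default_rng(3)
    return fs.sample_island_model(2, 60, 0.10, rng=rng)


@pytest.fixture(scope="session")
def three_pop_theta12():
    rng = np.random.default_rng(21)
    return fs.sample_island_model(3, 40, 0.12, rng=rng)


@pytest.fixture(scope="session")
def small_random_genotypes():
    """18 individuals, 2 loci, some missing data; single plot."""
    rng = np.random.default_rng(42)
    geno = rng.integers(1, 5, size=(18, 2, 2))
    miss = rng.random((18, 2)) < 0.15
    geno[miss] = 0
    return fs.GeoGenotypes(ids=[f"i{i}" for i in range(18)], plot=["P"] * 18,
                           x=rng.random(18) * 50, y=rng.random(18) * 50,
                           geno=geno, locus_names=["L1", "L2"])


@pytest.fixture(scope="session")
def fh_like_final_population():
    """One Fh-like scenario replicate evolved to generation 64."""
    s = fs.named_scenarios()["Fh-like"]
    s.seed = 3
    res = fs.run_scenario(s, n_reps=1, keep_snapshots=True)
    return res.snapshots[0], s
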