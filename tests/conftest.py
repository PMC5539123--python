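import numpy as np
import pytest

from sicomp.diallel import DiallelMatrix, GenotypeLabel
from sicomp.simulate import SILocusSpec, SimConfig, simulate_population


def make_matrix(scores, families=None, tag="2013"):
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    families = families or ["F1"] * n
    genos = [GenotypeLabel(f"g{i + 1}", families[i]) for i in range(n)]
    return DiallelMatrix(genos, scores, replicate_tag=tag)


@pytest.fixture
def small_matrix():
    """4x4 diallel, two families, one missing cell, one discordant
    reciprocal pair (g1 x g2: 10 vs 5)."""
    scores = [
        [0, 10, 7, 5],
        [5, 0, 10, 10],
        [7, 10, 0, np.nan],
        [5, 10, 4, 0],
    ]
    return make_matrix(scores, families=["HSF-1", "HSF-1", "HSF-2", "HSF-2"])


def tiny_sim_config(seed, **kw):
    """Down-scaled study: same structure as the default conditions, small
    enough for unit tests."""
    kw.setdefault("n_families", 2)
    kw.setdefault("family_sizes", (5, 5))
    kw.setdefault("n_founders", 8)
    kw.setdefault("burnin_generations", 3)
    kw.setdefault("burnin_size", 20)
    kw.setdefault("markers_per_lg", 25)
    kw.setdefault("n_linkage_groups", 2)
    kw.setdefault(
        "loci",
        (SILocusSpec("S", 1, 20.0, 6), SILocusSpec("Z", 2, 54.0, 6)),
    )
    return SimConfig(seed=seed, **kw)


@pytest.fixture
def tiny_pop():
    return simulate_population(tiny_sim_config(11))
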