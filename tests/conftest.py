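import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bsakit as bk

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_map() -> bk.GeneticMap:
    return bk.GeneticMap.demo()


@pytest.fixture(scope="session")
def demo_experiment(demo_map):
    """One simulated F2 experiment shared by read-only tests."""
    rng = np.random.default_rng(20240601)
    variants = bk.EMSVariantSet.random(demo_map, 300, rng=rng)
    mut = variants.sites[variants.sites["origin"] == "mutant-line"]
    row = mut.iloc[len(mut) // 2]
    causal = bk.CausalLocusSpec(str(row["chrom"]), int(row["pos"]))
    pop = bk.simulate_f2_population(demo_map, variants, causal, 1100, rng)
    wp, mp = bk.build_pools(
        pop, bk.PoolSpec("WP", 200), bk.PoolSpec("MP", 200), rng
    )
    counts = bk.simulate_pool_read_counts(wp, mp, rng)
    return {
        "map": demo_map,
        "variants": variants,
        "causal": causal,
        "pop": pop,
        "wp": wp,
        "mp": mp,
        "counts": counts,
    }


def single_chromosome_setup(
    cm_positions: list[float],
    causal_cm: float,
    *,
    length_cm: float = 100.0,
    length_bp: int = 100_000_000,
):
    """A one-chromosome map with variants at given genetic positions.

    Returns (map, variant set, causal spec); the causal site is included
    at ``causal_cm``. Positions are converted to bp by the linear map.
    """
    gmap = bk.GeneticMap([bk.Chromosome("chrA", length_bp, length_cm)])
    all_cm = sorted(set(cm_positions) | {causal_cm})
    rows = []
    for cm in all_cm:
        bp = max(1, int(round(gmap.cm_to_bp("chrA", cm))))
        rows.append(("chrA", bp, "G", "A", "mutant-line"))
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "origin"]
    )
    variants = bk.EMSVariantSet(sites, ems_bias=0.0)
    causal_bp = max(1, int(round(gmap.cm_to_bp("chrA", causal_cm))))
    return gmap, variants, bk.CausalLocusSpec("chrA", causal_bp)
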