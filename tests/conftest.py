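import logging

import numpy as np
import pandas as pd
import pytest

import methmirnet as mm

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_planted_bundle():
    """A small cohort with 3 planted triplets among decoys (fixed seed)."""
    cfg = mm.SynthConfig(seed=11, n_mirnas=20, n_mrnas=60, n_triplets=3,
                         coverage_mean=50)
    return mm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """A cohort with no planted effects."""
    cfg = mm.SynthConfig(seed=5, n_mirnas=15, n_mrnas=40, n_triplets=0)
    return mm.generate_cohort(cfg)


def make_cpg_table(chrom, positions, m, u, samples=("s1",)):
    """Wide CpG table from per-sample count arrays.

    ``m``/``u`` are dicts sample -> array, or arrays applied to a single
    sample.
    """
    df = pd.DataFrame({
        "chrom": [chrom] * len(positions),
        "pos": list(positions),
        "strand": ["+"] * len(positions),
    })
    if not isinstance(m, dict):
        m = {samples[0]: m}
        u = {samples[0]: u}
    for s in m:
        df[f"m_{s}"] = np.asarray(m[s], dtype=int)
        df[f"u_{s}"] = np.asarray(u[s], dtype=int)
    return df
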