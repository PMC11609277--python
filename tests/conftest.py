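import numpy as np
import pandas as pd
import pytest

from globalmeth import MethylomeConfig, ScreenConfig
from globalmeth import synthetic_data as synth
from globalmeth.methylome import BetaMatrix


def make_beta_matrix(values, arms, replicates=None, chrom="chr1", positions=None):
    """Small BetaMatrix from a (probes × samples) array and per-sample arms."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probes = pd.Index([f"cg{i:05d}" for i in range(n)], name="probe")
    if positions is None:
        positions = np.arange(1, n + 1) * 100
    manifest = pd.DataFrame({"chrom": chrom, "pos": positions}, index=probes)
    if replicates is None:
        counts: dict[str, int] = {}
        replicates = []
        for a in arms:
            counts[a] = counts.get(a, 0) + 1
            replicates.append(counts[a])
    sample_ids = pd.Index(
        [f"{a}_rep{r}" for a, r in zip(arms, replicates)], name="sample"
    )
    samples = pd.DataFrame(
        {"arm": arms, "sgrna": "sgAAVS1", "replicate": replicates}, index=sample_ids
    )
    betas = pd.DataFrame(values, index=probes, columns=sample_ids)
    return BetaMatrix(betas=betas, manifest=manifest, samples=samples)


@pytest.fixture(scope="session")
def small_methylome():
    cfg = MethylomeConfig(n_cpg=3000, seed=11)
    return synth.make_methylome(cfg)


@pytest.fixture(scope="session")
def null_screen():
    return synth.make_screen_counts(ScreenConfig(seed=2))
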