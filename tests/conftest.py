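import numpy as np
import pandas as pd
import pytest

from methylgxe import SimConfig, simulate


def make_manifest(kind: str, rows):
    """rows: list of (id, chrom, pos)."""
    col = "probe_id" if kind == "probe" else "snp_id"
    return pd.DataFrame(rows, columns=[col, "chrom", "pos"])


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by read-only tests (n=200, 4 loci/class)."""
    cfg = SimConfig(
        n_samples=200,
        loci_per_class={c: 4 for c in ("B", "G", "E", "GE_ADD", "GXE")},
        cis_per_locus=6,
        n_exposures=8,
        n_covariates=3,
        seed=11,
    )
    dataset, loci = simulate(cfg)
    return dataset, loci


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
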