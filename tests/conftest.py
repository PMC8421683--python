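import numpy as np
import pandas as pd
import pytest

from phenocorr.sumstats import ColumnMap, SumStatsTable, read_sumstats


def write_table(path, rows, header=("SNP", "A1", "A2", "FREQ", "BETA", "SE"), sep="\t"):
    """Write a small delimited summary-statistics file for tests."""
    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for row in rows:
            fh.write(sep.join(str(v) for v in row) + "\n")
    return path


def make_table(snp_ids, z, eaf=None, a1="A", a2="G", n=1000.0, beta=None, se=None):
    """Build a SumStatsTable directly from arrays."""
    m = len(snp_ids)
    df = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": [a1] * m if isinstance(a1, str) else list(a1),
        "other_allele": [a2] * m if isinstance(a2, str) else list(a2),
        "eaf": np.full(m, np.nan) if eaf is None else np.asarray(eaf, float),
        "beta": np.full(m, np.nan) if beta is None else np.asarray(beta, float),
        "se": np.full(m, np.nan) if se is None else np.asarray(se, float),
        "z": np.asarray(z, float),
        "n": np.full(m, n),
        "p": np.full(m, np.nan),
    })
    return SumStatsTable(df=df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def basic_pair_tables():
    """Two aligned 6-SNP tables with a variety of allele situations."""
    ids = [f"rs{i}" for i in range(6)]
    z1 = [0.5, -1.0, 2.0, 0.3, -0.7, 1.5]
    z2 = [0.4, -0.8, 1.9, 0.2, -0.5, 1.2]
    eaf = [0.01, 0.2, 0.001, 0.4, 0.0003, 0.05]
    t1 = make_table(ids, z1, eaf=eaf)
    t2 = make_table(ids, z2, eaf=eaf)
    return t1, t2
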