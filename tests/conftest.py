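import numpy as np
import pandas as pd
import pytest

from summr.harmonize import HarmonizedInstrumentSet


def build_hset(gamma, sigma_x, Gamma, sigma_y, rsids=None) -> HarmonizedInstrumentSet:
    """Construct a harmonized set directly from effect arrays."""
    gamma = np.asarray(gamma, float)
    J = len(gamma)
    if rsids is None:
        rsids = [f"rs{i + 1}" for i in range(J)]
    table = pd.DataFrame({
        "rsid": rsids,
        "gamma": gamma,
        "sigma_x": np.broadcast_to(np.asarray(sigma_x, float), (J,)).copy(),
        "Gamma": np.asarray(Gamma, float),
        "sigma_y": np.broadcast_to(np.asarray(sigma_y, float), (J,)).copy(),
        "eaf_exposure": 0.3,
        "eaf_outcome": 0.3,
        "palindromic": False,
        "excluded": False,
        "exclusion_reason": "",
    })
    return HarmonizedInstrumentSet(table)


@pytest.fixture
def make_hset():
    return build_hset


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def gwas_file(tmp_path):
    """Write rows (dicts) as a whitespace-delimited GWAS table, return path."""

    def _write(rows, name="study.tsv", columns=None):
        frame = pd.DataFrame(rows)
        if columns:
            frame = frame.rename(columns=columns)
        path = tmp_path / name
        frame.to_csv(path, sep="\t", index=False)
        return path

    return _write
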