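import numpy as np
import pandas as pd
import pytest

from lysdriver.mutations import PositionCounts
from lysdriver.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared across read-only tests."""
    return simulate_all(SimulationConfig(n_proteins=15, n_patients=60, seed=7))


@pytest.fixture
def make_counts():
    """Counts object with given sums (posterior depends on counts via sums)."""

    def _make(sum_mod, k, sum_bg, n_bg, protein_id="P0001"):
        mod = np.zeros(k, dtype=int)
        bg = np.zeros(n_bg, dtype=int)
        if k:
            mod[0] = sum_mod
        if n_bg:
            bg[0] = sum_bg
        return PositionCounts(
            protein_id=protein_id,
            cancer_type="PANCAN",
            mod_counts=mod,
            bg_counts=bg,
            k=k,
            n=k + n_bg,
        )

    return _make


@pytest.fixture
def mutation_tsv(tmp_path):
    """Write a MAF-like TSV and return its path."""

    def _write(rows, columns=None):
        columns = columns or [
            "sample_id",
            "cancer_type",
            "protein_id",
            "position",
            "ref_aa",
            "alt_aa",
            "variant_class",
        ]
        path = tmp_path / "muts.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    return _write
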