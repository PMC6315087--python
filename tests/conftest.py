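import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from xspecies_expr.datamodel import ExpressionMatrix
from xspecies_expr.simulate import SimulationConfig, simulate_dataset, worked_toy_dataset


def make_matrix(values, species=None, tissues=("MAG", "TESTIS"), is_log=False):
    """Small ExpressionMatrix from a 2-D array; columns cycle tissue fastest."""
    values = np.asarray(values, dtype=float)
    n_t, n_s = values.shape
    if species is None:
        n_sp = n_s // len(tissues)
        species = [f"sp{i + 1}" for i in range(n_sp)]
    cols, meta_rows = [], []
    i = 0
    for sp in species:
        for ti in tissues:
            if i >= n_s:
                break
            sid = f"{sp}_{ti}"
            cols.append(sid)
            meta_rows.append((sid, sp, ti, 1))
            i += 1
    ids = [f"g{i + 1}" for i in range(n_t)]
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "species", "tissue", "replicate"])
    return ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=cols), meta.set_index("sample_id"), is_log
    )


@pytest.fixture(scope="session")
def toy():
    return worked_toy_dataset()


@pytest.fixture(scope="session")
def small_sim():
    """500-transcript simulated dataset with all planted structure, seed 1."""
    cfg = SimulationConfig(seed=1, n_transcripts=500)
    return simulate_dataset(cfg)
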