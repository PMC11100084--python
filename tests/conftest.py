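import numpy as np
import pandas as pd
import pytest

from permscreen.data_model import ScreenDataset


def make_dataset(
    counts: np.ndarray,
    grna_of_cell: list[str],
    targeting: dict[str, bool],
    groups: dict[str, str] | None = None,
    targets: dict[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
) -> ScreenDataset:
    """Assemble a ScreenDataset from plain arrays (one gRNA per cell)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    response_ids = [f"g{i}" for i in range(n_genes)]
    assignment = pd.DataFrame({"cell_id": cell_ids, "grna_id": grna_of_cell})
    grna_ids = sorted(targeting)
    table = pd.DataFrame(
        {
            "grna_id": grna_ids,
            "target": [
                (targets or {}).get(g, "non-targeting" if not targeting[g] else g)
                for g in grna_ids
            ],
            "targeting": [targeting[g] for g in grna_ids],
            "grna_group": [(groups or {}).get(g, g) for g in grna_ids],
        }
    ).set_index("grna_id")
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    else:
        covariates = covariates.set_axis(pd.Index(cell_ids, name="cell_id"))
    ds = ScreenDataset(
        counts=counts,
        response_ids=response_ids,
        cell_ids=cell_ids,
        grna_assignment=assignment,
        grna_table=table,
        covariates=covariates,
    )
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_screen(rng):
    """12 genes x 60 cells, 3 NT gRNAs + 2 targeting groups."""
    counts = rng.poisson(2.0, size=(12, 60))
    grnas = ["nt_a"] * 12 + ["nt_b"] * 14 + ["nt_c"] * 10 + ["tg_1"] * 13 + ["tg_2"] * 11
    targeting = {"nt_a": False, "nt_b": False, "nt_c": False, "tg_1": True, "tg_2": True}
    targets = {"tg_1": "g0", "tg_2": "g5"}
    return make_dataset(counts, grnas, targeting, targets=targets)
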