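import warnings

import pytest

import poiarray as pa
from poiarray.spot_qc import filter_hybridization


@pytest.fixture(scope="session")
def default_run():
    """One full-scale synthetic contrast run through qc, normalization and
    differential expression: the shared dataset for recovery checks."""
    cfg = pa.SimulationConfig(seed=11)
    catalog, truth, atlas, hybs = pa.simulate_experiment(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = [filter_hybridization(h)[0] for h in hybs]
        mas = [pa.normalize_hybridization(h) for h in filtered]
        matrix = pa.assemble_matrix(mas, filtered)
        contrast = pa.contrast_result(matrix, n_perm=100, seed=11)
    return {
        "config": cfg,
        "catalog": catalog,
        "truth": truth,
        "atlas": atlas,
        "hybs": hybs,
        "filtered": filtered,
        "ma_tables": mas,
        "matrix": matrix,
        "contrast": contrast,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A fast small simulation for structural tests."""
    cfg = pa.SimulationConfig(n_genes=1200, grid_shape=(35, 35), seed=7)
    catalog, truth, atlas, hybs = pa.simulate_experiment(cfg)
    return {"config": cfg, "catalog": catalog, "truth": truth,
            "atlas": atlas, "hybs": hybs}
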