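import numpy as np
import pytest

from rootatlas.annotate import MarkerSet, annotate_pipeline
from rootatlas.preprocess import normalize, qc_filter
from rootatlas.synthetic import AtlasConfig, generate_atlas, generate_bulk_zones


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic atlas: 8 types, 4 stages, 2000 cells, 1500
    genes, 5 markers/type, marker_log2_effect=2."""
    return AtlasConfig(seed=1)


@pytest.fixture(scope="session")
def default_atlas(default_config):
    return generate_atlas(default_config)


@pytest.fixture(scope="session")
def small_config():
    return AtlasConfig(
        n_genes=300,
        n_cells=400,
        cell_types=("alpha", "beta", "gamma"),
        markers_per_type=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return generate_atlas(small_config)


@pytest.fixture(scope="session")
def annotated_default(default_config, default_atlas):
    """Full pipeline run on the default atlas, shared across tests."""
    cm, truth = default_atlas
    cm_f, _ = qc_filter(cm)
    expr = normalize(cm_f)
    zones = generate_bulk_zones(default_config)
    result = annotate_pipeline(
        expr,
        MarkerSet(default_config.marker_sets()),
        zones=zones.profiles,
        seed=1,
    )
    truth_types = truth.cells["true_type"].reindex(expr.cell_ids)
    truth_stages = truth.cells["true_stage"].reindex(expr.cell_ids)
    return {
        "expr": expr,
        "result": result,
        "truth_types": truth_types,
        "truth_stages": truth_stages,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
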