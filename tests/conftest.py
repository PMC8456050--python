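import numpy as np
import pytest

from pathsynergy import GeneratorConfig, PathwayDB, build_background, make_pathway_db


@pytest.fixture
def tiny_db() -> PathwayDB:
    """Four hand-built pathways over a 12-gene universe."""
    pathways = {
        "PA": {"g01", "g02", "g03"},
        "PB": {"g03", "g04", "g05", "g06"},
        "PC": {"g07", "g08"},
        "PD": {"g09", "g10", "g11", "g12"},
    }
    universe = {f"g{i:02d}" for i in range(1, 13)}
    return PathwayDB(pathways, frozenset(universe))


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(
        n_genes=400, n_pathways=50, pathway_size_range=(10, 18),
        n_compounds=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Shared synthetic pathway DB + background (built once per session)."""
    db = make_pathway_db(small_cfg)
    background = build_background(db, small_cfg.signature_size, n_draws=4000, seed=5)
    return db, background
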