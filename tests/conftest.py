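import numpy as np
import pandas as pd
import pytest

from ednakit.io import ReadCountTable, SampleSheet


def make_table(
    counts: dict[str, list[int]],
    cols: list[str],
    roles: dict[str, str] | None = None,
    water: dict[str, str] | None = None,
    sites: dict[str, str] | None = None,
    habitats: dict[str, str] | None = None,
    season: str = "2016",
) -> ReadCountTable:
    """Small read-count table with a minimal consistent sample sheet.

    By default every column is its own water sample and site with habitat
    ``seagrass``; ``roles`` marks control columns (habitat then empty).
    """
    roles = roles or {}
    water = water or {}
    sites = sites or {}
    habitats = habitats or {}
    rows = []
    for c in cols:
        role = roles.get(c, "sample")
        rows.append(
            {
                "replicate_id": c,
                "water_sample_id": water.get(c, f"ws_{c}"),
                "site_id": sites.get(c, f"site_{c}"),
                "habitat": habitats.get(c, "seagrass" if role == "sample" else ""),
                "season": season,
                "role": role,
            }
        )
    sheet = SampleSheet(pd.DataFrame(rows))
    frame = pd.DataFrame(counts, index=cols).T
    return ReadCountTable(frame, sheet)


@pytest.fixture(scope="session")
def pipeline_run():
    """One moderate synthetic study run through the whole pipeline, shared
    across tests that only inspect (never mutate) the result."""
    from ednakit.synthetic_data import SimulationConfig
    from ednakit.workflow import run_synthetic_pipeline

    cfg = SimulationConfig(
        n_species_pool=60, n_habitats=4, n_sites_per_habitat=3, seed=11
    )
    result, study = run_synthetic_pipeline(cfg)
    return cfg, result, study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
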