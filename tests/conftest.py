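from pathlib import Path

import pandas as pd
import pytest

import evatcrop as ec

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def site() -> ec.SiteMeta:
    """Sub-tropical plains site used throughout (26.38 °N, 80 m a.s.l.)."""
    return ec.SiteMeta(name="berubari", latitude=26.38, elevation=80.0)


@pytest.fixture(scope="session")
def synthetic_decade(site) -> ec.WeatherSeries:
    """Ten seeded synthetic years with all five variables."""
    return ec.generate_synthetic_weather(3650, site, seed=42)


@pytest.fixture(scope="session")
def fao56_oracle() -> pd.DataFrame:
    """Frozen outputs of an independently coded FAO-56 implementation
    (tests/oracle/fao56_reference.R) on randomized physical inputs."""
    return pd.read_csv(DATA_DIR / "fao56_oracle.csv")
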