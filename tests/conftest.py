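import numpy as np
import pandas as pd
import pytest

from tcbloom import GeoGrid

# 27-row 6-hourly best-track table (lat, lon, MM/DD/HH, max sustained wind,
# published translation speed — the last column is reference data only and
# is not fed to the parser).
TABLE1_ROWS = [
    (5.9, 80.8, "11/29/06", 12.5, None),
    (6.2, 79.7, "11/29/12", 12.5, 6.2),
    (6.7, 78.8, "11/29/18", 15.0, 4.9),
    (7.2, 77.9, "11/30/00", 17.5, 7.6),
    (7.8, 76.6, "11/30/06", 22.5, 6.0),
    (8.1, 75.8, "11/30/12", 22.5, 5.5),
    (8.5, 74.9, "11/30/18", 22.5, 4.8),
    (8.7, 74.2, "12/01/00", 27.5, 3.9),
    (8.8, 73.3, "12/01/06", 32.5, 4.6),
    (9.2, 72.8, "12/01/12", 32.5, 5.3),
    (9.4, 72.1, "12/01/18", 35.0, 3.7),
    (9.3, 71.5, "12/02/00", 37.5, 3.5),
    (9.8, 71.0, "12/02/06", 42.5, 2.9),
    (10.5, 70.3, "12/02/12", 42.5, 5.0),
    (11.1, 69.7, "12/02/18", 42.5, 4.7),
    (11.7, 69.2, "12/03/00", 42.5, 4.0),
    (12.3, 68.9, "12/03/06", 37.5, 3.4),
    (12.9, 68.7, "12/03/12", 37.5, 3.2),
    (13.5, 68.5, "12/03/18", 37.5, 3.2),
    (14.5, 68.5, "12/04/00", 35.0, 5.1),
    (14.7, 68.7, "12/04/06", 32.5, 2.9),
    (15.5, 69.2, "12/04/12", 30.0, 5.2),
    (16.6, 70.0, "12/04/18", 27.5, 5.1),
    (17.7, 70.9, "12/05/00", 22.5, 5.1),
    (18.3, 71.5, "12/05/06", 22.5, 4.2),
    (18.5, 71.4, "12/05/12", 15.0, 3.6),
    (19.2, 71.9, "12/05/18", 10.0, 4.3),
]

TABLE1_YEAR = 2017


@pytest.fixture(scope="session")
def table1_csv() -> str:
    lines = ["lat,lon,time,msw"]
    for lat, lon, t, msw, _ in TABLE1_ROWS:
        lines.append(f"{lat},{lon},{t},{msw}")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def table1_track(table1_csv):
    from tcbloom import parse_track

    return parse_track(table1_csv, year=TABLE1_YEAR)


@pytest.fixture
def small_grid():
    """0.25-degree tropical grid, 9-16N / 65-72E."""
    return GeoGrid(np.arange(9.0, 16.01, 0.25), np.arange(65.0, 72.01, 0.25))


@pytest.fixture
def daily_times():
    return pd.date_range("2017-11-22", periods=29, freq="D")
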