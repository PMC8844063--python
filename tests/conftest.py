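from datetime import date

import numpy as np
import pandas as pd
import pytest

from acousticniche import AssemblageRecord, CallTable, fit_all_spaces


@pytest.fixture(scope="session")
def hand_table() -> CallTable:
    """Six species with hand-set, well-conditioned call parameters."""
    rng = np.random.default_rng(42)
    n = 6
    dom = np.array([3.0, 3.2, 3.35, 3.5, 3.65, 3.8])
    bw = np.array([0.20, 0.15, 0.25, 0.18, 0.22, 0.30])
    df = pd.DataFrame(
        {
            "freq5_log10hz": dom - bw / 2,
            "freq95_log10hz": dom + bw / 2,
            "domfreq_log10hz": dom,
            "dur90_s": [0.5, 0.8, 1.2, 0.3, 0.9, 1.5],
            "peaktime_rel": [0.2, 0.5, 0.7, 0.4, 0.9, 0.1],
            "note_rate_hz": [4.0, 8.0, 12.0, 6.0, 10.0, 3.0],
        },
        index=pd.Index([f"sp{i}" for i in range(n)], name="species_id"),
    )
    # tiny jitter keeps every correlation submatrix full rank
    jitter = rng.normal(0, 1e-3, df.shape)
    return CallTable(df + jitter)


@pytest.fixture(scope="session")
def hand_spaces(hand_table):
    return fit_all_spaces(hand_table)


def make_assemblage(aid, species, lat=-27.0, lon=140.0, day=1, habitat="h0"):
    return AssemblageRecord(
        assemblage_id=aid,
        latitude=lat,
        longitude=lon,
        date=date(2018, 1, day),
        species=frozenset(species),
        habitat=habitat,
    )
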