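"""CSV readers and writers for assemblage and call-parameter tables.

Assemblage files follow GBIF-style occurrence exports: one row per
assemblage with a semicolon-separated species list (wide), or one row per
assemblage x species (long); the dialect is auto-detected. Coordinates are
decimal degrees (WGS84, east-positive longitude), dates ISO-8601.
"""

from __future__ import annotations

import logging
from datetime import date, datetime

import numpy as np
import pandas as pd

from .nullmodel import AssemblageRecord
from .similarity import PARAM_COLS, CallTable

logger = logging.getLogger(__name__)

ASSEMBLAGE_COLS = ["assemblage_id", "latitude", "longitude", "date", "species"]

#: Plausibility band for log10 Hz frequencies (10 Hz - 20 kHz).
FREQ_LOG10_BAND = (1.0, 4.3)


class SchemaError(ValueError):
    """Raised for missing columns or unparseable rows."""


def _parse_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, datetime):
        return value
    if isinstance(value, datetime):
        return value.date()
    return datetime.strptime(str(value).strip()[:10], "%Y-%m-%d").date()


def read_assemblages(path) -> list[AssemblageRecord]:
    """Read assemblage records from CSV (long or wide species format).

    Duplicate species within an assemblage are deduplicated with a warning;
    malformed rows are reported together with their line numbers.
    """
    df = pd.read_csv(path, dtype={"assemblage_id": str, "species": str},
                     float_precision="round_trip")
    missing = [c for c in ASSEMBLAGE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    has_habitat = "habitat" in df.columns

    wide = df["species"].astype(str).str.contains(";").any() or \
        not df["assemblage_id"].duplicated().any()

    errors: list[str] = []
    records: list[AssemblageRecord] = []

    def build(aid, group: pd.DataFrame, species: list[str], lineno: int):
        seen: list[str] = []
        for s in species:
            s = s.strip()
            if not s:
                continue
            if s in seen:
                logger.warning("%s: duplicate species %r in assemblage %s "
                               "deduplicated", path, s, aid)
            else:
                seen.append(s)
        row = group.iloc[0]
        try:
            records.append(
                AssemblageRecord(
                    assemblage_id=str(aid),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    date=_parse_date(row["date"]),
                    species=frozenset(seen),
                    habitat=(str(row["habitat"])
                             if has_habitat and pd.notna(row["habitat"]) else None),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: assemblage {aid!r}: {exc}")

    if wide:
        for i, (_, row) in enumerate(df.iterrows(), start=2):
            build(row["assemblage_id"], df.iloc[[i - 2]],
                  str(row["species"]).split(";"), i)
    else:
        for aid, group in df.groupby("assemblage_id", sort=False):
            lineno = int(group.index[0]) + 2
            build(aid, group, list(group["species"].astype(str)), lineno)

    if errors:
        raise SchemaError(f"{path}: {len(errors)} malformed row(s):\n"
                          + "\n".join(errors))
    return records


def write_assemblages(records: list[AssemblageRecord], path) -> None:
    """Write assemblages as wide CSV (semicolon-joined, sorted species)."""
    rows = [
        {
            "assemblage_id": r.assemblage_id,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "date": r.date.isoformat(),
            "species": ";".join(sorted(r.species)),
            "habitat": r.habitat if r.habitat is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_call_table(path) -> CallTable:
    """Read the species call-parameter CSV.

    Rows need at least ``species_id`` and ``domfreq_log10hz`` (literature
    dominant frequencies enter as dominant-only rows); duplicate species ids
    are an error; frequencies outside 10 Hz - 20 kHz draw a warning, and
    freq5 >= freq95 is a validation error.
    """
    df = pd.read_csv(path, dtype={"species_id": str},
                     float_precision="round_trip")
    if "species_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'species_id'")
    if "domfreq_log10hz" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'domfreq_log10hz'")
    if df["species_id"].duplicated().any():
        dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise SchemaError(f"{path}: duplicate species_id: {dupes}")
    for col in PARAM_COLS:
        if col not in df.columns:
            df[col] = np.nan
    df = df.set_index("species_id")

    for col in ("freq5_log10hz", "freq95_log10hz", "domfreq_log10hz"):
        vals = df[col].dropna()
        low, high = FREQ_LOG10_BAND
        bad = vals[(vals < low) | (vals > high)]
        if len(bad):
            logger.warning(
                "%s: %s outside plausible log10 Hz band [%s, %s] for %s",
                path, col, low, high, list(bad.index),
            )
    both = df[["freq5_log10hz", "freq95_log10hz"]].dropna()
    wrong = both.index[both["freq5_log10hz"] >= both["freq95_log10hz"]]
    if len(wrong):
        raise SchemaError(f"{path}: freq5 >= freq95 for species {list(wrong)}")
    return CallTable(df[PARAM_COLS])


def write_call_table(table: CallTable, path, source: str | None = None) -> None:
    """Write the call table in the canonical CSV schema."""
    out = table.params.copy()
    out["source"] = source if source is not None else "measured"
    # %.17g keeps float64 round-trips lossless
    out.to_csv(path, index=True, index_label="species_id", float_format="%.17g")


def write_similarity(similarity_df: pd.DataFrame, path) -> None:
    similarity_df.to_csv(path, index=False)


def write_ses(ses_df: pd.DataFrame, path) -> None:
    ses_df.to_csv(path, index=False)
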