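"""CSV interchange for gosling records.

The on-disk schema is a plain CSV with exactly the columns

    gosling_id,population,sex,cohort,nest_id,hatch_date,capture_date,
    age_days,mass_g,head_mm,tarsus_mm

with ISO-8601 dates.  Reading validates the header, parses dates and
cross-checks the recorded age against capture − hatch, naming the
offending row on failure.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .synthetic import CSV_COLUMNS


class GoslingCsvError(ValueError):
    pass


def write_gosling_csv(records: pd.DataFrame, path: str | Path) -> None:
    out = records[CSV_COLUMNS].copy()
    for col in ("hatch_date", "capture_date"):
        out[col] = [d.isoformat() for d in out[col]]
    out.to_csv(path, index=False)


def read_gosling_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gosling_id": str, "nest_id": str})
    if list(df.columns) != CSV_COLUMNS:
        raise GoslingCsvError(
            f"header mismatch: expected {CSV_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("hatch_date", "capture_date"):
        parsed = []
        for i, v in enumerate(df[col]):
            try:
                parsed.append(dt.date.fromisoformat(str(v)))
            except ValueError:
                raise GoslingCsvError(f"row {i}: unparseable {col} {v!r}") from None
        df[col] = parsed
    for i, row in enumerate(df.itertuples(index=False)):
        implied = (row.capture_date - row.hatch_date).days
        if implied < 0:
            raise GoslingCsvError(f"row {i}: capture precedes hatch")
        if implied != row.age_days:
            raise GoslingCsvError(
                f"row {i}: age_days={row.age_days} but capture-hatch={implied}"
            )
        if min(row.mass_g, row.head_mm, row.tarsus_mm) <= 0:
            raise GoslingCsvError(f"row {i}: non-positive measurement")
    df["cohort"] = df["cohort"].astype(int)
    df["age_days"] = df["age_days"].astype(int)
    return df
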