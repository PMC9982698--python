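"""Schema-validated delimited-text I/O and report assembly.

All file interfaces use fractions (never percents) and plain delimited text;
human-readable report lines show percents to one decimal.  Every writer is
deterministic given identical inputs, and runs that write outputs also drop
a machine-readable provenance record (config + seed + version) beside them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["read_passage_table", "write_passage_table", "write_report", "PassageTableError"]

REQUIRED_COLUMNS = ["patient_id", "note_id", "passage_id", "day_offset",
                    "score", "gold_label", "stratum"]
OPTIONAL_COLUMNS = ["arm"]


class PassageTableError(ValueError):
    """A passage table failed schema validation; messages carry line numbers."""


def read_passage_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a passage table.

    Validation errors name the offending column/key and the 1-based file
    line (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype={"patient_id": str, "note_id": str, "passage_id": str, "stratum": str},
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PassageTableError(f"{path.name}: missing required column(s): {missing}")

    lines = df.index + 2  # +1 header, +1 zero-base

    def _complain(mask, message):
        if mask.any():
            first = int(lines[mask][0])
            raise PassageTableError(
                f"{path.name}, line {first}: {message} "
                f"({int(mask.sum())} offending row(s) in total)"
            )

    score = pd.to_numeric(df["score"], errors="coerce")
    _complain(score.isna(), "score is not numeric")
    _complain((score < 0) | (score > 1), "score outside [0, 1]")
    df["score"] = score.astype(float)

    day = pd.to_numeric(df["day_offset"], errors="coerce")
    _complain(day.isna() | (day != day.round()), "day_offset is not an integer")
    _complain(day < 0, "day_offset is negative")
    df["day_offset"] = day.astype(int)

    gold = pd.to_numeric(df["gold_label"], errors="coerce")
    _complain(~gold.isin([0, 1]), "gold_label is not 0/1")
    df["gold_label"] = gold.astype(int)

    key = ["patient_id", "note_id", "passage_id"]
    dup = df.duplicated(key, keep="first")
    if dup.any():
        row = df[dup].iloc[0]
        raise PassageTableError(
            f"{path.name}, line {int(lines[dup][0])}: duplicate passage key "
            f"({row['patient_id']!r}, {row['note_id']!r}, {row['passage_id']!r})"
        )
    return df


def write_passage_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep=delimiter, index=False)


def _provenance(config: Mapping, seed) -> dict:
    from . import __version__

    return {"version": __version__, "seed": seed, "config": dict(config)}


def write_report(
    bundle: Mapping,
    out_dir,
    *,
    prefix: str = "report",
    config: Mapping | None = None,
    seed=None,
    delimiter: str = ",",
) -> list[Path]:
    """Write a results bundle as delimited tables plus a narrative summary.

    ``bundle`` maps names to DataFrames (written as ``<prefix>_<name>.csv``)
    or strings (collected into ``<prefix>_summary.txt``).  A provenance JSON
    with the run's config, seed and package version is always written.
    Output is deterministic given identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    narrative: list[str] = []
    for name in sorted(bundle):
        obj = bundle[name]
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{prefix}_{name}.csv"
            obj.to_csv(p, sep=delimiter, index=False)
            written.append(p)
        else:
            narrative.append(f"[{name}] {obj}")
    if narrative:
        p = out_dir / f"{prefix}_summary.txt"
        p.write_text("\n".join(narrative) + "\n")
        written.append(p)
    prov = out_dir / f"{prefix}_provenance.json"
    prov.write_text(json.dumps(_provenance(config or {}, seed), indent=2, default=str) + "\n")
    written.append(prov)
    return written
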