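"""CSV readers/writers with validation, and run manifests.

All tables are UTF-8 comma-separated files with a header row and "."
decimal separator; dates are ISO 8601.  Readers validate row-level
invariants and report offending rows by line number (header = line 1).
A RunManifest ties every artifact to its inputs (by SHA-256), settings
and seed so any output can be reproduced.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .beach_color import BeachRecord, VolcanoRecord, haversine_km
from .nesting import NestCountTable
from .norms import IncubationDataset

__all__ = [
    "ValidationError",
    "read_beaches",
    "read_volcanos",
    "read_nests",
    "read_incubation",
    "write_beaches",
    "RunManifest",
    "file_sha256",
]


class ValidationError(ValueError):
    """Input table violates its schema or row invariants."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _line(i: int) -> int:
    return i + 2  # header occupies line 1


def read_beaches(path) -> list[BeachRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "lat1", "lon1", "lat2", "lon2", "darkness"], path)
    out, bad = [], []
    for i, row in df.iterrows():
        length = row.get("length_km")
        if pd.isna(length):
            length = haversine_km(row.lat1, row.lon1, row.lat2, row.lon2)
        date = row.get("image_date")
        try:
            out.append(
                BeachRecord(
                    id=str(row.id),
                    lat1=float(row.lat1),
                    lon1=float(row.lon1),
                    lat2=float(row.lat2),
                    lon2=float(row.lon2),
                    darkness=float(row.darkness),
                    length_km=float(length),
                    image_date=None if pd.isna(date) else str(date),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {_line(i)}: {exc}")
    if bad:
        raise ValidationError(f"{path}: invalid beach rows:\n  " + "\n  ".join(bad))
    return out


def read_volcanos(path) -> list[VolcanoRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "lat", "lon"], path)
    out, bad = [], []
    for i, row in df.iterrows():
        try:
            out.append(VolcanoRecord(name=str(row["name"]), lat=float(row.lat), lon=float(row.lon)))
        except (ValueError, TypeError) as exc:
            bad.append(f"line {_line(i)}: {exc}")
    if bad:
        raise ValidationError(f"{path}: invalid volcano rows:\n  " + "\n  ".join(bad))
    return out


def read_nests(path) -> NestCountTable:
    df = pd.read_csv(path)
    _require_columns(df, ["beach_id", "year", "nests"], path)
    bad = [
        f"line {_line(i)}: negative nest count {row.nests}"
        for i, row in df.iterrows()
        if row.nests < 0
    ]
    if bad:
        raise ValidationError(f"{path}: invalid nest rows:\n  " + "\n  ".join(bad))
    return NestCountTable.from_dataframe(df)


def read_incubation(path) -> IncubationDataset:
    df = pd.read_csv(path)
    _require_columns(
        df, ["temperature_C", "n_eggs", "n_hatched", "n_sexed", "n_female", "n_male"], path
    )
    try:
        return IncubationDataset(df)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_beaches(beaches: list[BeachRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "id": b.id,
                "lat1": b.lat1,
                "lon1": b.lon1,
                "lat2": b.lat2,
                "lon2": b.lon2,
                "darkness": b.darkness,
                "length_km": b.length_km,
                "image_date": b.image_date,
            }
            for b in beaches
        ]
    ).to_csv(path, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record embedded in every JSON artifact."""

    subcommand: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    settings: dict = field(default_factory=dict)
    seed: int | None = None
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, subcommand: str, input_paths: dict, settings: dict, seed=None) -> "RunManifest":
        from . import __version__

        return cls(
            subcommand=subcommand,
            inputs={str(k): file_sha256(v) for k, v in input_paths.items()},
            settings=settings,
            seed=seed,
            package_version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def to_dict(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "inputs": self.inputs,
            "settings": self.settings,
            "seed": self.seed,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }


def write_json_artifact(path, payload: dict, manifest: RunManifest) -> None:
    out = {"schema_version": 1, "manifest": manifest.to_dict(), **payload}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
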