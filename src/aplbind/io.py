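"""TSV readers/writers and run manifests.

All tables are UTF-8, tab-separated, '.' decimal. Reporter files carry the
construct definition inline so a file round-trips to the same datasets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bending import BendMeasurement
from .fitting import ReporterConstruct, ReporterDataset
from .invitro import GelShiftDataset

__all__ = [
    "read_dataset", "read_reporter", "read_gelshift", "read_bend",
    "write_reporter", "write_gelshift", "write_bend", "write_manifest",
]

_REPORTER_COLS = ["construct", "config", "readout", "pR_active", "pL_active",
                  "c", "relative_expression", "replicate"]
_GELSHIFT_COLS = ["fragment", "c", "fraction_free", "normalized"]
_BEND_COLS = ["mu_M", "mu_E", "replicate"]


class DatasetFormatError(ValueError):
    pass


def _load(path, required, numeric):
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise DatasetFormatError(
                f"{path}: non-numeric value in column {col!r} at data rows "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        if parsed.isna().any():
            raise DatasetFormatError(f"{path}: empty cells in column {col!r}")
        df[col] = parsed
    return df


def read_reporter(path) -> list[ReporterDataset]:
    df = _load(path, _REPORTER_COLS, ["pR_active", "pL_active", "c",
                                      "relative_expression"])
    dup = df.duplicated(subset=["construct", "c", "replicate"])
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise DatasetFormatError(
            f"{path}: duplicate (construct, c, replicate) keys at rows {rows}"
        )
    out = []
    for label, g in df.groupby("construct", sort=False):
        cfgs = g["config"].unique()
        reads = g["readout"].unique()
        if len(cfgs) != 1 or len(reads) != 1:
            raise DatasetFormatError(
                f"{path}: construct {label!r} has inconsistent config/readout"
            )
        con = ReporterConstruct(
            config=cfgs[0], readout=reads[0],
            pR_active=bool(g["pR_active"].iloc[0]),
            pL_active=bool(g["pL_active"].iloc[0]),
            label=str(label),
        )
        try:
            out.append(ReporterDataset(con, g["c"].to_numpy(),
                                       g["relative_expression"].to_numpy(),
                                       g["replicate"].to_numpy()))
        except ValueError as e:
            raise DatasetFormatError(f"{path}: construct {label!r}: {e}") from e
    return out


def write_reporter(datasets: list[ReporterDataset], path) -> None:
    rows = []
    for ds in datasets:
        con = ds.construct
        for c, v, r in zip(ds.c, ds.value, ds.replicate):
            rows.append({"construct": con.label or con.config,
                         "config": con.config, "readout": con.readout,
                         "pR_active": int(con.pR_active),
                         "pL_active": int(con.pL_active),
                         "c": c, "relative_expression": v, "replicate": r})
    pd.DataFrame(rows, columns=_REPORTER_COLS).to_csv(path, sep="\t", index=False)


def read_gelshift(path) -> list[GelShiftDataset]:
    df = _load(path, _GELSHIFT_COLS, ["c", "fraction_free", "normalized"])
    out = []
    for frag, g in df.groupby("fragment", sort=False):
        try:
            out.append(GelShiftDataset(fragment=str(frag),
                                       c=g["c"].to_numpy(),
                                       fraction_free=g["fraction_free"].to_numpy(),
                                       normalized=bool(g["normalized"].iloc[0])))
        except ValueError as e:
            raise DatasetFormatError(f"{path}: fragment {frag!r}: {e}") from e
    return out


def write_gelshift(datasets: list[GelShiftDataset], path) -> None:
    rows = []
    for ds in datasets:
        for c, f in zip(ds.c, ds.fraction_free):
            rows.append({"fragment": ds.fragment, "c": c, "fraction_free": f,
                         "normalized": int(ds.normalized)})
    pd.DataFrame(rows, columns=_GELSHIFT_COLS).to_csv(path, sep="\t", index=False)


def read_bend(path) -> list[BendMeasurement]:
    df = _load(path, _BEND_COLS, ["mu_M", "mu_E"])
    out = []
    for i, row in df.iterrows():
        try:
            out.append(BendMeasurement(mu_M=float(row["mu_M"]),
                                       mu_E=float(row["mu_E"]),
                                       replicate=str(row["replicate"])))
        except ValueError as e:
            raise DatasetFormatError(f"{path}: data row {int(i) + 2}: {e}") from e
    return out


def write_bend(measurements: list[BendMeasurement], path) -> None:
    pd.DataFrame(
        [{"mu_M": m.mu_M, "mu_E": m.mu_E, "replicate": m.replicate}
         for m in measurements],
        columns=_BEND_COLS,
    ).to_csv(path, sep="\t", index=False)


_READERS = {"reporter": read_reporter, "gelshift": read_gelshift,
            "bend": read_bend}


def read_dataset(path, kind: str):
    """Read a typed dataset: kind is 'reporter', 'gelshift' or 'bend'."""
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown dataset kind {kind!r}") from None
    return reader(path)


def write_manifest(out_dir, command: str, seed, options: dict) -> Path:
    """Reproducibility manifest: package version, command, seed, option hash."""
    from . import __version__

    payload = {"package": "aplbind", "version": __version__,
               "command": command, "seed": seed,
               "options": {k: options[k] for k in sorted(options)}}
    payload["config_sha256"] = hashlib.sha256(
        json.dumps(payload["options"], sort_keys=True, default=str).encode()
    ).hexdigest()
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
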