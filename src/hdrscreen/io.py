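"""Readers and writers for the pipeline's TSV/JSON formats.

All tables are tab-separated UTF-8 with a header row; signed SNP offsets
use the DSB-at-0, 5'-negative convention, stated in every written header
comment. Packaged example data (``load_example_*``) are synthetic but
consistent with the published screen's per-construct counts; the exact
pool-level composition and SNP coordinates were not published.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .pooling import PoolRecord
from .tracts import CallState, ConversionCallSet, SNPMap

__all__ = [
    "ExperimentTableError",
    "read_experiment_table",
    "write_experiment_table",
    "experiment_to_pools",
    "read_snp_map",
    "write_snp_map",
    "read_conversion_calls",
    "write_conversion_calls",
    "load_example_experiment",
    "load_example_snp_map",
    "load_example_conversion_calls",
    "PipelineConfig",
    "load_config",
]

EXPERIMENT_COLUMNS = ["construct", "donor_type", "pool_id", "n_founders",
                      "positive", "g0_survivors_total"]

#: header comment written atop every output table
COORDINATE_NOTE = ("# coordinates: signed bp offsets relative to the "
                   "predicted DSB (0); 5' negative, 3' positive")


class ExperimentTableError(ValueError):
    """Validation failure with row-level detail."""


_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(series: pd.Series, errors: list[str]) -> pd.Series:
    out = []
    for i, v in series.items():
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out.append(True)
        elif s in _FALSY:
            out.append(False)
        else:
            errors.append(f"row {i}: unparseable positive flag {v!r}")
            out.append(False)
    return pd.Series(out, index=series.index)


def validate_experiment_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a pool-level experiment table; raise with row messages."""
    errors: list[str] = []
    missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ExperimentTableError(f"missing required columns: {missing}")
    if df.empty:
        raise ExperimentTableError("experiment table has no rows")
    df = df.copy()
    if df["positive"].dtype != bool:
        df["positive"] = _parse_bool(df["positive"], errors)
    for col in ("n_founders", "g0_survivors_total"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        for i in bad:
            errors.append(f"row {i}: non-numeric {col} {df.loc[i, col]!r}")
    if errors:
        raise ExperimentTableError("; ".join(errors))
    df["n_founders"] = df["n_founders"].astype(int)
    df["g0_survivors_total"] = df["g0_survivors_total"].astype(int)
    for i, row in df.iterrows():
        if row["n_founders"] < 1:
            errors.append(f"row {i}: n_founders must be >= 1")
        if row["g0_survivors_total"] < 0:
            errors.append(f"row {i}: negative g0_survivors_total")
    dup = df["pool_id"].duplicated()
    for i in df.index[dup]:
        errors.append(f"row {i}: duplicate pool_id {df.loc[i, 'pool_id']!r}")
    for construct, grp in df.groupby("construct"):
        totals = grp["g0_survivors_total"].unique()
        if len(totals) != 1:
            errors.append(f"construct {construct!r}: inconsistent "
                          f"g0_survivors_total {sorted(totals)}")
            continue
        # not every survivor joins a pool, but pools cannot exceed survivors
        if grp["n_founders"].sum() > totals[0]:
            errors.append(
                f"construct {construct!r}: pooled founders "
                f"({grp['n_founders'].sum()}) exceed surviving G0 ({totals[0]})")
    if errors:
        raise ExperimentTableError("; ".join(errors))
    return df


def read_experiment_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a pool-level experiment TSV."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise ExperimentTableError(f"{path}: empty file") from None
    return validate_experiment_table(df)


def write_experiment_table(df: pd.DataFrame, path: str | Path,
                           header_note: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False)


def experiment_to_pools(df: pd.DataFrame) -> dict[str, list[PoolRecord]]:
    """Group a validated experiment table into PoolRecords per construct."""
    out: dict[str, list[PoolRecord]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["construct"], []).append(PoolRecord(
            pool_id=str(row["pool_id"]), construct_id=row["construct"],
            n_founders=int(row["n_founders"]), positive=bool(row["positive"])))
    return out


def read_snp_map(path: str | Path) -> SNPMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "offset" not in df.columns:
        raise ValueError(f"{path}: SNP map needs an 'offset' column")
    return SNPMap.from_frame(df)


def write_snp_map(snp_map: SNPMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        snp_map.to_frame().to_csv(fh, sep="\t", index=False)


def read_conversion_calls(path: str | Path) -> list[ConversionCallSet]:
    """Read a long-format call table (one row per event x SNP).

    Required columns: event_id, offset, state; optional pool_id,
    construct, span_lo, span_hi (span defaults to the called offsets'
    range). Events keep file order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"event_id", "offset", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for event_id, grp in df.groupby("event_id", sort=False):
        if {"span_lo", "span_hi"} <= set(grp.columns):
            span = (int(grp["span_lo"].iloc[0]), int(grp["span_hi"].iloc[0]))
        else:
            span = (int(grp["offset"].min()), int(grp["offset"].max()))
        out.append(ConversionCallSet(
            event_id=str(event_id),
            pool_id=str(grp["pool_id"].iloc[0]) if "pool_id" in grp else "",
            calls={int(r["offset"]): CallState(str(r["state"]))
                   for _, r in grp.iterrows()},
            sequenced_span=span))
    return out


def write_conversion_calls(call_sets: Iterable[ConversionCallSet],
                           path: str | Path) -> None:
    rows = []
    for cs in call_sets:
        for offset in sorted(cs.calls):
            rows.append({"event_id": cs.event_id, "pool_id": cs.pool_id,
                         "span_lo": cs.sequenced_span[0],
                         "span_hi": cs.sequenced_span[1],
                         "offset": offset, "state": cs.calls[offset].value})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("hdrscreen.data").joinpath(name)


def load_example_experiment() -> pd.DataFrame:
    """Packaged screen table: published per-construct positive-pool counts
    and survivor totals; pool-level composition is synthetic (~20
    founders per pool)."""
    with resources.as_file(_data_path("experiment_pools_synthetic.tsv")) as p:
        return read_experiment_table(p)


def load_example_snp_map(construct: str = "190-recoded") -> SNPMap:
    """Packaged synthetic marker map for '190-recoded' or '234-recoded'.

    Coordinates are invented but honour each construct's SNP-free
    window adjacent to the cut (5' for 190-recoded, 3' for 234-recoded)
    and contain the offsets of the reported extreme conversion events.
    """
    name = {"190-recoded": "snp_map_190_recoded_synthetic.tsv",
            "234-recoded": "snp_map_234_recoded_synthetic.tsv"}[construct]
    with resources.as_file(_data_path(name)) as p:
        return read_snp_map(p)


def load_example_conversion_calls(construct: str | None = None
                                  ) -> list[ConversionCallSet]:
    """Packaged synthetic call table for the ten characterised HDR events
    (6 unidirectional, 2 non-conversion, 2 bidirectional, including the
    725/16 bp and 94/149 bp bidirectional events)."""
    with resources.as_file(_data_path("conversion_calls_synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    if construct is not None:
        df = df[df["construct"] == construct]
    import io as _io
    buf = _io.StringIO(df.to_csv(sep="\t", index=False))
    return read_conversion_calls(buf)


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run; echoed into every report."""

    seed: int = 0
    out_dir: str = "hdrscreen-out"
    experiment_path: str | None = None   # None -> packaged example
    snp_map_paths: dict[str, str] = field(default_factory=dict)
    calls_paths: dict[str, str] = field(default_factory=dict)
    reference_construct: str = "190-perfect"
    level: float = 0.95
    rate_dp: int = 2
    founders_per_pool: int = 20
    detection_prob: float = 1.0
    simulate: dict | None = None         # SimDesign kwargs, optional stage
    tract_model: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.rate_dp < 0:
            raise ValueError("rate_dp must be >= 0")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
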