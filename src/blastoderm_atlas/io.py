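"""Tab-delimited text I/O for per-nucleus tables, atlases and affine maps.

All tables are UTF-8, tab-delimited with a mandatory header line; headers
are validated strictly and parse failures report the offending line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EmbryoProfile, ParseError
from .integration import BinnedProfile
from .registration import AffineMap1D

NUCLEUS_TABLE_COLUMNS = ["embryo_id", "nucleus_id", "x_percent_EL", "y_percent_height"]
ATLAS_COLUMNS = ["gene", "time_class", "bin", "x_mid", "mean", "sd", "n"]
MAP_COLUMNS = ["embryo_id", "a", "b"]


def _check_header(path: Path, expected_prefix: list[str], header: list[str]) -> None:
    for col in expected_prefix:
        if col not in header:
            raise ParseError(f"{path.name}: missing column {col!r}", line=1)


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:     # pandas error messages lack line numbers
        raise ParseError(f"{path.name}: {exc}") from exc
    _check_header(path, required, list(df.columns))
    for col in numeric:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path.name}: non-numeric value {df[col][bad].iloc[0]!r} in column {col!r}",
                line=int(bad.idxmax()) + 2,
            )
        df[col] = converted
    return df


def write_nucleus_table(path, profiles: list[EmbryoProfile]) -> None:
    """Write one cohort as a single tab-delimited per-nucleus table."""
    frames = []
    for p in profiles:
        out = p.data.rename(columns={"x": "x_percent_EL", "y": "y_percent_height"}).copy()
        out.insert(0, "embryo_id", p.embryo_id)
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep="\t", index=False)


def read_nucleus_table(path) -> list[EmbryoProfile]:
    """Read a per-nucleus table back into one profile per embryo."""
    df = _read_table(Path(path), NUCLEUS_TABLE_COLUMNS,
                     ["nucleus_id", "x_percent_EL", "y_percent_height"])
    intensity_cols = [c for c in df.columns if c.startswith("I_")]
    df = _read_table(Path(path), NUCLEUS_TABLE_COLUMNS,
                     ["nucleus_id", "x_percent_EL", "y_percent_height"] + intensity_cols)
    profiles = []
    for eid, grp in df.groupby("embryo_id", sort=False):
        data = grp.rename(columns={"x_percent_EL": "x", "y_percent_height": "y"})
        data = data.drop(columns=["embryo_id"]).reset_index(drop=True)
        data["nucleus_id"] = data["nucleus_id"].astype(int)
        profiles.append(EmbryoProfile(embryo_id=str(eid), data=data))
    return profiles


def write_atlas(path, profiles: list[BinnedProfile]) -> None:
    frames = []
    for bp in profiles:
        out = bp.table[["bin", "x_mid", "mean", "sd", "n"]].copy()
        out.insert(0, "gene", bp.gene)
        out.insert(1, "time_class", bp.time_class)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_atlas(path) -> list[BinnedProfile]:
    df = _read_table(Path(path), ATLAS_COLUMNS, ["bin", "x_mid", "mean", "sd", "n"])
    out = []
    for (gene, tc), grp in df.groupby(["gene", "time_class"], sort=False):
        table = grp.drop(columns=["gene", "time_class"]).reset_index(drop=True)
        table["bin"] = table["bin"].astype(int)
        table["n"] = table["n"].astype(int)
        table["interpolated"] = table["n"] == 0
        out.append(BinnedProfile(gene=str(gene), time_class=str(tc), table=table,
                                 meta={"n_bins": len(table)}))
    return out


def write_affine_maps(path, maps: dict[str, AffineMap1D]) -> None:
    rows = [{"embryo_id": eid, "a": m.a, "b": m.b} for eid, m in maps.items()]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_affine_maps(path) -> dict[str, AffineMap1D]:
    df = _read_table(Path(path), MAP_COLUMNS, ["a", "b"])
    return {str(r.embryo_id): AffineMap1D(float(r.a), float(r.b)) for r in df.itertuples()}


def write_distance_matrix(path, ids: list[str], values: np.ndarray) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def write_config_echo(path, config_dict: dict) -> None:
    """Machine-readable echo of the run configuration (YAML)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
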