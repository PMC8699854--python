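"""Delimited-text I/O: trajectory tables, result tables, libraries, configs."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import SimLibrary

log = logging.getLogger("symrec")

CONFIG_VERSION = 1


class ParseError(ValueError):
    pass


def read_trajectory_table(path) -> pd.DataFrame:
    """Read a TSV of trajectories: label, v0..v{n-1}; one row per residue.

    Rows whose first point is not 1 are normalized on load (with a warning),
    matching the first-plane normalization of the experiment.  Duplicate
    labels, missing values and non-numeric cells raise ParseError naming the
    location.
    """
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing 'label' column")
    vcols = [c for c in df.columns if c.startswith("v")]
    if not vcols:
        raise ParseError(f"{path}: no intensity columns (v0, v1, ...)")
    dup = df["label"][df["label"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate label {dup.iloc[0]!r}")
    for col in vcols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing value at row {bad[0] + 2}, "
                f"column {col!r}"
            )
        df[col] = df[col].astype(float)
    first = df[vcols[0]].to_numpy()
    if not np.allclose(first, 1.0):
        log.warning("%s: normalizing %d trajectories to first point 1.0",
                    path, int((~np.isclose(first, 1.0)).sum()))
        df[vcols] = df[vcols].div(first, axis=0)
    return df


def write_trajectory_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results(path, df: pd.DataFrame) -> None:
    """Per-residue fit results as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_library(path, lib: SimLibrary) -> None:
    """Persist a simulation library as TSV with a small comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# symrec library v{CONFIG_VERSION}\n")
        fh.write(f"# increment_s\t{lib.increment!r}\n")
        fh.write(f"# n_points\t{lib.n_points}\n")
        header = "coupling_Hz\t" + "\t".join(f"v{i}" for i in range(lib.n_points))
        fh.write(header + "\n")
        for c, row in zip(lib.couplings, lib.trajectories):
            fh.write("%.10g\t" % c + "\t".join("%.12g" % v for v in row) + "\n")


def load_library(path) -> SimLibrary:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    try:
        increment = float(meta["increment_s"])
        n_points = int(meta["n_points"])
    except KeyError as e:
        raise ParseError(f"{path}: missing library header field {e}") from None
    vcols = [f"v{i}" for i in range(n_points)]
    return SimLibrary(
        couplings=df["coupling_Hz"].to_numpy(float),
        trajectories=df[vcols].to_numpy(float),
        increment=increment,
        n_points=n_points,
    )


def read_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    version = cfg.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ParseError(f"{path}: unsupported config version {version}")
    return cfg
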