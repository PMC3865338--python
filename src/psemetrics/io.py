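"""Reading and writing coded PSE data and run configuration.

Two interchange layouts are supported for the binary coding tensors:

long
    one row per (subject, scale, picture, category) with a 0/1 value;
    the canonical format.
wide
    one row per subject, one column per ``PICTURE_CATEGORY`` pair
    (e.g. ``A_NS``); one scale per file.

Legacy fixed-column ``.DAT`` exports can be read by supplying an explicit
column map, since such files do not document their own layout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import ScoringTensor

__all__ = [
    "read_long",
    "write_long",
    "read_wide",
    "write_wide",
    "read_dat",
    "RunConfig",
    "load_run_config",
    "write_manifest",
]

LONG_COLUMNS = ["subject_id", "scale", "picture", "category", "value"]


def _validate_binary(values: pd.Series, path: Path) -> None:
    bad = ~values.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-binary value {values.iloc[row]!r} at data row {row}"
        )


def _tensor_from_frame(df: pd.DataFrame, scale: str) -> ScoringTensor:
    subjects = list(dict.fromkeys(df["subject_id"]))
    pictures = tuple(dict.fromkeys(df["picture"]))
    categories = tuple(dict.fromkeys(df["category"]))
    sub_ix = {s: i for i, s in enumerate(subjects)}
    pic_ix = {p: i for i, p in enumerate(pictures)}
    cat_ix = {c: i for i, c in enumerate(categories)}
    x = np.zeros((len(subjects), len(pictures), len(categories)), dtype=np.int64)
    seen = np.zeros_like(x, dtype=bool)
    for row in df.itertuples(index=False):
        j, p, c = sub_ix[row.subject_id], pic_ix[row.picture], cat_ix[row.category]
        x[j, p, c] = int(row.value)
        seen[j, p, c] = True
    if not seen.all():
        raise ValueError(
            f"scale {scale!r}: incomplete subject x picture x category grid "
            f"({int((~seen).sum())} missing cells)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ScoringTensor(x, pictures, categories, scale_id=scale)


def read_long(path: str | Path, delimiter: str | None = None) -> dict[str, ScoringTensor]:
    """Read long-format coded data; returns one tensor per scale."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    _validate_binary(df["value"], path)
    return {
        str(scale): _tensor_from_frame(group, str(scale))
        for scale, group in df.groupby("scale", sort=False)
    }


def write_long(
    tensors: Mapping[str, ScoringTensor] | ScoringTensor,
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write tensors in the long layout (the canonical interchange format)."""
    if isinstance(tensors, ScoringTensor):
        tensors = {tensors.scale_id: tensors}
    rows = []
    for scale, t in tensors.items():
        for j in range(t.n_subjects):
            for p, pic in enumerate(t.pictures):
                for c, cat in enumerate(t.categories):
                    rows.append((j + 1, scale, pic, cat, int(t.values[j, p, c])))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


def read_wide(
    path: str | Path, scale_id: str = "scale", delimiter: str | None = None
) -> ScoringTensor:
    """Read one scale's tensor from the wide PICTURE_CATEGORY layout."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    cols = [c for c in df.columns if c != "subject_id"]
    pairs = []
    for c in cols:
        if "_" not in c:
            raise ValueError(f"{path}: column {c!r} is not a PICTURE_CATEGORY pair")
        pairs.append(tuple(c.split("_", 1)))
    pictures = tuple(dict.fromkeys(p for p, _ in pairs))
    categories = tuple(dict.fromkeys(c for _, c in pairs))
    if len(pairs) != len(pictures) * len(categories):
        raise ValueError(f"{path}: columns do not form a full picture x category grid")
    for c in cols:
        _validate_binary(df[c], path)
    x = np.zeros((len(df), len(pictures), len(categories)), dtype=np.int64)
    for col, (pic, cat) in zip(cols, pairs):
        x[:, pictures.index(pic), categories.index(cat)] = df[col].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ScoringTensor(x, pictures, categories, scale_id=scale_id)


def write_wide(t: ScoringTensor, path: str | Path, delimiter: str = ",") -> None:
    data = {"subject_id": np.arange(1, t.n_subjects + 1)}
    for p, pic in enumerate(t.pictures):
        for c, cat in enumerate(t.categories):
            data[f"{pic}_{cat}"] = t.values[:, p, c]
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def read_dat(
    path: str | Path, column_map: Mapping
) -> dict[str, ScoringTensor]:
    """Read a fixed-column .DAT export using an explicit column map.

    ``column_map`` keys:

    delimiter
        field separator (default: any whitespace);
    subject_column
        0-based index of a subject-id column, or None for row order;
    columns
        mapping of 0-based column index -> [scale, picture, category].
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    delim = column_map.get("delimiter")
    assignments = {
        int(k): tuple(v) for k, v in column_map["columns"].items()
    }
    sub_col = column_map.get("subject_column")
    df = pd.read_csv(
        path,
        sep=delim if delim is not None else r"\s+",
        header=None,
        engine="python",
    )
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        sid = row[sub_col] if sub_col is not None else i + 1
        for col, (scale, pic, cat) in assignments.items():
            rows.append((sid, scale, pic, cat, row[col]))
    long_df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    _validate_binary(long_df["value"], path)
    return {
        str(scale): _tensor_from_frame(g, str(scale))
        for scale, g in long_df.groupby("scale", sort=False)
    }


_RUNCONFIG_KEYS = {
    "input", "layout", "scales", "weighting", "coefficients",
    "var_denominator", "lambda4_strategy", "omega_n_factors", "output_dir",
    "verbosity", "seed", "dat_column_map", "ft_rule", "strict",
}


@dataclass
class RunConfig:
    """Validated run settings for the command-line surface."""

    input: str | None = None
    layout: str = "long"
    scales: tuple[str, ...] = ("HS", "FF")
    weighting: bool = True
    coefficients: tuple[str, ...] = (
        "lambda1", "lambda2", "alpha", "lambda4", "lambda5", "lambda6",
        "omega_total",
    )
    var_denominator: str = "n"
    lambda4_strategy: str = "max"
    omega_n_factors: int = 1
    output_dir: str = "."
    verbosity: int = 1
    seed: int = 0
    dat_column_map: dict = field(default_factory=dict)
    ft_rule: str = "conjunctive"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.layout not in {"long", "wide", "dat"}:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.var_denominator not in {"n", "n-1"}:
            raise ValueError("var_denominator must be 'n' or 'n-1'")
        if self.input is not None and not Path(self.input).exists():
            raise FileNotFoundError(self.input)

    @property
    def ddof(self) -> int:
        return 0 if self.var_denominator == "n" else 1


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _RUNCONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("scales", "coefficients"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def write_manifest(path: str | Path, config: Mapping, seed: int | None = None) -> None:
    """Write a JSON run manifest sufficient to reproduce the run."""
    from . import __version__

    manifest = {
        "package": "psemetrics",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in dict(config).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
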