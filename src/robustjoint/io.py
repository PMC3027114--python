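"""Tabular I/O and run configuration.

The interchange unit is a TSV of per-SNP genotype counts, one SNP per row::

    snp_id  r0_1 r1_1 r2_1 s0_1 s1_1 s2_1  r0_2 r1_2 r2_2 s0_2 s1_2 s2_2

with r*/s* the case/control counts over genotypes (gg, Gg, GG), stage 1
then stage 2.  The risk allele G must be the second-listed allele; use
``flip=True`` (CLI ``--flip``) for tables oriented the other way.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import GenotypeTable, TwoStageData

__all__ = [
    "COUNT_COLUMNS",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_results",
    "load_config",
]

COUNT_COLUMNS = [
    f"{arm}{g}_{stage}" for stage in (1, 2) for arm in ("r", "s") for g in (0, 1, 2)
]


class CountsFormatError(ValueError):
    """Raised for malformed count tables."""


def read_counts_tsv(path, flip: bool = False) -> list[tuple[str, TwoStageData]]:
    """Read per-SNP two-stage genotype counts.

    Returns ``(snp_id, TwoStageData)`` pairs.  Rows with an all-zero stage
    are skipped with a warning; negative or non-integer counts are a hard
    error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns:
        raise CountsFormatError(f"{path}: missing required column 'snp_id'")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountsFormatError(f"{path}: missing count columns {missing}")
    out: list[tuple[str, TwoStageData]] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        snp = row["snp_id"]
        try:
            vals = np.array([float(row[c]) for c in COUNT_COLUMNS])
        except (TypeError, ValueError) as exc:
            raise CountsFormatError(f"{path} line {line} ({snp}): non-numeric count") from exc
        if (vals < 0).any():
            raise CountsFormatError(f"{path} line {line} ({snp}): negative count")
        if not np.allclose(vals, np.round(vals)):
            raise CountsFormatError(f"{path} line {line} ({snp}): non-integer count")
        vals = vals.astype(int)
        r1, s1, r2, s2 = vals[0:3], vals[3:6], vals[6:9], vals[9:12]
        if r1.sum() + s1.sum() == 0 or r2.sum() + s2.sum() == 0:
            warnings.warn(f"{path} line {line} ({snp}): all-zero stage, row skipped", stacklevel=2)
            continue
        t1 = GenotypeTable(tuple(r1), tuple(s1))
        t2 = GenotypeTable(tuple(r2), tuple(s2))
        if flip:
            t1, t2 = t1.flipped(), t2.flipped()
        out.append((str(snp), TwoStageData(t1, t2, snp_id=str(snp))))
    return out


def write_counts_tsv(path, records) -> None:
    """Write ``(snp_id, TwoStageData)`` pairs in the counts layout."""
    rows = []
    for snp, data in records:
        vals = list(data.stage1.case_counts) + list(data.stage1.control_counts)
        vals += list(data.stage2.case_counts) + list(data.stage2.control_counts)
        rows.append([snp] + [int(v) for v in vals])
    pd.DataFrame(rows, columns=["snp_id"] + COUNT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results(path, table: pd.DataFrame, sidecar: dict | None = None) -> None:
    """Write a results TSV plus a JSON sidecar with config and MC metadata."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(_jsonable(sidecar), indent=2, sort_keys=True) + "\n"
        )


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
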