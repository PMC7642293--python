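"""Readers and writers for the tab-separated tables the pipeline consumes.

All on-disk formats are plain TSV (UTF-8, header row).  Expression matrices
are genes-in-rows with the gene identifier in the first column.  Signature
files carry a ``#``-commented metadata header.  Quantification tables follow a
MaxQuant-like wide dialect where a zero or empty intensity cell means
*missing*, never a measured zero.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("swisig")

VALID_STATES = ("benign", "PCa", "CRPC-Adeno", "CRPC-NE")

ANNOTATION_OPTIONAL_COLUMNS = ("gleason_group", "risk_score", "event", "time")


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping, for log auditing."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_stage(stage: str, config: Mapping | None = None) -> None:
    h = config_hash(config) if config is not None else "-"
    logger.info("stage=%s config_hash=%s", stage, h)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, dtype=float) -> pd.DataFrame:
    """Read a genes × samples TSV matrix.

    The first column holds gene identifiers; remaining columns are samples.
    Raises ``ValueError`` on duplicate gene or sample identifiers, ragged
    rows, or non-numeric cells (naming the offending row/column).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path.name}: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path.name}: {dup}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"ragged or empty cell in {path.name} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    try:
        out = df.astype(dtype)
    except (TypeError, ValueError):
        for c in df.columns:
            bad = pd.to_numeric(df[c], errors="coerce").isna()
            if bad.any():
                g = df.index[bad.values.nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric cell in {path.name} at gene {g!r}, sample {c!r}"
                ) from None
        raise
    out.index.name = df.index.name or "gene"
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "gene"
    matrix.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-sample phenotype table.

    Requires a ``sample`` index column and a ``state`` column drawn from
    ``VALID_STATES``.  Optional columns: ``gleason_group`` (ordinal 1-5),
    ``risk_score`` (real), ``event`` (0/1), ``time`` (non-negative).
    Absent optional columns stay absent.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    return validate_annotation(df, name=Path(path).name)


def validate_annotation(df: pd.DataFrame, name: str = "annotation") -> pd.DataFrame:
    if "state" not in df.columns:
        raise ValueError(f"{name}: required column 'state' missing")
    unknown = set(df["state"].unique()) - set(VALID_STATES)
    if unknown:
        raise ValueError(f"{name}: unknown state label(s): {sorted(unknown)}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample id(s): {dup}")
    if "time" in df.columns and (pd.to_numeric(df["time"]) < 0).any():
        raise ValueError(f"{name}: negative survival time")
    if "gleason_group" in df.columns:
        gg = pd.to_numeric(df["gleason_group"])
        if ((gg < 1) | (gg > 5)).any():
            raise ValueError(f"{name}: gleason_group outside 1-5")
    df.index.name = df.index.name or "sample"
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation = annotation.copy()
    annotation.index.name = annotation.index.name or "sample"
    annotation.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# signature files
# ---------------------------------------------------------------------------

def read_signature(path: str | Path):
    """Read a signature TSV with ``#`` metadata header.

    Returns a :class:`swisig.signature.SignatureModel`.
    """
    from .signature import SignatureModel

    path = Path(path)
    meta: dict = {}
    body_lines = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            payload = line.lstrip("#").strip()
            if "=" in payload:
                k, v = payload.split("=", 1)
                meta[k.strip()] = yaml.safe_load(v.strip())
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    required = {"gene", "weight", "direction", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: signature columns missing: {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"{path.name}: duplicate signature gene(s): {dup}")
    nz = df["weight"] != 0
    if not (np.sign(df.loc[nz, "weight"]) == df.loc[nz, "direction"]).all():
        raise ValueError(f"{path.name}: direction must equal sign(weight)")
    df = df.sort_values("rank", kind="mergesort")
    return SignatureModel(
        genes=df["gene"].tolist(),
        weights=dict(zip(df["gene"], df["weight"].astype(float))),
        directions=dict(zip(df["gene"], df["direction"].astype(int))),
        derivation=meta,
    )


def write_signature(sig, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {k} = {json.dumps(v)}" for k, v in sig.derivation.items()]
    lines.append("gene\tweight\tdirection\trank")
    for rank, g in enumerate(sig.genes, start=1):
        lines.append(f"{g}\t{sig.weights[g]:.10g}\t{sig.directions[g]}\t{rank}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# quantification tables (MaxQuant-like wide dialect)
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path,
    design: Mapping[str, tuple[str, int]],
    id_column: str = "protein",
    peptide_column: str | None = None,
) -> pd.DataFrame:
    """Read a wide intensity table into long-format records.

    ``design`` maps intensity column names (e.g. ``"Intensity IP_1"``) to
    ``(condition, replicate)`` pairs.  A cell that is ``0`` or empty is
    recorded as missing (``NaN``), per the MaxQuant convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0)
    if id_column not in df.columns:
        raise ValueError(f"{path.name}: id column {id_column!r} absent")
    for col in design:
        if col not in df.columns:
            raise ValueError(f"{path.name}: design column {col!r} absent from file")
    id_cols = [id_column] + ([peptide_column] if peptide_column else [])
    records = []
    for col, (condition, replicate) in design.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        vals = vals.where(vals > 0)  # 0 or empty -> missing
        chunk = df[id_cols].copy()
        chunk["condition"] = condition
        chunk["replicate"] = int(replicate)
        chunk["intensity"] = vals
        records.append(chunk)
    out = pd.concat(records, ignore_index=True)
    if peptide_column:
        out = out.rename(columns={peptide_column: "peptide"})
    return out.rename(columns={id_column: "protein"})


def write_quant_table(
    long: pd.DataFrame, path: str | Path, value_prefix: str = "Intensity"
) -> None:
    """Write long-format quant records back to the wide dialect (missing -> 0)."""
    idx = ["protein"] + (["peptide"] if "peptide" in long.columns else [])
    wide = long.pivot_table(
        index=idx,
        columns=["condition", "replicate"],
        values="intensity",
        aggfunc="first",
        dropna=False,
    )
    wide.columns = [f"{value_prefix} {c}_{r}" for c, r in wide.columns]
    wide = wide.fillna(0)
    wide.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{Path(path).name}: config must be a mapping")
    return cfg


def write_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
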