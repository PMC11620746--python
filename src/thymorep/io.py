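"""Clonotype tables: AIRR Rearrangement TSV input/output and validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIFE_STAGES = ("foetal", "adult", "adult_hc")
CELL_TYPES = ("DP", "CD69negDP", "CD69posDP", "CD3loDP", "CD3hiDP", "SP4", "SP8")
CHAINS = ("TRA", "TRB")

_MANDATORY = ("v_call", "j_call", "junction", "duplicate_count")

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "FormatError",
    "read_airr",
    "write_airr",
    "validate_sample",
    "read_manifest",
]


class FormatError(ValueError):
    """Raised for malformed repertoire tables."""


@dataclass(frozen=True)
class Clonotype:
    """One unique rearrangement (V gene x J gene x junction) with abundance.

    ``insert_len``, ``v_deleted`` and ``j_deleted`` are optional junction
    decomposition annotations (ground truth when simulated, inferred
    otherwise); ``None`` means unknown.
    """

    v_name: str
    j_name: str
    junction_nt: str
    abundance: int
    productive: bool
    junction_aa: str = ""
    insert_len: int | None = None
    v_deleted: int | None = None
    j_deleted: int | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_name, self.j_name, self.junction_nt)


@dataclass
class RepertoireSample:
    """One (individual x cell type x chain) repertoire."""

    sample_id: str
    life_stage: str
    cell_type: str
    chain: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life_stage {self.life_stage!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_abundance(self) -> int:
        return int(sum(c.abundance for c in self.clonotypes))

    def abundances(self) -> np.ndarray:
        return np.array([c.abundance for c in self.clonotypes], dtype=np.int64)

    def cdr3_set(self, level: str = "aa") -> set[str]:
        """Distinct CDR3 strings; ``aa`` level covers productive clonotypes."""
        if level == "aa":
            return {c.junction_aa for c in self.clonotypes if c.junction_aa}
        if level == "nt":
            return {c.junction_nt for c in self.clonotypes}
        raise ValueError(f"unknown CDR3 level {level!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_id": f"{self.sample_id}-{i}",
                "v_call": c.v_name,
                "j_call": c.j_name,
                "junction": c.junction_nt,
                "junction_aa": c.junction_aa,
                "duplicate_count": c.abundance,
                "productive": "T" if c.productive else "F",
                "insert_len": c.insert_len,
                "v_deleted": c.v_deleted,
                "j_deleted": c.j_deleted,
            }
            for i, c in enumerate(sorted(self.clonotypes, key=lambda c: c.key))
        ]
        cols = [
            "sequence_id", "v_call", "j_call", "junction", "junction_aa",
            "duplicate_count", "productive", "insert_len", "v_deleted",
            "j_deleted",
        ]
        return pd.DataFrame(rows, columns=cols)


def _parse_productive(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().upper()
    return s in ("T", "TRUE", "1")


def read_airr(
    path: str | Path,
    sample_id: str | None = None,
    life_stage: str = "adult",
    cell_type: str = "DP",
    chain: str = "TRB",
) -> RepertoireSample:
    """Read an AIRR Rearrangement TSV into a :class:`RepertoireSample`.

    Rows sharing (v_call, j_call, junction) are merged, summing
    duplicate_count.  Sample metadata is supplied by the caller (CLI
    flags or a manifest row) since AIRR files carry none.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        return RepertoireSample(sample_id or path.stem, life_stage, cell_type, chain)

    df["duplicate_count"] = pd.to_numeric(df["duplicate_count"]).astype(int)
    agg: dict[str, object] = {"duplicate_count": "sum"}
    for opt in ("junction_aa", "productive", "insert_len", "v_deleted", "j_deleted"):
        if opt in df.columns:
            agg[opt] = "first"
    merged = (
        df.groupby(["v_call", "j_call", "junction"], sort=False, dropna=False)
        .agg(agg)
        .reset_index()
    )

    def _opt_int(row, col):
        if col not in merged.columns or pd.isna(row[col]) or row[col] == "":
            return None
        return int(float(row[col]))

    clonotypes = []
    for _, row in merged.iterrows():
        clonotypes.append(
            Clonotype(
                v_name=row["v_call"],
                j_name=row["j_call"],
                junction_nt=row["junction"],
                abundance=int(row["duplicate_count"]),
                productive=_parse_productive(row.get("productive", "F")),
                junction_aa=(
                    "" if "junction_aa" not in merged.columns or pd.isna(row["junction_aa"])
                    else str(row["junction_aa"])
                ),
                insert_len=_opt_int(row, "insert_len"),
                v_deleted=_opt_int(row, "v_deleted"),
                j_deleted=_opt_int(row, "j_deleted"),
            )
        )
    return RepertoireSample(
        sample_id or path.stem, life_stage, cell_type, chain, clonotypes
    )


def write_airr(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample as AIRR TSV with deterministic row order."""
    for c in sample.clonotypes:
        if set(c.junction_nt) - set("ACGT"):
            logger.warning(
                "non-ACGT junction written verbatim: %r", c.junction_nt
            )
    sample.to_frame().to_csv(path, sep="\t", index=False)


def validate_sample(sample: RepertoireSample) -> list[str]:
    """Return a list of human-readable consistency issues (empty = valid)."""
    issues: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    for c in sample.clonotypes:
        if c.key in seen:
            issues.append(f"duplicate clonotype key {c.key}")
        seen.add(c.key)
        if c.abundance < 1:
            issues.append(f"non-positive abundance for {c.key}")
        if c.productive:
            if len(c.junction_nt) % 3 != 0:
                issues.append(
                    f"productive clonotype with out-of-frame junction {c.key}"
                )
            if not c.junction_aa:
                issues.append(
                    f"productive clonotype without junction_aa {c.key}"
                )
    return issues


def read_manifest(path: str | Path) -> list[RepertoireSample]:
    """Load samples listed in a manifest TSV.

    Columns: path, sample_id, life_stage, cell_type, chain.  Relative
    paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"path", "sample_id", "life_stage", "cell_type", "chain"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        samples.append(
            read_airr(p, row.sample_id, row.life_stage, row.cell_type, row.chain)
        )
    return samples
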