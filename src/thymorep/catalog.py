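"""Germline V/J segment catalogs.

A catalog holds ordered germline segments for both TCR chains, with
junction-proximal nucleotide sequence, CDR1/CDR2 annotation for V
segments, and per-V selection weights used by the simulator's positive
selection stage.  Chromosomal order is always taken from the catalog's
``chromosomal_index`` (never parsed from segment names).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["GermlineSegment", "SegmentCatalog", "build_catalog"]

_NT = np.array(list("ACGT"))
# codons that never translate to a stop, used for germline backbones
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V or J gene segment.

    ``junction_seq`` is the junction-proximal germline region: for V
    segments it starts at the conserved cysteine codon and extends 3';
    for J segments it ends at the conserved phenylalanine codon.
    """

    name: str
    chain: str  # TRA | TRB
    kind: str  # V | J
    chromosomal_index: int  # 0-based rank in 5'->3' order
    junction_seq: str
    frame_offset: int = 0
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    cluster_id: int = 0  # TRBJ only: 1 or 2

    def __post_init__(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.kind not in ("V", "J"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.junction_seq or set(self.junction_seq) - set("ACGT"):
            raise ValueError("junction_seq must be non-empty over ACGT")
        if (self.kind == "J") != (self.cdr1_aa == "" and self.cdr2_aa == ""):
            raise ValueError("cdr1_aa/cdr2_aa must be empty iff kind == J")


@dataclass
class SegmentCatalog:
    """Ordered germline segments plus per-V selection weights."""

    segments: list[GermlineSegment]
    selection_weights: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {s.name: s for s in self.segments}
        seen: set[tuple[str, str, int]] = set()
        for s in self.segments:
            key = (s.chain, s.kind, s.chromosomal_index)
            if key in seen:
                raise ValueError(f"duplicate chromosomal_index {key}")
            seen.add(key)

    def get(self, name: str) -> GermlineSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown segment name {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def axis(self, chain: str, kind: str) -> list[GermlineSegment]:
        """Segments of one (chain, kind) in chromosomal (5'->3') order."""
        sel = [s for s in self.segments if s.chain == chain and s.kind == kind]
        return sorted(sel, key=lambda s: s.chromosomal_index)

    def names(self, chain: str, kind: str) -> list[str]:
        return [s.name for s in self.axis(chain, kind)]

    def selection_weight(self, v_name: str, lineage: str) -> float:
        w4, w8 = self.selection_weights[v_name]
        if lineage == "SP4":
            return w4
        if lineage == "SP8":
            return w8
        raise ValueError(f"no selection weight for lineage {lineage!r}")

    # ------------------------------------------------------------------
    # TSV round trip
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            w4, w8 = self.selection_weights.get(s.name, (np.nan, np.nan))
            rows.append(
                {**dataclasses.asdict(s), "w_sp4": w4, "w_sp8": w8}
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        # shortest round-trip-exact float representation for the weights
        for col in ("w_sp4", "w_sp8"):
            df[col] = df[col].map(repr)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SegmentCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"cdr1_aa": str, "cdr2_aa": str},
                         float_precision="round_trip")
        df = df.fillna({"cdr1_aa": "", "cdr2_aa": ""})
        segs = [
            GermlineSegment(
                name=r.name,
                chain=r.chain,
                kind=r.kind,
                chromosomal_index=int(r.chromosomal_index),
                junction_seq=r.junction_seq,
                frame_offset=int(r.frame_offset),
                cdr1_aa=r.cdr1_aa,
                cdr2_aa=r.cdr2_aa,
                cluster_id=int(r.cluster_id),
            )
            for r in df.itertuples(index=False)
        ]
        weights = {
            r.name: (float(r.w_sp4), float(r.w_sp8))
            for r in df.itertuples(index=False)
            if r.kind == "V" and np.isfinite(r.w_sp4)
        }
        return cls(segs, weights)


def _random_cdr(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    while True:
        s = "".join(rng.choice(_AA20, size=length))
        if s not in taken:
            taken.add(s)
            return s


def _v_junction(rng: np.random.Generator) -> str:
    # conserved Cys codon followed by 2-4 stop-free germline codons
    n_extra = int(rng.integers(2, 5))
    return "TGT" + "".join(rng.choice(_SAFE_CODONS, size=n_extra))


def _j_junction(rng: np.random.Generator) -> str:
    # 2-4 stop-free codons ending in the conserved Phe codon
    n_extra = int(rng.integers(2, 5))
    return "".join(rng.choice(_SAFE_CODONS, size=n_extra)) + "TTT"


def build_catalog(
    n_trav: int = 98,
    n_traj: int = 60,
    n_trbv: int = 22,
    n_trbj: int = 12,
    seed: int = 0,
    selection_weight_sigma: float = 1.0,
) -> SegmentCatalog:
    """Build a deterministic pseudo-random segment catalog.

    Segment counts default to a mouse-like scale.  TRBJ segments are
    split evenly into two clusters (cluster_id 1 then 2 along the
    chromosome).  Each V segment receives a unique CDR1 x CDR2 pair and
    a pair of log-normal selection weights (SP4, SP8) used by
    :func:`thymorep.simulate.apply_selection`.
    """
    for label, n in (("n_trav", n_trav), ("n_traj", n_traj),
                     ("n_trbv", n_trbv), ("n_trbj", n_trbj)):
        if n < 2:
            raise ValueError(f"{label} must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    taken_cdr: set[str] = set()
    segments: list[GermlineSegment] = []
    weights: dict[str, tuple[float, float]] = {}

    for chain, kind, n in (
        ("TRA", "V", n_trav),
        ("TRA", "J", n_traj),
        ("TRB", "V", n_trbv),
        ("TRB", "J", n_trbj),
    ):
        for i in range(n):
            name = f"{chain}{kind}SIM{i + 1}"
            if kind == "V":
                seg = GermlineSegment(
                    name=name,
                    chain=chain,
                    kind=kind,
                    chromosomal_index=i,
                    junction_seq=_v_junction(rng),
                    cdr1_aa=_random_cdr(rng, 5, taken_cdr),
                    cdr2_aa=_random_cdr(rng, 6, taken_cdr),
                )
                weights[name] = (
                    float(np.exp(rng.normal(0.0, selection_weight_sigma))),
                    float(np.exp(rng.normal(0.0, selection_weight_sigma))),
                )
            else:
                cluster = 0
                if chain == "TRB":
                    cluster = 1 if i < (n + 1) // 2 else 2
                seg = GermlineSegment(
                    name=name,
                    chain=chain,
                    kind=kind,
                    chromosomal_index=i,
                    junction_seq=_j_junction(rng),
                    cluster_id=cluster,
                )
            segments.append(seg)

    return SegmentCatalog(segments, weights)
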