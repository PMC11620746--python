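"""Junction features: productivity, decomposition, CDR statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import GermlineSegment, SegmentCatalog
from .io import RepertoireSample

__all__ = [
    "JunctionDecomposition",
    "translate",
    "classify_productivity",
    "decompose_junction",
    "weighted_mean_insert_length",
    "mean_unique_cdr3_length",
    "nonproductive_fraction",
    "cdr12_counts",
]

_CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string ('*' marks stop codons)."""
    if len(nt) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    return "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def classify_productivity(junction_nt: str) -> tuple[bool, str]:
    """Classify a junction as productive, naming the first failed rule.

    Productive requires: in-frame length, no stop codon, cysteine first
    codon, phenylalanine/tryptophan last codon.
    """
    if not junction_nt or set(junction_nt) - set("ACGT"):
        raise ValueError("junction must be non-empty over ACGT")
    if len(junction_nt) % 3 != 0:
        return False, "frame"
    aa = translate(junction_nt)
    if "*" in aa:
        return False, "stop"
    if aa[0] != "C":
        return False, "anchor_c"
    if aa[-1] not in "FW":
        return False, "anchor_fw"
    return True, "productive"


@dataclass(frozen=True)
class JunctionDecomposition:
    """Split of a junction into V match, insert, and J match."""

    v_match_len: int
    j_match_len: int
    insert_len: int
    v_deleted: int
    j_deleted: int

    def __post_init__(self) -> None:
        if min(
            self.v_match_len, self.j_match_len, self.insert_len,
            self.v_deleted, self.j_deleted,
        ) < 0:
            raise ValueError("decomposition fields must be non-negative")


def decompose_junction(
    junction_nt: str, v: GermlineSegment, j: GermlineSegment
) -> JunctionDecomposition:
    """Greedy maximal contiguous germline matching of a junction.

    The V match is the longest common prefix of the junction with the V
    junction-proximal germline; the J match is the longest common suffix
    of the remainder with the J germline.  Whatever is left in between is
    the insert (which, for beta chains, deliberately includes D-region
    nucleotides).
    """
    v_seq, j_seq = v.junction_seq, j.junction_seq
    v_match = 0
    limit = min(len(junction_nt), len(v_seq))
    while v_match < limit and junction_nt[v_match] == v_seq[v_match]:
        v_match += 1
    rest = junction_nt[v_match:]
    j_match = 0
    limit = min(len(rest), len(j_seq))
    while j_match < limit and rest[len(rest) - 1 - j_match] == j_seq[len(j_seq) - 1 - j_match]:
        j_match += 1
    insert = len(junction_nt) - v_match - j_match
    return JunctionDecomposition(
        v_match_len=v_match,
        j_match_len=j_match,
        insert_len=insert,
        v_deleted=len(v_seq) - v_match,
        j_deleted=len(j_seq) - j_match,
    )


def weighted_mean_insert_length(
    sample: RepertoireSample, catalog: SegmentCatalog | None = None
) -> float:
    """Abundance-weighted mean insert length over all rearrangements.

    Uses stored per-clonotype insert annotations when present,
    otherwise infers them by :func:`decompose_junction` against the
    catalog.
    """
    num = den = 0
    for c in sample.clonotypes:
        ins = c.insert_len
        if ins is None:
            if catalog is None:
                raise ValueError(
                    "clonotypes lack insert_len and no catalog was given"
                )
            ins = decompose_junction(
                c.junction_nt, catalog.get(c.v_name), catalog.get(c.j_name)
            ).insert_len
        num += c.abundance * ins
        den += c.abundance
    if den == 0:
        raise ValueError("empty sample")
    return num / den


def mean_unique_cdr3_length(sample: RepertoireSample) -> float:
    """Unweighted mean amino-acid CDR3 length over unique productive clonotypes."""
    lengths = [len(c.junction_aa) for c in sample.clonotypes if c.productive]
    if not lengths:
        raise ValueError("no productive clonotypes")
    return float(np.mean(lengths))


def nonproductive_fraction(sample: RepertoireSample, weighting: str = "total") -> float:
    """Fraction of non-productive rearrangements.

    ``total`` weights by abundance (default); ``unique`` counts each
    clonotype once.
    """
    if not sample.clonotypes:
        raise ValueError("empty sample")
    if weighting == "total":
        bad = sum(c.abundance for c in sample.clonotypes if not c.productive)
        return bad / sample.total_abundance
    if weighting == "unique":
        return sum(not c.productive for c in sample.clonotypes) / len(sample)
    raise ValueError(f"unknown weighting {weighting!r}")


def cdr12_counts(
    sample: RepertoireSample, catalog: SegmentCatalog, weighting: str = "unique"
) -> dict[tuple[str, str], float]:
    """Count clonotypes per (CDR1, CDR2) pair of their V segment.

    V segments sharing a CDR1 x CDR2 pair pool into one bin.
    """
    if weighting not in ("unique", "total"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts: dict[tuple[str, str], float] = {}
    for c in sample.clonotypes:
        v = catalog.get(c.v_name)
        key = (v.cdr1_aa, v.cdr2_aa)
        counts[key] = counts.get(key, 0) + (
            1 if weighting == "unique" else c.abundance
        )
    return counts
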