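"""Rarefaction engine and diversity indices (Shannon, Gini, Jaccard)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RepertoireSample

__all__ = [
    "RarefiedStatistic",
    "rarefy",
    "shannon_entropy",
    "gini_index",
    "jaccard_similarity",
    "rarefied_index",
    "intra_group_jaccard",
]


@dataclass(frozen=True)
class RarefiedStatistic:
    statistic: str
    depth: int
    n_repeats: int
    seed: int
    mean: float
    per_repeat: np.ndarray

    def __post_init__(self) -> None:
        if len(self.per_repeat) != self.n_repeats:
            raise ValueError("per_repeat length must equal n_repeats")


def _counts_of(sample) -> np.ndarray:
    if isinstance(sample, RepertoireSample):
        return sample.abundances()
    return np.asarray(sample, dtype=np.int64)


def rarefy(sample, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample ``depth`` molecules without replacement.

    Every one of the sum-of-abundance molecules is equally likely
    (multivariate hypergeometric); returns per-clonotype counts (zeros
    kept) summing to ``depth``.
    """
    counts = _counts_of(sample)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total abundance {total}")
    return rng.multivariate_hypergeometric(counts, depth)


def shannon_entropy(counts, base: float | None = None) -> float:
    """H = -sum p_i log p_i (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.min(initial=0) < 0 or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive sum")
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def gini_index(counts) -> float:
    """Gini inequality of a unique-clonotype abundance vector.

    Equals sum_ij |x_i - x_j| / (2 n^2 mean), computed via the sorted
    O(n log n) identity.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 clonotypes")
    if x[0] < 0 or x.sum() <= 0:
        raise ValueError("counts must be non-negative with positive sum")
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * x.sum()))


def jaccard_similarity(set_a: set, set_b: set) -> float:
    """|A intersection B| / |A union B|."""
    if not set_a and not set_b:
        raise ValueError("both sets empty")
    return len(set_a & set_b) / len(set_a | set_b)


def _subsample_set(items: list, depth: int, rng: np.random.Generator) -> set:
    if depth > len(items):
        raise ValueError(f"depth {depth} exceeds set size {len(items)}")
    if depth == len(items):
        return set(items)
    idx = rng.choice(len(items), size=depth, replace=False)
    return {items[i] for i in idx}


def rarefied_index(
    samples,
    statistic: str,
    depth: int,
    n_repeats: int = 1000,
    seed: int = 0,
    cdr3_level: str = "aa",
) -> RarefiedStatistic:
    """Mean diversity index over repeated rarefaction.

    ``shannon``/``gini`` take one sample: each repeat draws ``depth``
    molecules without replacement and evaluates the index on the
    subsampled abundance vector (clonotypes absent from the subsample
    are dropped, not zero-padded).  ``jaccard`` takes a pair of samples:
    each repeat draws ``depth`` distinct CDR3 strings uniformly from
    each sample's CDR3 set.
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_repeats)
    if statistic in ("shannon", "gini"):
        sample = samples[0] if isinstance(samples, (list, tuple)) else samples
        counts = _counts_of(sample)
        fn = shannon_entropy if statistic == "shannon" else gini_index
        for r in range(n_repeats):
            sub = rarefy(counts, depth, rng)
            values[r] = fn(sub[sub > 0])
    elif statistic == "jaccard":
        a, b = samples
        items_a = sorted(a.cdr3_set(cdr3_level))
        items_b = sorted(b.cdr3_set(cdr3_level))
        for r in range(n_repeats):
            values[r] = jaccard_similarity(
                _subsample_set(items_a, depth, rng),
                _subsample_set(items_b, depth, rng),
            )
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return RarefiedStatistic(
        statistic=statistic,
        depth=depth,
        n_repeats=n_repeats,
        seed=seed,
        mean=float(values.mean()),
        per_repeat=values,
    )


def intra_group_jaccard(
    samples: list[RepertoireSample],
    depth: int,
    n_repeats: int = 1000,
    seed: int = 0,
    cdr3_level: str = "aa",
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise rarefied Jaccard within a group of samples.

    Returns (symmetric matrix with NaN diagonal, per-sample mean over
    the other samples).
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for k in range(i + 1, n):
            stat = rarefied_index(
                (samples[i], samples[k]), "jaccard", depth, n_repeats,
                seed=seed + 7919 * i + k, cdr3_level=cdr3_level,
            )
            mat[i, k] = mat[k, i] = stat.mean
    means = np.nanmean(mat, axis=1)
    return mat, means
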