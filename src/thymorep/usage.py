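"""V/J and V x J segment usage tables and differential tiling.

All axes are ordered by the catalog's chromosomal index (5' to 3').
``unique`` weighting counts each clonotype once; ``total`` weighting is
abundance-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .catalog import SegmentCatalog
from .io import RepertoireSample

__all__ = [
    "usage_vector",
    "vxj_matrix",
    "group_mean_heatmap",
    "benjamini_hochberg",
    "differential_vxj",
]

TILE_CATEGORIES = (
    "increased", "decreased", "no_change",
    "absent_A", "absent_B", "absent_both", "not_compared",
)


def _weights(sample: RepertoireSample, weighting: str) -> np.ndarray:
    if weighting == "unique":
        return np.ones(len(sample.clonotypes))
    if weighting == "total":
        return sample.abundances().astype(float)
    raise ValueError(f"unknown weighting {weighting!r}")


def usage_vector(
    sample: RepertoireSample,
    axis: str,
    weighting: str,
    catalog: SegmentCatalog,
) -> pd.Series:
    """Proportional segment usage over the full catalog axis."""
    if axis not in ("V", "J"):
        raise ValueError(f"axis must be 'V' or 'J', got {axis!r}")
    names = catalog.names(sample.chain, axis)
    index = {n: i for i, n in enumerate(names)}
    w = _weights(sample, weighting)
    out = np.zeros(len(names))
    for c, wi in zip(sample.clonotypes, w):
        name = c.v_name if axis == "V" else c.j_name
        if name not in index:
            raise KeyError(f"segment {name!r} not in catalog")
        out[index[name]] += wi
    total = out.sum()
    if total > 0:
        out /= total
    return pd.Series(out, index=names, name=sample.sample_id)


def vxj_matrix(
    sample: RepertoireSample, weighting: str, catalog: SegmentCatalog
) -> pd.DataFrame:
    """V x J count grid (rows = V, cols = J, chromosomal order)."""
    v_names = catalog.names(sample.chain, "V")
    j_names = catalog.names(sample.chain, "J")
    vi = {n: i for i, n in enumerate(v_names)}
    ji = {n: i for i, n in enumerate(j_names)}
    grid = np.zeros((len(v_names), len(j_names)))
    w = _weights(sample, weighting)
    for c, wi in zip(sample.clonotypes, w):
        if c.v_name not in vi:
            raise KeyError(f"segment {c.v_name!r} not in catalog")
        if c.j_name not in ji:
            raise KeyError(f"segment {c.j_name!r} not in catalog")
        grid[vi[c.v_name], ji[c.j_name]] += wi
    return pd.DataFrame(grid, index=v_names, columns=j_names)


def group_mean_heatmap(
    groups: dict[str, list[RepertoireSample]],
    axis: str,
    weighting: str,
    catalog: SegmentCatalog,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Group-mean usage matrix plus a column dendrogram.

    Columns (groups) are clustered by average-linkage hierarchical
    clustering on Euclidean distance; rows keep fixed chromosomal order
    and are never clustered.
    """
    cols = {}
    for label, samples in groups.items():
        if not samples:
            raise ValueError(f"empty group {label!r}")
        vectors = [usage_vector(s, axis, weighting, catalog) for s in samples]
        cols[label] = pd.concat(vectors, axis=1).mean(axis=1)
    matrix = pd.DataFrame(cols)
    linkage = None
    if matrix.shape[1] > 1:
        linkage = hierarchy.linkage(
            pdist(matrix.T.to_numpy(), metric="euclidean"), method="average"
        )
    return matrix, linkage


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DifferentialUsageResult:
    """Tile table for one group-pair comparison over the V x J grid."""

    table: pd.DataFrame  # columns: v, j, detected_a, detected_b, mean_a, mean_b, p, q, tile
    min_detected: int
    alpha: float

    def tiles(self, category: str) -> pd.DataFrame:
        return self.table[self.table.tile == category]


def differential_vxj(
    group_a: list[RepertoireSample],
    group_b: list[RepertoireSample],
    catalog: SegmentCatalog,
    weighting: str = "total",
    min_detected: int = 3,
    alpha: float = 0.05,
) -> DifferentialUsageResult:
    """Differential V x J combination usage between two sample groups.

    Per-sample proportions of each combination are compared by unpaired
    Student's t-test for combinations detected (count > 0) in at least
    ``min_detected`` samples of each group; p-values are BH-adjusted
    jointly across all compared combinations of this panel.  Tiles:
    ``increased``/``decreased`` (in group A, q < alpha), ``no_change``,
    ``absent_A``/``absent_B``/``absent_both`` (zero detections in the
    named group(s)), ``not_compared`` (detected but below
    ``min_detected`` in either group).
    """
    if len(group_a) < min_detected or len(group_b) < min_detected:
        raise ValueError("each group needs at least min_detected samples")

    def _props(samples):
        mats = []
        for s in samples:
            m = vxj_matrix(s, weighting, catalog)
            total = m.to_numpy().sum()
            mats.append(m / total if total > 0 else m)
        return mats

    props_a, props_b = _props(group_a), _props(group_b)
    v_names = props_a[0].index
    j_names = props_a[0].columns
    stack_a = np.stack([m.to_numpy() for m in props_a])  # samples x V x J
    stack_b = np.stack([m.to_numpy() for m in props_b])
    det_a = (stack_a > 0).sum(axis=0)
    det_b = (stack_b > 0).sum(axis=0)

    rows = []
    test_idx = []
    for i, v in enumerate(v_names):
        for k, j in enumerate(j_names):
            da, db = int(det_a[i, k]), int(det_b[i, k])
            if da == 0 and db == 0:
                tile = "absent_both"
            elif da == 0:
                tile = "absent_A"
            elif db == 0:
                tile = "absent_B"
            elif da < min_detected or db < min_detected:
                tile = "not_compared"
            else:
                tile = "compared"
            rows.append(
                dict(
                    v=v, j=j, detected_a=da, detected_b=db,
                    mean_a=float(stack_a[:, i, k].mean()),
                    mean_b=float(stack_b[:, i, k].mean()),
                    p=np.nan, q=np.nan, tile=tile,
                )
            )
            if tile == "compared":
                test_idx.append((len(rows) - 1, i, k))

    if test_idx:
        ps = []
        for _, i, k in test_idx:
            a_vals, b_vals = stack_a[:, i, k], stack_b[:, i, k]
            if np.ptp(a_vals) == 0 and np.ptp(b_vals) == 0 and a_vals[0] == b_vals[0]:
                ps.append(1.0)  # degenerate: identical constant groups
                continue
            p = stats.ttest_ind(a_vals, b_vals, equal_var=True).pvalue
            ps.append(1.0 if np.isnan(p) else float(p))
        qs = benjamini_hochberg(ps)
        for (row_i, i, k), p, q in zip(test_idx, ps, qs):
            row = rows[row_i]
            row["p"], row["q"] = p, float(q)
            if q < alpha:
                row["tile"] = "increased" if row["mean_a"] > row["mean_b"] else "decreased"
            else:
                row["tile"] = "no_change"

    return DifferentialUsageResult(pd.DataFrame(rows), min_detected, alpha)
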