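"""End-to-end cohort orchestration.

``run_cohort`` simulates (or accepts) a cohort of repertoires and emits
tidy result tables: per-sample abundance and junction statistics,
rarefied diversity, intra-group sharing, group-mean heatmaps,
differential V x J tiles, and PCAs, with every random stage seeded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .abundance import clonality_stats, fit_power_law
from .catalog import SegmentCatalog, build_catalog
from .cdr import (
    cdr12_counts,
    mean_unique_cdr3_length,
    nonproductive_fraction,
    weighted_mean_insert_length,
)
from .diversity import intra_group_jaccard, rarefied_index
from .io import RepertoireSample
from .pca import log_z_transform, run_pca
from .simulate import preset, simulate_sample
from .usage import differential_vxj, group_mean_heatmap, vxj_matrix

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "scalar_group_test", "run_cohort", "vxj_feature_table",
           "cdr12_feature_table"]


@dataclass
class CohortConfig:
    """Study-level simulation/analysis configuration."""

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("foetal", 7), ("adult", 6)]
    )
    cell_types: list[str] = field(default_factory=lambda: ["DP", "SP4", "SP8"])
    chains: list[str] = field(default_factory=lambda: ["TRB", "TRA"])
    n_clonotypes: int = 3000
    catalog_seed: int = 0
    root_seed: int = 0
    rarefaction_depth: dict[str, int] = field(
        default_factory=lambda: {"DP": 2000, "SP4": 500, "SP8": 500}
    )
    jaccard_depth: dict[str, int] = field(
        default_factory=lambda: {"DP": 500, "SP4": 200, "SP8": 200}
    )
    n_repeats: int = 100
    out_dir: str | Path = "results"

    def __post_init__(self) -> None:
        for _, n in self.groups:
            if n < 1:
                raise ValueError("n_individuals must be >= 1")
        for d in (*self.rarefaction_depth.values(), *self.jaccard_depth.values()):
            if d < 1:
                raise ValueError("depths must be positive")


def scalar_group_test(values_a, values_b) -> tuple[float, float, str]:
    """Two-sided two-sample t-test, Student or Welch by a Levene pre-test.

    Levene's test (mean-centred) at alpha = 0.05 decides whether the
    equal-variance (Student) or unequal-variance (Welch) form is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        equal_var = True
    else:
        equal_var = stats.levene(a, b, center="mean").pvalue >= 0.05
    name = "student" if equal_var else "welch"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    stat = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    return stat, p, name


def simulate_cohort(
    config: CohortConfig, catalog: SegmentCatalog
) -> dict[tuple[str, str, str], list[RepertoireSample]]:
    """Simulate every (life_stage, cell_type, chain) group of the cohort."""
    cohort: dict[tuple[str, str, str], list[RepertoireSample]] = {}
    seed = config.root_seed
    for stage, n_ind in config.groups:
        for cell_type in config.cell_types:
            for chain in config.chains:
                samples = []
                for i in range(n_ind):
                    cfg = preset(stage, cell_type, chain).replace(
                        n_clonotypes=config.n_clonotypes, seed=seed
                    )
                    seed += 1
                    samples.append(simulate_sample(cfg, catalog))
                cohort[(stage, cell_type, chain)] = samples
    return cohort


def vxj_feature_table(
    samples: list[RepertoireSample],
    catalog: SegmentCatalog,
    weighting: str = "unique",
) -> pd.DataFrame:
    """Samples x (VxJ) feature count matrix for PCA."""
    rows = {}
    for s in samples:
        m = vxj_matrix(s, weighting, catalog)
        rows[s.sample_id] = m.to_numpy().ravel()
    m0 = vxj_matrix(samples[0], weighting, catalog)
    features = [f"{v}|{j}" for v in m0.index for j in m0.columns]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = features
    return df.loc[:, df.sum(axis=0) > 0]


def cdr12_feature_table(
    samples: list[RepertoireSample],
    catalog: SegmentCatalog,
    weighting: str = "unique",
) -> pd.DataFrame:
    """Samples x (CDR1 x CDR2) feature count matrix for PCA."""
    rows = {
        s.sample_id: {
            f"{c1}-{c2}": v
            for (c1, c2), v in cdr12_counts(s, catalog, weighting).items()
        }
        for s in samples
    }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def _per_sample_stats(samples, catalog) -> pd.DataFrame:
    rows = []
    for s in samples:
        fit = fit_power_law(s.abundances())
        clon = clonality_stats(s) if len(s) >= 100 else None
        rows.append(
            dict(
                sample_id=s.sample_id,
                life_stage=s.life_stage,
                cell_type=s.cell_type,
                chain=s.chain,
                n_clonotypes=len(s),
                total_abundance=s.total_abundance,
                power_law_alpha=fit.alpha if fit.converged else np.nan,
                top1pct_share=clon.top_share if clon else np.nan,
                mean_top_abundance=clon.mean_top_abundance if clon else np.nan,
                nonproductive_fraction=nonproductive_fraction(s),
                mean_insert_len=weighted_mean_insert_length(s, catalog),
                mean_cdr3_len=mean_unique_cdr3_length(s),
            )
        )
    return pd.DataFrame(rows)


def run_cohort(
    config: CohortConfig,
    catalog: SegmentCatalog | None = None,
    cohort: dict[tuple[str, str, str], list[RepertoireSample]] | None = None,
) -> dict:
    """Run the full analysis battery over a (simulated) cohort.

    Returns the result bundle as a dict and writes TSV/JSON tables under
    ``config.out_dir``.  Deterministic for a fixed configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if catalog is None:
        catalog = build_catalog(seed=config.catalog_seed)
    if cohort is None:
        cohort = simulate_cohort(config, catalog)

    bundle: dict = {"config": config, "catalog": catalog, "cohort": cohort}

    all_samples = [s for group in cohort.values() for s in group]
    sample_stats = _per_sample_stats(all_samples, catalog)
    sample_stats.to_csv(out / "sample_stats.tsv", sep="\t", index=False)
    bundle["sample_stats"] = sample_stats

    # rarefied diversity per group
    div_rows = []
    for (stage, cell_type, chain), samples in cohort.items():
        depth = config.rarefaction_depth.get(cell_type, 500)
        for s in samples:
            if s.total_abundance < depth:
                logger.warning(
                    "skipping rarefied indices for %s: depth %d infeasible",
                    s.sample_id, depth,
                )
                continue
            for stat_name in ("shannon", "gini"):
                r = rarefied_index(
                    s, stat_name, depth, config.n_repeats, seed=config.root_seed
                )
                div_rows.append(
                    dict(
                        sample_id=s.sample_id, life_stage=stage,
                        cell_type=cell_type, chain=chain,
                        statistic=stat_name, depth=depth, mean=r.mean,
                    )
                )
    diversity = pd.DataFrame(div_rows)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    bundle["diversity"] = diversity

    # intra-group CDR3 sharing
    jac_rows = []
    for (stage, cell_type, chain), samples in cohort.items():
        if len(samples) < 2:
            logger.warning("skipping intra-group Jaccard for group of 1")
            continue
        depth = config.jaccard_depth.get(cell_type, 200)
        min_set = min(len(s.cdr3_set()) for s in samples)
        if min_set < depth:
            logger.warning(
                "skipping Jaccard for (%s, %s, %s): depth %d infeasible",
                stage, cell_type, chain, depth,
            )
            continue
        _, means = intra_group_jaccard(
            samples, depth, config.n_repeats, seed=config.root_seed
        )
        for s, m in zip(samples, means):
            jac_rows.append(
                dict(
                    sample_id=s.sample_id, life_stage=stage,
                    cell_type=cell_type, chain=chain,
                    mean_jaccard=m, depth=depth,
                )
            )
    jaccard = pd.DataFrame(jac_rows)
    jaccard.to_csv(out / "intra_group_jaccard.tsv", sep="\t", index=False)
    bundle["intra_group_jaccard"] = jaccard

    # between-group scalar comparisons
    stages = [g for g, _ in config.groups]
    scalar_rows = []
    scalar_cols = [
        "power_law_alpha", "top1pct_share", "nonproductive_fraction",
        "mean_insert_len", "mean_cdr3_len",
    ]
    for cell_type in config.cell_types:
        for chain in config.chains:
            for ia in range(len(stages)):
                for ib in range(ia + 1, len(stages)):
                    sel = sample_stats[
                        (sample_stats.cell_type == cell_type)
                        & (sample_stats.chain == chain)
                    ]
                    a = sel[sel.life_stage == stages[ia]]
                    b = sel[sel.life_stage == stages[ib]]
                    if len(a) < 2 or len(b) < 2:
                        logger.warning("skipping scalar tests for group n < 2")
                        continue
                    for col in scalar_cols:
                        va, vb = a[col].dropna(), b[col].dropna()
                        if len(va) < 2 or len(vb) < 2:
                            continue
                        t, p, test = scalar_group_test(va, vb)
                        scalar_rows.append(
                            dict(
                                cell_type=cell_type, chain=chain,
                                group_a=stages[ia], group_b=stages[ib],
                                metric=col, mean_a=va.mean(), mean_b=vb.mean(),
                                ci95_a=_ci95(va), ci95_b=_ci95(vb),
                                statistic=t, p=p, test=test,
                            )
                        )
    scalar = pd.DataFrame(scalar_rows)
    scalar.to_csv(out / "scalar_tests.tsv", sep="\t", index=False)
    bundle["scalar_tests"] = scalar

    # differential VxJ tiles and heatmaps per cell type/chain
    tiles_frames = []
    for cell_type in config.cell_types:
        for chain in config.chains:
            groups_here = {
                stage: cohort.get((stage, cell_type, chain), [])
                for stage, _ in config.groups
            }
            groups_here = {k: v for k, v in groups_here.items() if v}
            if len(groups_here) >= 1:
                heat, _ = group_mean_heatmap(groups_here, "V", "unique", catalog)
                heat.to_csv(out / f"heatmap_V_{cell_type}_{chain}.tsv", sep="\t")
            labels = list(groups_here)
            for ia in range(len(labels)):
                for ib in range(ia + 1, len(labels)):
                    ga, gb = groups_here[labels[ia]], groups_here[labels[ib]]
                    if len(ga) < 3 or len(gb) < 3:
                        continue
                    res = differential_vxj(ga, gb, catalog)
                    t = res.table.copy()
                    t.insert(0, "chain", chain)
                    t.insert(0, "cell_type", cell_type)
                    t.insert(0, "group_a", labels[ia])
                    t.insert(0, "group_b", labels[ib])
                    tiles_frames.append(t)
    tiles = (
        pd.concat(tiles_frames, ignore_index=True)
        if tiles_frames else pd.DataFrame()
    )
    tiles.to_csv(out / "differential_vxj.tsv", sep="\t", index=False)
    bundle["differential_vxj"] = tiles

    # PCAs: joint and per life stage, on VxJ and CDR1xCDR2 features
    pca_summary = []
    for chain in config.chains:
        for features in ("vxj", "cdr12"):
            for subset in ("all", *stages):
                samples = [
                    s
                    for (stage, ct, ch), group in cohort.items()
                    for s in group
                    if ch == chain and (subset == "all" or stage == subset)
                ]
                if len(samples) < 3:
                    continue
                table = (
                    vxj_feature_table(samples, catalog)
                    if features == "vxj"
                    else cdr12_feature_table(samples, catalog)
                )
                if table.shape[1] < 2:
                    continue
                res = run_pca(log_z_transform(table))
                pca_summary.append(
                    dict(
                        chain=chain, features=features, subset=subset,
                        n_samples=len(samples),
                        pc1_pct=100 * res.variance_fraction[0],
                        pc2_pct=100 * res.variance_fraction[1],
                    )
                )
    pca_df = pd.DataFrame(pca_summary)
    pca_df.to_csv(out / "pca_summary.tsv", sep="\t", index=False)
    bundle["pca_summary"] = pca_df

    manifest = {
        "thymorep_version": __version__,
        "root_seed": config.root_seed,
        "catalog_seed": config.catalog_seed,
        "groups": config.groups,
        "cell_types": config.cell_types,
        "chains": config.chains,
        "n_clonotypes": config.n_clonotypes,
        "tables": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def _ci95(values: pd.Series) -> float:
    """Half-width of the 95% t-interval of the mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(
        stats.t.ppf(0.975, len(v) - 1) * v.std(ddof=1) / np.sqrt(len(v))
    )
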