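"""V(D)J rearrangement simulator with life-stage-dependent structure.

The generative model, per clonotype:

1. V/J segment choice.  The initial draw prefers recombination-proximal
   segments (3' V with 5' J) with geometrically decaying probability over
   rank distance.  For the alpha chain, a Poisson number of additional
   progressive rearrangement rounds each displaces the V index 5'-ward
   and the J index 3'-ward; only the final pair is emitted.  For the beta
   chain the J is drawn by first choosing one of the two J clusters.
2. Junction assembly.  Geometric germline trimming at the V 3' and J 5'
   ends (anchor codons always survive), then a geometric number of
   uniform-random non-template nucleotides.  D-region nucleotides are not
   modelled separately; they are folded into the insert.
3. Clone sizes are i.i.d. draws from the discrete power law (zeta
   distribution) with exponent ``clone_size_alpha``.
4. Single-positive populations pass a selection filter whose per-V
   weights live in the catalog; ``selection_strength`` scales how
   sharply lineage weights shape retention.

Every stage consumes a named substream of the root seed so that the
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalog import GermlineSegment, SegmentCatalog, build_catalog
from .cdr import classify_productivity, translate
from .io import CELL_TYPES, CHAINS, LIFE_STAGES, Clonotype, RepertoireSample

__all__ = [
    "SimulationConfig",
    "JunctionTruth",
    "preset",
    "draw_tra_pair",
    "draw_trb_pair",
    "make_junction",
    "assign_clone_sizes",
    "apply_selection",
    "simulate_sample",
]

logger = logging.getLogger(__name__)

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class JunctionTruth:
    """Ground-truth junction decomposition for one simulated clonotype."""

    v_deleted: int
    j_deleted: int
    insert_len: int
    insert_seq: str

    def __post_init__(self) -> None:
        if self.insert_len != len(self.insert_seq):
            raise ValueError("insert_len must equal len(insert_seq)")
        if min(self.v_deleted, self.j_deleted, self.insert_len) < 0:
            raise ValueError("junction truth fields must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameter bundle for one simulated repertoire."""

    life_stage: str
    cell_type: str
    chain: str
    n_clonotypes: int = 5000
    proximal_bias: float = 0.15
    rearrangement_rounds_mean: float = 0.0
    insert_mean: float = 2.0
    deletion_mean: float = 0.06
    clone_size_alpha: float = 2.5
    selection_strength: float = 1.0
    nonproductive_rate: float = 0.1
    trbj_cluster1_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life_stage {self.life_stage!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if self.clone_size_alpha <= 1:
            raise ValueError("clone_size_alpha must be > 1")
        for name in (
            "proximal_bias", "rearrangement_rounds_mean", "insert_mean",
            "deletion_mean", "selection_strength",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.nonproductive_rate <= 1.0:
            raise ValueError("nonproductive_rate must be in [0, 1]")
        if not 0.0 <= self.trbj_cluster1_weight <= 1.0:
            raise ValueError("trbj_cluster1_weight must be in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# Documented default parameter bundles.  Numbers are synthetic-model
# choices tuned only for direction: foetal repertoires get short inserts
# (no TdT), few progressive alpha rearrangement rounds, stronger
# proximal segment bias, a heavier clone-size tail and weaker selection;
# the hydrocortisone-recovery preset keeps adult junctions but
# foetal-like rearrangement kinetics.
_PRESETS: dict[str, dict[str, float]] = {
    "foetal": dict(
        proximal_bias=0.25,
        rearrangement_rounds_mean=0.3,
        insert_mean=1.0,
        deletion_mean=0.05,
        clone_size_alpha=2.2,
        selection_strength=0.5,
        nonproductive_rate=0.08,
        trbj_cluster1_weight=0.70,
    ),
    "adult": dict(
        proximal_bias=0.25,
        rearrangement_rounds_mean=2.0,
        insert_mean=4.0,
        deletion_mean=0.08,
        clone_size_alpha=3.0,
        selection_strength=2.0,
        nonproductive_rate=0.12,
        trbj_cluster1_weight=0.45,
    ),
}
# beta-chain overrides: no progressive rearrangement on the beta locus;
# the foetal 3'TRBV preference is expressed through a stronger proximal
# bias instead.
_PRESETS_TRB = {
    "foetal": dict(rearrangement_rounds_mean=0.0, proximal_bias=0.15),
    "adult": dict(rearrangement_rounds_mean=0.0, proximal_bias=0.03),
}


def preset(name: str, cell_type: str = "DP", chain: str = "TRB") -> SimulationConfig:
    """Documented default :class:`SimulationConfig` bundles.

    ``adult_hc`` models the post-depletion recovering thymus: adult
    junctional parameters with foetal rearrangement kinetics.
    """
    if name == "adult_hc":
        params = dict(_PRESETS["adult"])
        params["rearrangement_rounds_mean"] = _PRESETS["foetal"][
            "rearrangement_rounds_mean"
        ]
        if chain == "TRB":
            params.update(_PRESETS_TRB["adult"])
            params["proximal_bias"] = _PRESETS_TRB["foetal"]["proximal_bias"]
            params["trbj_cluster1_weight"] = _PRESETS["foetal"]["trbj_cluster1_weight"]
    elif name in _PRESETS:
        params = dict(_PRESETS[name])
        if chain == "TRB":
            params.update(_PRESETS_TRB[name])
    else:
        raise ValueError(f"unknown preset {name!r}")
    return SimulationConfig(
        life_stage=name, cell_type=cell_type, chain=chain, **params
    )


# ----------------------------------------------------------------------
# segment draws
# ----------------------------------------------------------------------

_RANK_CDF_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _geometric_rank(n: int, rate: float, rng: np.random.Generator) -> int:
    """Draw a rank in [0, n) with P(d) proportional to exp(-rate * d)."""
    if rate == 0.0:
        return int(rng.integers(n))
    cdf = _RANK_CDF_CACHE.get((n, rate))
    if cdf is None:
        w = np.exp(-rate) ** np.arange(n)
        cdf = np.cumsum(w / w.sum())
        _RANK_CDF_CACHE[(n, rate)] = cdf
    return min(n - 1, int(np.searchsorted(cdf, rng.random(), side="right")))


def _geometric_step(rng: np.random.Generator, p: float = 0.5) -> int:
    return int(rng.geometric(p))


def draw_tra_pair(
    catalog: SegmentCatalog, config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw TRA (v_index, j_index) in chromosomal coordinates.

    The initial draw favours the recombination-proximal ends (3' V, 5'
    J); each additional progressive round replaces the pair, moving V
    5'-ward and J 3'-ward by at least one segment, clamped to the locus.
    """
    n_v = len(catalog.axis("TRA", "V"))
    n_j = len(catalog.axis("TRA", "J"))
    d_v = _geometric_rank(n_v, config.proximal_bias, rng)
    d_j = _geometric_rank(n_j, config.proximal_bias, rng)
    v_index = n_v - 1 - d_v
    j_index = d_j
    rounds = int(rng.poisson(config.rearrangement_rounds_mean))
    for _ in range(rounds):
        v_index = max(0, v_index - _geometric_step(rng))
        j_index = min(n_j - 1, j_index + _geometric_step(rng))
    return v_index, j_index


def draw_trb_pair(
    catalog: SegmentCatalog, config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw TRB (v_index, j_index): proximal-biased V, cluster-weighted J."""
    v_segments = catalog.axis("TRB", "V")
    j_segments = catalog.axis("TRB", "J")
    d_v = _geometric_rank(len(v_segments), config.proximal_bias, rng)
    v_index = len(v_segments) - 1 - d_v
    cluster = 1 if rng.random() < config.trbj_cluster1_weight else 2
    members = [i for i, s in enumerate(j_segments) if s.cluster_id == cluster]
    j_index = members[int(rng.integers(len(members)))]
    return v_index, j_index


# ----------------------------------------------------------------------
# junction assembly
# ----------------------------------------------------------------------

def _geom0(mean: float, rng: np.random.Generator) -> int:
    """Geometric on {0, 1, ...} with the given mean."""
    if mean == 0.0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def make_junction(
    v: GermlineSegment,
    j: GermlineSegment,
    config: SimulationConfig,
    rng: np.random.Generator,
    frame_target: bool | None = None,
) -> tuple[str, JunctionTruth]:
    """Assemble a junction from trimmed germline ends plus an insert.

    Trimming is geometric with mean ``deletion_mean`` per end, capped so
    the conserved anchor codons survive.  The insert length is geometric
    with mean ``insert_mean`` and its nucleotides uniform.  If
    ``frame_target`` is given, the insert length is nudged to the
    nearest value that makes the total junction length (not) a multiple
    of three, which is how the simulator realises its configured
    non-productive fraction.
    """
    if v.kind != "V" or j.kind != "J" or v.chain != j.chain:
        raise ValueError("make_junction needs a V and a J of the same chain")
    v_del = min(_geom0(config.deletion_mean, rng), len(v.junction_seq) - 3)
    j_del = min(_geom0(config.deletion_mean, rng), len(j.junction_seq) - 3)
    ins = _geom0(config.insert_mean, rng)
    if frame_target is not None:
        total = (len(v.junction_seq) - v_del) + ins + (len(j.junction_seq) - j_del)
        rem = total % 3
        if frame_target and rem != 0:
            ins = ins - rem if ins >= rem else ins + (3 - rem)
        elif not frame_target and rem == 0:
            ins += 1
    insert_seq = "".join(rng.choice(_NT, size=ins)) if ins else ""
    junction = (
        v.junction_seq[: len(v.junction_seq) - v_del]
        + insert_seq
        + j.junction_seq[j_del:]
    )
    return junction, JunctionTruth(v_del, j_del, ins, insert_seq)


def assign_clone_sizes(
    n_clonotypes: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. clone sizes from the discrete power law f(k) = C k^-alpha."""
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    return stats.zipf.rvs(alpha, size=n_clonotypes, random_state=rng).astype(np.int64)


def apply_selection(
    clonotypes: list[Clonotype],
    cell_type: str,
    selection_strength: float,
    catalog: SegmentCatalog,
    rng: np.random.Generator,
) -> list[Clonotype]:
    """Positive-selection filter for SP populations.

    Retention probability is proportional to the catalog's lineage
    weight raised to ``selection_strength`` (normalised so the
    best-retained V keeps probability one).  DP-stage populations pass
    through unchanged.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    if cell_type not in ("SP4", "SP8"):
        return list(clonotypes)
    if not clonotypes:
        return []
    w = np.array(
        [catalog.selection_weight(c.v_name, cell_type) for c in clonotypes]
    )
    logp = selection_strength * np.log(w)
    p = np.exp(logp - logp.max())
    keep = rng.random(len(clonotypes)) < p
    return [c for c, k in zip(clonotypes, keep) if k]


# ----------------------------------------------------------------------
# whole-sample simulation
# ----------------------------------------------------------------------

def _substream(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, label)))


def simulate_sample(
    config: SimulationConfig, catalog: SegmentCatalog
) -> RepertoireSample:
    """Simulate one repertoire; deterministic given (config, catalog).

    Junction ground truth is carried on each clonotype's ``insert_len``,
    ``v_deleted`` and ``j_deleted`` fields.
    """
    rng_seg = _substream(config.seed, 0)
    rng_junc = _substream(config.seed, 1)
    rng_abund = _substream(config.seed, 2)
    rng_sel = _substream(config.seed, 3)

    v_axis = catalog.axis(config.chain, "V")
    j_axis = catalog.axis(config.chain, "J")
    draw_pair = draw_tra_pair if config.chain == "TRA" else draw_trb_pair

    records: dict[tuple[str, str, str], dict] = {}
    for _ in range(config.n_clonotypes):
        # productivity target is fixed per clonotype so the unique-level
        # non-productive fraction is binomial at the configured rate;
        # colliding rearrangements are redrawn, not merged
        want_productive = rng_junc.random() >= config.nonproductive_rate
        for _attempt in range(200):
            v_idx, j_idx = draw_pair(catalog, config, rng_seg)
            v, j = v_axis[v_idx], j_axis[j_idx]
            junction, truth = make_junction(
                v, j, config, rng_junc, frame_target=want_productive
            )
            productive = classify_productivity(junction)[0]
            key = (v.name, j.name, junction)
            if productive == want_productive and key not in records:
                records[key] = dict(
                    v_name=v.name,
                    j_name=j.name,
                    junction_nt=junction,
                    junction_aa=translate(junction) if productive else "",
                    productive=productive,
                    insert_len=truth.insert_len,
                    v_deleted=truth.v_deleted,
                    j_deleted=truth.j_deleted,
                )
                break
        else:
            logger.warning(
                "junction space saturated after 200 attempts; sample has "
                "%d of %d requested clonotypes", len(records), config.n_clonotypes
            )

    sizes = assign_clone_sizes(len(records), config.clone_size_alpha, rng_abund)
    clonotypes = [
        Clonotype(abundance=int(k), **rec)
        for rec, k in zip(records.values(), sizes)
    ]
    clonotypes = apply_selection(
        clonotypes, config.cell_type, config.selection_strength, catalog, rng_sel
    )
    sample_id = (
        f"{config.life_stage}-{config.cell_type}-{config.chain}-s{config.seed}"
    )
    return RepertoireSample(
        sample_id, config.life_stage, config.cell_type, config.chain, clonotypes
    )
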