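import numpy as np
import pytest

from thymorep.catalog import build_catalog
from thymorep.io import Clonotype, RepertoireSample


@pytest.fixture(scope="session")
def catalog():
    """Small seeded catalog shared across tests."""
    return build_catalog(n_trav=30, n_traj=20, n_trbv=22, n_trbj=12, seed=1)


@pytest.fixture(scope="session")
def mouse_catalog():
    """Mouse-scale catalog (98 TRAV / 60 TRAJ)."""
    return build_catalog(seed=1)


def make_sample(abundances, sample_id="s", life_stage="adult", cell_type="DP",
                chain="TRB", v="TRBVSIM1", j="TRBJSIM1"):
    """Toy sample with the given abundance vector and synthetic junctions."""
    clonotypes = []
    for i, a in enumerate(abundances):
        nt = "TGT" + "GCA" * (i % 5 + 1) + "AGC" * (i // 5 + 1) + "TTT"
        clonotypes.append(
            Clonotype(
                v_name=v, j_name=j, junction_nt=nt + "ACGT"[i % 4] * 3,
                abundance=int(a), productive=False,
            )
        )
    return RepertoireSample(sample_id, life_stage, cell_type, chain, clonotypes)


@pytest.fixture
def toy_sample():
    return make_sample([1, 1, 2, 5, 10])
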