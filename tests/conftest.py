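import numpy as np
import pytest

from mintkit.complex_triage import PredictedComplex, PredictionBundle


def make_model(n_bait: int, n_cand: int, pae: np.ndarray,
               iptm: float, rank: int = 1,
               cand_offset: np.ndarray | None = None) -> PredictedComplex:
    """In-memory two-chain model with one Cα per residue, for triage tests
    that do not need disk round-trips."""
    bait_ca = np.zeros((n_bait, 3))
    bait_ca[:, 0] = np.arange(n_bait) * 3.8
    cand_ca = np.zeros((n_cand, 3))
    cand_ca[:, 0] = np.arange(n_cand) * 3.8
    cand_ca[:, 1] = 8.0
    if cand_offset is not None:
        cand_ca = cand_ca + cand_offset
    coords = np.vstack([bait_ca, cand_ca])
    n = n_bait + n_cand
    return PredictedComplex(
        model_rank=rank,
        chain_ids=np.array(["A"] * n_bait + ["B"] * n_cand),
        residue_indices=np.array(list(range(1, n_bait + 1)) +
                                 list(range(1, n_cand + 1))),
        residue_names=np.array(["ALA"] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=coords,
        pae=pae,
        iptm=iptm,
    )


def make_bundle(iptms, inter_pae: float, n_bait: int = 8, n_cand: int = 4,
                intra_pae: float = 3.0, pair_id: str = "pair",
                offsets=None) -> PredictionBundle:
    n = n_bait + n_cand
    pae = np.full((n, n), intra_pae)
    pae[:n_bait, n_bait:] = inter_pae
    pae[n_bait:, :n_bait] = inter_pae
    if offsets is None:
        offsets = [None] * len(iptms)
    models = [make_model(n_bait, n_cand, pae.copy(), iptm, rank=i + 1,
                         cand_offset=off)
              for i, (iptm, off) in enumerate(zip(iptms, offsets))]
    return PredictionBundle(pair_id=pair_id, models=models,
                            bait_chains=["A"], candidate_chains=["B"])


@pytest.fixture
def bundle_factory():
    return make_bundle


@pytest.fixture
def model_factory():
    return make_model
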