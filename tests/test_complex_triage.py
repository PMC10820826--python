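"""Unit and property tests of the predicted-complex screening logic."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mintkit.complex_triage import (
    TriageThresholds,
    interchain_pae,
    interface_contacts,
    load_prediction_bundle,
    load_scores,
    mean_iptm,
    model_consistency,
    run_screen,
    superpose,
    triage,
)
from mintkit.synthetic_data import TriageScenario, gen_prediction_bundle
from tests.conftest import make_bundle, make_model


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def rotation_grid_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Oracle: best RMSD over finely discretised rotations (with optimal
    translation via centroid matching), refined around the best cell."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def rmsd_for(rots: Rotation) -> np.ndarray:
        moved = np.einsum("nij,pj->npi", rots.as_matrix(), mov_c)
        return np.sqrt(((moved - ref_c) ** 2).sum(-1).mean(-1))

    # coarse Euler grid, then three nested refinements around the best cell
    step = 15.0
    alphas = np.arange(0, 360, step)
    betas = np.arange(0, 180 + step, step)
    gammas = np.arange(0, 360, step)
    grid = np.array(np.meshgrid(alphas, betas, gammas)).reshape(3, -1).T
    rots = Rotation.from_euler("zyz", grid, degrees=True)
    best_idx = int(np.argmin(rmsd_for(rots)))
    best = grid[best_idx]
    for _ in range(4):
        step /= 5.0
        offsets = np.arange(-2, 3) * step
        local = (best[None, :]
                 + np.array(np.meshgrid(offsets, offsets, offsets))
                 .reshape(3, -1).T)
        rots = Rotation.from_euler("zyz", local, degrees=True)
        vals = rmsd_for(rots)
        best = local[int(np.argmin(vals))]
    return float(vals.min())


class TestSuperpose:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        out = superpose(pts, pts)
        assert out["rmsd"] < 1e-12
        assert np.allclose(out["rotation"], np.eye(3), atol=1e-9)

    def test_removes_arbitrary_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 11.0])
        out = superpose(pts, moved)
        assert out["rmsd"] < 1e-9

    def test_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            out = superpose(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
            r = out["rotation"]
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self):
        """Kabsch RMSD equals exhaustive search over discretised rotations
        on random small point sets, within discretisation tolerance."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            ref = rng.normal(size=(5, 3))
            mov = rng.normal(size=(5, 3))
            kabsch = superpose(ref, mov)["rmsd"]
            oracle = rotation_grid_rmsd(ref, mov)
            assert oracle >= kabsch - 1e-9   # Kabsch is the optimum
            assert oracle - kabsch < 0.02

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(4)
        ref, mov = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        base = superpose(ref, mov)["rmsd"]
        rot = Rotation.random(random_state=11).as_matrix()
        shift = np.array([3.0, 1.0, -7.0])
        moved = superpose(ref @ rot.T + shift, mov @ rot.T + shift)["rmsd"]
        assert moved == pytest.approx(base, abs=1e-9)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# PAE statistics
# ---------------------------------------------------------------------------

class TestInterchainPae:
    def test_constant_blocks(self, model_factory):
        m = make_model(8, 4, np.full((12, 12), 5.0), iptm=0.5)
        stats = interchain_pae(m, ["A"], ["B"], cutoff=10.0)
        assert stats == {"min": 5.0, "mean": 5.0, "frac_below_cutoff": 1.0}
        m.pae = np.full((12, 12), 30.0)
        assert interchain_pae(m, ["A"], ["B"], cutoff=10.0)["frac_below_cutoff"] == 0.0

    def test_stripe_fraction_is_area_ratio(self):
        """A 13-residue low-error stripe on a high background occupies
        exactly stripe-area / block-area of the pooled blocks."""
        n_bait, n_cand = 120, 20
        n = n_bait + n_cand
        pae = np.full((n, n), 28.0)
        pae[40:53, n_bait:] = 4.0   # 13 bait rows x all candidate cols
        pae[n_bait:, 40:53] = 4.0
        m = make_model(n_bait, n_cand, pae, iptm=0.5)
        stats = interchain_pae(m, ["A"], ["B"], cutoff=10.0)
        assert stats["min"] == 4.0
        assert stats["frac_below_cutoff"] == pytest.approx(13 / 120)

    def test_swap_invariance(self):
        rng = np.random.default_rng(5)
        pae = rng.uniform(0, 30, size=(12, 12))
        m = make_model(8, 4, pae, iptm=0.5)
        a = interchain_pae(m, ["A"], ["B"], cutoff=10.0)
        b = interchain_pae(m, ["B"], ["A"], cutoff=10.0)
        assert a == pytest.approx(b)

    def test_unknown_chain_rejected(self):
        m = make_model(8, 4, np.full((12, 12), 5.0), iptm=0.5)
        with pytest.raises(ValueError, match="unknown chain"):
            interchain_pae(m, ["A"], ["Z"])


class TestMeanIptm:
    @pytest.mark.parametrize("values, expected", [
        ((0.2, 0.3, 0.4), 0.3),
        ((0.9,), 0.9),
        ((0.31, 0.28, 0.35), (0.31 + 0.28 + 0.35) / 3),
    ])
    def test_arithmetic_mean(self, values, expected):
        bundle = make_bundle(values, inter_pae=5.0)
        assert mean_iptm(bundle) == pytest.approx(expected)

    def test_missing_iptm_rejected(self):
        bundle = make_bundle((0.5,), inter_pae=5.0)
        bundle.models[0].iptm = None
        with pytest.raises(ValueError):
            mean_iptm(bundle)


# ---------------------------------------------------------------------------
# model consistency
# ---------------------------------------------------------------------------

class TestModelConsistency:
    def test_identical_models_give_zero(self):
        bundle = make_bundle((0.5, 0.5, 0.5), inter_pae=5.0)
        assert model_consistency(bundle) == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_model_median(self):
        """One candidate chain rigidly displaced by 10 Å among three models:
        the pairwise RMSDs are {10, 10, 0} and the median is 10."""
        bundle = make_bundle(
            (0.5, 0.5, 0.5), inter_pae=5.0,
            offsets=[None, None, np.array([0.0, 0.0, 10.0])])
        assert model_consistency(bundle) == pytest.approx(10.0, abs=1e-9)

    def test_requires_two_models(self):
        bundle = make_bundle((0.5,), inter_pae=5.0)
        with pytest.raises(ValueError):
            model_consistency(bundle)

    def test_gaussian_noise_scaling(self, tmp_path):
        """Candidate chains perturbed by iid coordinate noise sd σ give a
        consistency RMSD near σ√6 (two noisy copies, three coordinates)."""
        bundle, _ = gen_prediction_bundle(
            TriageScenario(partner_size=50, coordinate_noise_sd=1.0, seed=9),
            tmp_path)
        expected = np.sqrt(6.0)
        assert model_consistency(bundle) == pytest.approx(expected, rel=0.2)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def brute_force_contacts(model, bait, candidate, cutoff):
    """O(N²) all-pairs oracle for the residue-pair contact count."""
    pairs = set()
    for i in range(len(model.coords)):
        if model.chain_ids[i] not in bait:
            continue
        for j in range(len(model.coords)):
            if model.chain_ids[j] not in candidate:
                continue
            if np.linalg.norm(model.coords[i] - model.coords[j]) <= cutoff:
                pairs.add(((model.chain_ids[i], int(model.residue_indices[i])),
                           (model.chain_ids[j], int(model.residue_indices[j]))))
    return pairs


def two_residue_model(res_a, atoms_a, res_b, atoms_b):
    """Minimal two-chain model from explicit atom listings
    (name, element, xyz)."""
    names, elements, coords, chains, res_idx, res_names = [], [], [], [], [], []
    for chain, res, atoms in (("A", res_a, atoms_a), ("B", res_b, atoms_b)):
        for name, element, xyz in atoms:
            chains.append(chain)
            res_idx.append(1)
            res_names.append(res)
            names.append(name)
            elements.append(element)
            coords.append(xyz)
    from mintkit.complex_triage import PredictedComplex
    return PredictedComplex(
        model_rank=1, chain_ids=np.array(chains),
        residue_indices=np.array(res_idx), residue_names=np.array(res_names),
        atom_names=np.array(names), elements=np.array(elements),
        coords=np.array(coords, dtype=float))


class TestInterfaceContacts:
    def test_single_pair_within_cutoff(self):
        m = two_residue_model("ALA", [("CB", "C", [0, 0, 0])],
                              "ALA", [("CB", "C", [3.0, 0, 0])])
        contacts = interface_contacts(m, ["A"], ["B"], distance_cutoff=4.0)
        assert len(contacts) == 1
        assert contacts[0]["contact_class"] == "hydrophobic"

    def test_salt_bridge_classification(self):
        m = two_residue_model(
            "GLU", [("OE1", "O", [0, 0, 0])],
            "ARG", [("NH1", "N", [3.2, 0, 0])])
        contacts = interface_contacts(m, ["A"], ["B"])
        assert contacts[0]["contact_class"] == "electrostatic"

    def test_polar_classification(self):
        m = two_residue_model("SER", [("OG", "O", [0, 0, 0])],
                              "THR", [("OG1", "O", [3.0, 0, 0])])
        contacts = interface_contacts(m, ["A"], ["B"])
        assert contacts[0]["contact_class"] == "hydrogen-bond/polar"

    def test_empty_selection_is_empty_list(self):
        m = two_residue_model("ALA", [("CB", "C", [0, 0, 0])],
                              "ALA", [("CB", "C", [50.0, 0, 0])])
        assert interface_contacts(m, ["A"], ["B"]) == []

    def test_count_matches_brute_force_on_toy_complex(self, tmp_path):
        bundle, _ = gen_prediction_bundle(TriageScenario(seed=3), tmp_path)
        model = bundle.models[0]
        contacts = interface_contacts(model, ["A"], ["B"], distance_cutoff=4.0)
        oracle = brute_force_contacts(model, {"A"}, {"B"}, 4.0)
        assert {(c["bait_residue"], c["candidate_residue"])
                for c in contacts} == oracle

    def test_count_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(12)
        n_a, n_b = 15, 10
        coords = np.vstack([rng.uniform(0, 15, size=(n_a, 3)),
                            rng.uniform(0, 15, size=(n_b, 3))])
        from mintkit.complex_triage import PredictedComplex
        m = PredictedComplex(
            model_rank=1,
            chain_ids=np.array(["A"] * n_a + ["B"] * n_b),
            residue_indices=np.array(list(range(1, n_a + 1))
                                     + list(range(1, n_b + 1))),
            residue_names=np.array(["ALA"] * (n_a + n_b)),
            atom_names=np.array(["CB"] * (n_a + n_b)),
            elements=np.array(["C"] * (n_a + n_b)),
            coords=coords)
        contacts = interface_contacts(m, ["A"], ["B"], distance_cutoff=5.0)
        oracle = brute_force_contacts(m, {"A"}, {"B"}, 5.0)
        assert {(c["bait_residue"], c["candidate_residue"])
                for c in contacts} == oracle


# ---------------------------------------------------------------------------
# triage verdicts
# ---------------------------------------------------------------------------

class TestTriage:
    def test_clear_candidate_and_clear_no_call(self):
        strong = make_bundle((0.6, 0.6, 0.6), inter_pae=5.0)
        weak = make_bundle((0.1, 0.1, 0.1), inter_pae=30.0)
        assert triage(strong).verdict == "interactor_candidate"
        assert triage(weak).verdict == "no_call"

    def test_boundary_iptm_threshold(self):
        """Mean iPTM exactly at the 0.3 gate passes; 0.29 fails, with an
        identical sparse sub-cutoff PAE signal."""
        n_bait, n_cand = 20, 8
        n = n_bait + n_cand
        pae = np.full((n, n), 28.0)
        # sparse sub-cutoff stripe: 4 of 320 pooled entries (1.25% >= 1%)
        pae[5:7, n_bait] = 9.0
        pae[n_bait, 5:7] = 9.0
        models_at = make_bundle((0.3, 0.3, 0.3), inter_pae=28.0,
                                n_bait=n_bait, n_cand=n_cand)
        for m in models_at.models:
            m.pae = pae.copy()
        assert triage(models_at).verdict == "interactor_candidate"
        below = make_bundle((0.29, 0.29, 0.29), inter_pae=28.0,
                            n_bait=n_bait, n_cand=n_cand)
        for m in below.models:
            m.pae = pae.copy()
        assert triage(below).verdict == "no_call"

    def test_single_chain_rejected(self):
        bundle = make_bundle((0.5,), inter_pae=5.0)
        m = bundle.models[0]
        m.chain_ids = np.array(["A"] * len(m.chain_ids))
        m.residue_indices = np.arange(1, len(m.chain_ids) + 1)
        m.residue_keys = [("A", int(r)) for r in m.residue_indices]
        bundle.models = [m]
        with pytest.raises(ValueError):
            triage(bundle)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, seed):
        """Raising any model's iPTM or lowering any inter-chain PAE entry
        never flips interactor_candidate → no_call."""
        rng = np.random.default_rng(seed)
        iptms = tuple(rng.uniform(0.05, 0.7, size=3))
        inter = float(rng.uniform(2, 30))
        bundle = make_bundle(iptms, inter_pae=inter)
        before = triage(bundle).verdict
        # apply 10 random favourable perturbations
        for _ in range(10):
            which = rng.integers(0, len(bundle.models))
            m = bundle.models[which]
            if rng.random() < 0.5:
                m.iptm = min(1.0, m.iptm + float(rng.uniform(0, 0.3)))
            else:
                i = rng.integers(0, 8)
                j = 8 + rng.integers(0, 4)
                dec = float(rng.uniform(0, 10))
                m.pae[i, j] = max(0.0, m.pae[i, j] - dec)
                m.pae[j, i] = max(0.0, m.pae[j, i] - dec)
        after = triage(bundle).verdict
        if before == "interactor_candidate":
            assert after == "interactor_candidate"


# ---------------------------------------------------------------------------
# loading and screening
# ---------------------------------------------------------------------------

class TestLoading:
    def test_bundle_round_trip(self, tmp_path):
        """Generated files re-read through the standard readers preserve
        the design: 140-residue PAE, designed iPTM, both dialects."""
        bundle, _ = gen_prediction_bundle(
            TriageScenario(receptor_size=120, partner_size=20,
                           designed_iptm=(0.6, 0.5, 0.4)), tmp_path)
        assert len(bundle.models) == 3
        for m in bundle.models:
            assert m.pae.shape == (140, 140)
        assert mean_iptm(bundle) == pytest.approx(0.5)

    def test_mmcif_round_trip(self, tmp_path):
        pdb_bundle, _ = gen_prediction_bundle(TriageScenario(seed=4),
                                              tmp_path / "pdb", "pdb")
        cif_bundle, _ = gen_prediction_bundle(TriageScenario(seed=4),
                                              tmp_path / "cif", "cif")
        np.testing.assert_allclose(pdb_bundle.models[0].coords,
                                   cif_bundle.models[0].coords, atol=1e-3)

    def test_pae_dimension_mismatch_names_both_counts(self, tmp_path):
        bundle, manifest = gen_prediction_bundle(TriageScenario(seed=5), tmp_path)
        scores = tmp_path / "scores_rank_1.json"
        data = json.loads(scores.read_text())
        data["pae"] = [[1.0] * 10 for _ in range(10)]
        scores.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="10.*140|140.*10"):
            load_prediction_bundle(
                [tmp_path / m["model_path"] for m in manifest["models"]],
                [tmp_path / m["scores_path"] for m in manifest["models"]],
                manifest["chain_map"])

    def test_truncated_score_file_names_file(self, tmp_path):
        bad = tmp_path / "truncated.json"
        bad.write_text('{"pae": [[1.0, 2.0], [')
        with pytest.raises(ValueError, match="truncated.json"):
            load_scores(bad)

    def test_missing_iptm_still_loads(self, tmp_path):
        path = tmp_path / "scores.json"
        path.write_text(json.dumps({"pae": [[0.0, 5.0], [5.0, 0.0]]}))
        scores = load_scores(path)
        assert scores["iptm"] is None
        assert scores["pae"].shape == (2, 2)


class TestRunScreen:
    def test_strong_weak_malformed_manifest(self, tmp_path):
        gen_prediction_bundle(TriageScenario(
            designed_iptm=(0.6, 0.6, 0.6), interchain_pae_level=5.0,
            pair_id="strong"), tmp_path / "strong")
        gen_prediction_bundle(TriageScenario(
            designed_iptm=(0.1, 0.1, 0.1), interchain_pae_level=30.0,
            background_pae_level=30.0, pair_id="weak"), tmp_path / "weak")
        manifest = {
            "pairs": [
                {"pair_id": "strong", "chain_map": {"bait": ["A"], "candidate": ["B"]},
                 "models": [{"model_path": f"strong/rank_{k}.pdb",
                             "scores_path": f"strong/scores_rank_{k}.json"}
                            for k in (1, 2, 3)]},
                {"pair_id": "weak", "chain_map": {"bait": ["A"], "candidate": ["B"]},
                 "models": [{"model_path": f"weak/rank_{k}.pdb",
                             "scores_path": f"weak/scores_rank_{k}.json"}
                            for k in (1, 2, 3)]},
                {"pair_id": "broken", "chain_map": {"bait": ["A"], "candidate": ["B"]},
                 "models": [{"model_path": "missing.pdb",
                             "scores_path": "missing.json"}]},
            ]
        }
        mpath = tmp_path / "manifest.json"
        mpath.write_text(json.dumps(manifest))
        summary = run_screen(mpath)
        assert list(summary.verdict) == ["interactor_candidate", "no_call",
                                         "rejected"]

    def test_empty_manifest_gives_header_only(self, tmp_path):
        mpath = tmp_path / "manifest.json"
        mpath.write_text(json.dumps({"pairs": []}))
        summary = run_screen(mpath)
        assert len(summary) == 0
        assert "verdict" in summary.columns

    def test_rerun_is_identical(self, tmp_path):
        gen_prediction_bundle(TriageScenario(pair_id="p"), tmp_path / "p")
        manifest = {"pairs": [{
            "pair_id": "p", "chain_map": {"bait": ["A"], "candidate": ["B"]},
            "models": [{"model_path": f"p/rank_{k}.pdb",
                        "scores_path": f"p/scores_rank_{k}.json"}
                       for k in (1, 2, 3)]}]}
        mpath = tmp_path / "manifest.json"
        mpath.write_text(json.dumps(manifest))
        assert run_screen(mpath).equals(run_screen(mpath))
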