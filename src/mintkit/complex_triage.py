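"""Triage of predicted multimer complexes into direct-interactor verdicts.

Screens bundles of ranked AlphaFold2-Multimer models of a candidate
protein pair using the evidence a structural biologist inspects by eye:

* **iPTM** — the interfacial predicted TM-score averaged across models;
  pairs below ~0.3 rarely survive manual assessment.
* **inter-chain PAE** — statistics over the off-diagonal blocks of the
  predicted-aligned-error matrix; a low-error block is the "strong signal"
  of a confidently placed interface.
* **model consistency** — after superposing every model pair on the bait
  backbone, the median RMSD of the candidate chain measures whether
  independent predictions agree on the binding pose.
* **interface contacts** — inter-chain heavy-atom contacts classified as
  electrostatic (salt bridge), hydrogen-bond/polar, or hydrophobic.

The verdict gate uses only the confidence metrics (iPTM and PAE);
consistency and contacts are reported as supporting evidence, mirroring a
two-stage screen in which promising pairs get closer manual scrutiny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PredictedComplex",
    "PredictionBundle",
    "TriageThresholds",
    "TriageResult",
    "load_model_coordinates",
    "load_scores",
    "load_prediction_bundle",
    "mean_iptm",
    "interchain_pae",
    "superpose",
    "model_consistency",
    "interface_contacts",
    "triage",
    "write_triage_result",
    "run_screen",
]

# Contact-classification distance conventions (Å): standard structural-
# biology cutoffs; none are stated by any single source of truth, so all
# are configurable at the interface_contacts call.
HEAVY_ATOM_CONTACT_A = 4.0
POLAR_CONTACT_A = 3.5
SALT_BRIDGE_A = 4.0

ACIDIC_SIDECHAIN_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_SIDECHAIN_N = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                     ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PredictedComplex:
    """One ranked model: coordinates, per-residue confidence, PAE, scores.

    Atom arrays are parallel (one entry per heavy atom).  ``residue_keys``
    lists ``(chain_id, residue_index)`` in PAE row/column order, the
    explicit bookkeeping between author residue numbering and the 0-based
    matrix index.
    """

    model_rank: int
    chain_ids: np.ndarray          # str per atom
    residue_indices: np.ndarray    # int per atom (author numbering)
    residue_names: np.ndarray      # str per atom
    atom_names: np.ndarray         # str per atom
    elements: np.ndarray           # str per atom
    coords: np.ndarray             # (n_atoms, 3) Å
    pae: np.ndarray | None = None  # (n_res, n_res) Å
    per_residue_confidence: np.ndarray | None = None  # pLDDT, [0, 100]
    iptm: float | None = None
    ptm: float | None = None
    residue_keys: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residue_keys:
            seen = []
            for c, r in zip(self.chain_ids, self.residue_indices):
                if not seen or seen[-1] != (c, int(r)):
                    seen.append((c, int(r)))
            self.residue_keys = seen
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            n = len(self.residue_keys)
            if self.pae.shape != (n, n):
                raise ValueError(
                    f"PAE matrix is {self.pae.shape[0]}x{self.pae.shape[1]} "
                    f"but the coordinates contain {n} residues")
            if (self.pae < 0).any():
                raise ValueError("PAE entries must be non-negative")

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(c)
        return out

    def residue_rows(self, chains: set[str] | list[str]) -> np.ndarray:
        """PAE row indices of all residues belonging to ``chains``."""
        chains = set(chains)
        return np.array([i for i, (c, _) in enumerate(self.residue_keys)
                         if c in chains], dtype=int)

    def atom_mask(self, chains, atom_names=None) -> np.ndarray:
        mask = np.isin(self.chain_ids, list(chains))
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        return mask

    def reference_atoms(self, chains) -> dict:
        """Map (chain, residue_index) -> Cα coordinate for ``chains``."""
        mask = self.atom_mask(chains, atom_names=["CA"])
        return {
            (c, int(r)): xyz
            for c, r, xyz in zip(self.chain_ids[mask],
                                 self.residue_indices[mask],
                                 self.coords[mask])
        }


@dataclass
class PredictionBundle:
    """All ranked models for one candidate pair, plus the bait/candidate map."""

    pair_id: str
    models: list[PredictedComplex]
    bait_chains: list[str]
    candidate_chains: list[str]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("a bundle needs at least one model")
        self.models = sorted(self.models, key=lambda m: m.model_rank)
        keys0 = self.models[0].residue_keys
        for m in self.models[1:]:
            if m.residue_keys != keys0:
                raise ValueError(
                    "all models in a bundle must share chain/residue composition")
        if set(self.bait_chains) & set(self.candidate_chains):
            raise ValueError("bait and candidate chain sets must be disjoint")


@dataclass(frozen=True)
class TriageThresholds:
    """Configurable gates encoding the screening judgment.

    ``iptm_threshold`` gates the across-model mean iPTM (set
    ``per_model_iptm`` to gate every model instead).  The PAE-signal
    criterion requires the best inter-chain error at or below
    ``pae_signal_max`` Å and at least ``min_frac_below`` of block entries
    under ``pae_cutoff`` Å.
    """

    iptm_threshold: float = 0.3
    pae_cutoff: float = 10.0
    pae_signal_max: float = 10.0
    min_frac_below: float = 0.01
    contact_cutoff: float = HEAVY_ATOM_CONTACT_A
    per_model_iptm: bool = False


@dataclass
class TriageResult:
    """Aggregated evidence and verdict for one candidate pair."""

    pair_id: str
    mean_iptm: float | None
    min_interchain_pae: float | None
    mean_interchain_pae: float | None
    frac_interchain_pae_below_cutoff: float | None
    consistency_rmsd: float | None
    n_contacts: int
    contact_classes: dict
    verdict: str  # interactor_candidate | no_call | rejected
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "mean_iptm": self.mean_iptm,
            "min_interchain_pae": self.min_interchain_pae,
            "mean_interchain_pae": self.mean_interchain_pae,
            "frac_interchain_pae_below_cutoff": self.frac_interchain_pae_below_cutoff,
            "consistency_rmsd": self.consistency_rmsd,
            "n_contacts": self.n_contacts,
            "contact_classes": self.contact_classes,
            "verdict": self.verdict,
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_model_coordinates(path, model_rank: int = 1) -> PredictedComplex:
    """Read heavy-atom coordinates from a PDB or mmCIF file (via gemmi)."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chain_ids, res_idx, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for chain in model:
        prev = None
        for residue in chain:
            if prev is not None and residue.seqid.num <= prev:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {chain.name}")
            prev = residue.seqid.num
            for atom in residue:
                if atom.element.name == "H":
                    continue
                chain_ids.append(chain.name)
                res_idx.append(residue.seqid.num)
                res_names.append(residue.name)
                atom_names.append(atom.name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not chain_ids:
        raise ValueError(f"no atoms found in {path}")
    if any(not c for c in chain_ids):
        raise ValueError(f"empty chain identifier in {path}")
    return PredictedComplex(
        model_rank=model_rank,
        chain_ids=np.array(chain_ids),
        residue_indices=np.array(res_idx, dtype=int),
        residue_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        coords=np.array(coords, dtype=float),
    )


def load_scores(path) -> dict:
    """Parse a score JSON in either supported dialect.

    Accepts ``{"pae": [[...]], "iptm": x, "ptm": y}`` as well as the
    dialect keying the matrix as ``predicted_aligned_error``.  Missing
    iPTM is recorded as absent, not an error.
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"could not parse score file {path}: {exc}") from exc
    if isinstance(data, list):  # some exporters wrap the record in a list
        data = data[0]
    pae = data.get("pae", data.get("predicted_aligned_error"))
    if pae is None:
        raise ValueError(f"score file {path} carries no PAE matrix")
    return {
        "pae": np.asarray(pae, dtype=float),
        "iptm": data.get("iptm"),
        "ptm": data.get("ptm"),
        "plddt": (np.asarray(data["plddt"], dtype=float)
                  if "plddt" in data else None),
    }


def load_prediction_bundle(model_paths, score_paths, chain_map,
                           pair_id: str = "pair") -> PredictionBundle:
    """Assemble a rank-sorted bundle from per-model coordinate + score files.

    ``chain_map`` is ``{"bait": [...chain ids...], "candidate": [...]}``.
    """
    if len(model_paths) != len(score_paths) or not model_paths:
        raise ValueError("need one score file per model, at least one model")
    models = []
    for rank, (mp, sp) in enumerate(zip(model_paths, score_paths), start=1):
        model = load_model_coordinates(mp, model_rank=rank)
        scores = load_scores(sp)
        n_res = len(model.residue_keys)
        if scores["pae"].shape != (n_res, n_res):
            raise ValueError(
                f"PAE matrix in {sp} is {scores['pae'].shape[0]} residues but "
                f"{mp} contains {n_res} residues")
        model.pae = scores["pae"]
        model.iptm = scores["iptm"]
        model.ptm = scores["ptm"]
        model.per_residue_confidence = scores["plddt"]
        models.append(model)
    return PredictionBundle(
        pair_id=pair_id,
        models=models,
        bait_chains=list(chain_map["bait"]),
        candidate_chains=list(chain_map["candidate"]),
    )


# ---------------------------------------------------------------------------
# evidence operations
# ---------------------------------------------------------------------------

def mean_iptm(bundle: PredictionBundle) -> float:
    """Arithmetic mean of per-model iPTM across the bundle."""
    values = [m.iptm for m in bundle.models if m.iptm is not None]
    if not values:
        raise ValueError("no model in the bundle carries an iPTM value")
    return float(np.mean(values))


def interchain_pae(model: PredictedComplex, bait_chains, candidate_chains,
                   cutoff: float = 10.0) -> dict:
    """Statistics over the two off-diagonal inter-chain PAE blocks.

    Pools the bait-rows × candidate-columns block with its transpose block
    (PAE is asymmetric: the row is the aligned-on residue), so the result
    is invariant to swapping the bait/candidate labels.
    """
    if model.pae is None:
        raise ValueError("model carries no PAE matrix")
    bait_chains, candidate_chains = set(bait_chains), set(candidate_chains)
    if not bait_chains or not candidate_chains:
        raise ValueError("both chain sets must be non-empty")
    if bait_chains & candidate_chains:
        raise ValueError("chain sets must be disjoint")
    known = set(c for c, _ in model.residue_keys)
    unknown = (bait_chains | candidate_chains) - known
    if unknown:
        raise ValueError(f"unknown chain id(s): {sorted(unknown)}")
    rows_a = model.residue_rows(bait_chains)
    rows_b = model.residue_rows(candidate_chains)
    block = np.concatenate([
        model.pae[np.ix_(rows_a, rows_b)].ravel(),
        model.pae[np.ix_(rows_b, rows_a)].ravel(),
    ])
    return {
        "min": float(block.min()),
        "mean": float(block.mean()),
        "frac_below_cutoff": float(np.mean(block < cutoff)),
    }


def superpose(reference_points: np.ndarray, moving_points: np.ndarray) -> dict:
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Returns the proper rotation (det +1), translation, and the RMSD after
    applying ``x -> R @ x + t`` to the moving points.
    """
    ref = np.asarray(reference_points, dtype=float)
    mov = np.asarray(moving_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    h = mov_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - rot @ mov.mean(axis=0)
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return {"rotation": rot, "translation": trans, "rmsd": rmsd}


def model_consistency(bundle: PredictionBundle) -> float:
    """Median pairwise candidate-chain RMSD after bait-backbone alignment.

    For every model pair, superpose model j onto model i using the shared
    bait Cα atoms, then measure the candidate-chain Cα RMSD without any
    further fitting.  The median over pairs is robust to one divergent
    model among three.
    """
    if len(bundle.models) < 2:
        raise ValueError("consistency needs at least 2 models")
    rmsds = []
    for i in range(len(bundle.models)):
        for j in range(i + 1, len(bundle.models)):
            a, b = bundle.models[i], bundle.models[j]
            ref_a = a.reference_atoms(bundle.bait_chains)
            ref_b = b.reference_atoms(bundle.bait_chains)
            shared = [k for k in ref_a if k in ref_b]
            if len(shared) < 3:
                raise ValueError("fewer than 3 shared bait reference atoms")
            sup = superpose(np.array([ref_a[k] for k in shared]),
                            np.array([ref_b[k] for k in shared]))
            cand_a = a.reference_atoms(bundle.candidate_chains)
            cand_b = b.reference_atoms(bundle.candidate_chains)
            shared_c = [k for k in cand_a if k in cand_b]
            if not shared_c:
                raise ValueError("no shared candidate reference atoms")
            pa = np.array([cand_a[k] for k in shared_c])
            pb = np.array([cand_b[k] for k in shared_c])
            pb_moved = pb @ sup["rotation"].T + sup["translation"]
            rmsds.append(float(np.sqrt(np.mean(np.sum((pb_moved - pa) ** 2,
                                                      axis=1)))))
    return float(np.median(rmsds))


def _classify_contact(res_a: str, atoms_a: list, res_b: str, atoms_b: list) -> str:
    """Classify one residue-pair contact from its contributing atom pairs.

    ``atoms_a``/``atoms_b`` are parallel lists of (atom_name, element,
    distance) triples for the atom pairs within the contact cutoff.
    Precedence: electrostatic > hydrogen-bond/polar > hydrophobic.
    """
    has_polar = False
    all_carbon = True
    for (name_a, elem_a, _), (name_b, elem_b, dist) in zip(atoms_a, atoms_b):
        pair_ao = (res_a, name_a) in ACIDIC_SIDECHAIN_O and \
            (res_b, name_b) in BASIC_SIDECHAIN_N
        pair_bo = (res_b, name_b) in ACIDIC_SIDECHAIN_O and \
            (res_a, name_a) in BASIC_SIDECHAIN_N
        if (pair_ao or pair_bo) and dist <= SALT_BRIDGE_A:
            return "electrostatic"
        if elem_a in ("N", "O") and elem_b in ("N", "O") and dist <= POLAR_CONTACT_A:
            has_polar = True
        if not (elem_a == "C" and elem_b == "C"):
            all_carbon = False
    if has_polar:
        return "hydrogen-bond/polar"
    if all_carbon:
        return "hydrophobic"
    return "other"


def interface_contacts(model: PredictedComplex, bait_chains, candidate_chains,
                       distance_cutoff: float = HEAVY_ATOM_CONTACT_A) -> list[dict]:
    """Inter-chain heavy-atom contacts grouped and classified per residue pair.

    Returns one record per contacting residue pair with the atom-pair
    count and a class in {electrostatic, hydrogen-bond/polar, hydrophobic,
    other}.  An empty selection yields an empty list.
    """
    bait_chains, candidate_chains = set(bait_chains), set(candidate_chains)
    if bait_chains & candidate_chains:
        raise ValueError("chain sets must be disjoint")
    mask_a = model.atom_mask(bait_chains)
    mask_b = model.atom_mask(candidate_chains)
    if not mask_a.any() or not mask_b.any():
        return []
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    tree = cKDTree(model.coords[idx_b])
    pairs: dict[tuple, dict] = {}
    neighbor_lists = tree.query_ball_point(model.coords[idx_a], distance_cutoff)
    for ia, neighbors in zip(idx_a, neighbor_lists):
        for jb in neighbors:
            ib = idx_b[jb]
            dist = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
            key = ((model.chain_ids[ia], int(model.residue_indices[ia])),
                   (model.chain_ids[ib], int(model.residue_indices[ib])))
            rec = pairs.setdefault(key, {
                "bait_residue": key[0],
                "candidate_residue": key[1],
                "bait_resname": str(model.residue_names[ia]),
                "candidate_resname": str(model.residue_names[ib]),
                "atoms_a": [], "atoms_b": [],
            })
            rec["atoms_a"].append((str(model.atom_names[ia]),
                                   str(model.elements[ia]), dist))
            rec["atoms_b"].append((str(model.atom_names[ib]),
                                   str(model.elements[ib]), dist))
    contacts = []
    for rec in pairs.values():
        rec["n_atom_pairs"] = len(rec["atoms_a"])
        rec["min_distance"] = min(d for _, _, d in rec["atoms_a"])
        rec["contact_class"] = _classify_contact(
            rec["bait_resname"], rec["atoms_a"],
            rec["candidate_resname"], rec["atoms_b"])
        del rec["atoms_a"], rec["atoms_b"]
        contacts.append(rec)
    contacts.sort(key=lambda r: (r["bait_residue"], r["candidate_residue"]))
    return contacts


# ---------------------------------------------------------------------------
# verdict
# ---------------------------------------------------------------------------

def triage(bundle: PredictionBundle,
           thresholds: TriageThresholds | None = None) -> TriageResult:
    """Apply the screening gates and assemble the evidence for one pair.

    ``interactor_candidate`` requires the iPTM gate AND the PAE-signal
    criterion; anything confidently loadable that misses either gate is
    ``no_call``.  Consistency RMSD and contact classes are reported as
    supporting evidence without gating the verdict.
    """
    th = thresholds or TriageThresholds()
    if len(set(c for c, _ in bundle.models[0].residue_keys)) < 2:
        raise ValueError("triage requires a complex with at least two chains")

    miptm = mean_iptm(bundle)
    if th.per_model_iptm:
        iptm_ok = all(m.iptm is not None and m.iptm >= th.iptm_threshold
                      for m in bundle.models)
    else:
        iptm_ok = miptm >= th.iptm_threshold

    per_model = [interchain_pae(m, bundle.bait_chains, bundle.candidate_chains,
                                cutoff=th.pae_cutoff)
                 for m in bundle.models if m.pae is not None]
    if not per_model:
        raise ValueError("no model in the bundle carries a PAE matrix")
    min_pae = min(s["min"] for s in per_model)
    mean_pae = float(np.mean([s["mean"] for s in per_model]))
    frac_below = float(np.mean([s["frac_below_cutoff"] for s in per_model]))
    pae_ok = (min_pae <= th.pae_signal_max) and (frac_below >= th.min_frac_below)

    consistency = (model_consistency(bundle) if len(bundle.models) >= 2 else None)
    contacts = interface_contacts(bundle.models[0], bundle.bait_chains,
                                  bundle.candidate_chains,
                                  distance_cutoff=th.contact_cutoff)
    classes = {"hydrophobic": 0, "hydrogen-bond/polar": 0,
               "electrostatic": 0, "other": 0}
    for c in contacts:
        classes[c["contact_class"]] += 1

    verdict = "interactor_candidate" if (iptm_ok and pae_ok) else "no_call"
    return TriageResult(
        pair_id=bundle.pair_id,
        mean_iptm=miptm,
        min_interchain_pae=min_pae,
        mean_interchain_pae=mean_pae,
        frac_interchain_pae_below_cutoff=frac_below,
        consistency_rmsd=consistency,
        n_contacts=len(contacts),
        contact_classes=classes,
        verdict=verdict,
    )


def write_triage_result(result: TriageResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def run_screen(manifest_path, thresholds: TriageThresholds | None = None) -> pd.DataFrame:
    """Screen every candidate pair listed in a bundle manifest.

    The manifest JSON is ``{"pairs": [{"pair_id", "chain_map",
    "models": [{"model_path", "scores_path"}, ...]}, ...]}``; paths are
    resolved relative to the manifest.  A pair that fails to load becomes
    a ``rejected`` row and the screen continues — the machine analog of a
    screening summary table.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    rows = []
    for entry in manifest.get("pairs", []):
        pair_id = entry.get("pair_id", "pair")
        try:
            bundle = load_prediction_bundle(
                [base / m["model_path"] for m in entry["models"]],
                [base / m["scores_path"] for m in entry["models"]],
                entry["chain_map"], pair_id=pair_id)
            result = triage(bundle, thresholds)
        except (ValueError, KeyError, OSError) as exc:
            result = TriageResult(
                pair_id=pair_id, mean_iptm=None, min_interchain_pae=None,
                mean_interchain_pae=None, frac_interchain_pae_below_cutoff=None,
                consistency_rmsd=None, n_contacts=0, contact_classes={},
                verdict="rejected", error=str(exc))
        rows.append({
            "pair_id": result.pair_id,
            "mean_iptm": result.mean_iptm,
            "min_interchain_pae": result.min_interchain_pae,
            "frac_below_cutoff": result.frac_interchain_pae_below_cutoff,
            "consistency_rmsd": result.consistency_rmsd,
            "n_contacts": result.n_contacts,
            "verdict": result.verdict,
        })
    columns = ["pair_id", "mean_iptm", "min_interchain_pae", "frac_below_cutoff",
               "consistency_rmsd", "n_contacts", "verdict"]
    return pd.DataFrame(rows, columns=columns)
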