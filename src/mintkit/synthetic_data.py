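"""Ground-truth-bearing synthetic inputs for all three pipeline stages.

Every generator is seeded and emits machine-readable ground truth next to
the data it produces, so recovery tests can consume only the data and
compare only against the truth record.  The defaults mirror the study
conditions the pipelines were built for: 3000-frame 10 Hz movies of
128×128 px at 106 nm/pixel with appearing/disappearing diffraction-
limited puncta; 1:1 titrations of 0.7 mM peptide into 50 μM protein;
three-model prediction bundles with designed iPTM values and constant
inter-chain PAE blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np

from .fusion_events import Movie
from .thermo_itc import Isotherm, TitrationProtocol, simulate_isotherm
from .complex_triage import PredictionBundle, load_prediction_bundle

__all__ = [
    "FusionSchedule",
    "TriageScenario",
    "random_schedule",
    "gen_movie",
    "paper_itc_protocol",
    "gen_isotherm",
    "gen_prediction_bundle",
    "simulate_fusion_cohort",
]


# ---------------------------------------------------------------------------
# TIRF movies
# ---------------------------------------------------------------------------

@dataclass
class FusionSchedule:
    """Scheduled puncta for a synthetic movie.

    ``events`` are (x, y, appear_frame, disappear_frame, amplitude)
    tuples rendered on frames [appear, disappear); ``persistors`` are
    (x, y, appear_frame, amplitude) spots lasting to the movie end.
    Amplitudes are in the same counts as ``noise_sd``, so an event with
    amplitude = snr·noise_sd has per-frame peak SNR = snr.
    """

    events: list = field(default_factory=list)
    persistors: list = field(default_factory=list)
    psf_sigma: float = 1.5
    background: float = 100.0
    noise_model: str = "gaussian"  # or "poisson"
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (_, _, a, d, _) in self.events:
            if d <= a:
                raise ValueError("disappear_frame must exceed appear_frame")


def random_schedule(n_events: int = 12, n_persistors: int = 2,
                    shape: tuple[int, int] = (128, 128),
                    n_frames: int = 3000, interval_length: int = 100,
                    snr: float = 8.0, noise_sd: float = 10.0,
                    min_separation: float = 6.0,
                    seed: int = 0) -> FusionSchedule:
    """Draw a non-overlapping schedule of completed events plus persistors.

    Events last 4–10 intervals and always disappear before the final
    interval (so each scheduled event is a callable completed event);
    spot positions keep ``min_separation`` pixels apart so distinct
    vesicles never merge into one spatiotemporal cluster.
    """
    rng = np.random.default_rng(seed)
    n_intervals = n_frames // interval_length
    if n_intervals < 6:
        raise ValueError("movie too short to schedule events")
    margin = 6
    positions: list[tuple[int, int]] = []
    attempts = 0
    while len(positions) < n_events + n_persistors:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place spots with requested separation")
        x = int(rng.integers(margin, shape[1] - margin))
        y = int(rng.integers(margin, shape[0] - margin))
        if all((x - px) ** 2 + (y - py) ** 2 >= min_separation ** 2
               for px, py in positions):
            positions.append((x, y))
    amplitude = snr * noise_sd
    max_duration = min(10, n_intervals - 2)  # always callable as completed
    events = []
    for x, y in positions[:n_events]:
        dur = int(rng.integers(4, max_duration + 1))         # intervals
        first = int(rng.integers(0, max(n_intervals - 1 - dur, 1)))
        appear = first * interval_length
        disappear = (first + dur) * interval_length          # < last interval
        events.append((x, y, appear, disappear, amplitude))
    persistors = [(x, y, 0, amplitude) for x, y in positions[n_events:]]
    return FusionSchedule(events=events, persistors=persistors,
                          noise_sd=noise_sd, seed=seed)


def _render_spot(frames: np.ndarray, x: int, y: int, amplitude: float,
                 sigma: float, t0: int, t1: int) -> None:
    h, w = frames.shape[1:]
    r = max(int(np.ceil(4 * sigma)), 2)
    y0, y1 = max(y - r, 0), min(y + r + 1, h)
    x0, x1 = max(x - r, 0), min(x + r + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    patch = amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    frames[t0:t1, y0:y1, x0:x1] += patch.astype(frames.dtype)


def gen_movie(schedule: FusionSchedule,
              shape: tuple[int, int] = (128, 128),
              n_frames: int = 3000,
              frame_rate: float = 10.0,
              pixel_size: float = 106.0,
              interval_length: int = 100,
              stimulation_frame: int | None = None) -> tuple[Movie, dict]:
    """Render a schedule into a noisy movie plus its ground-truth record.

    Ground truth lists the scheduled completed events (those disappearing
    before the movie end) with their interval indices, and the persistors
    separately.  Bit-identical output under a fixed seed for the Gaussian
    noise model.
    """
    for (x, y, *_rest) in schedule.events + schedule.persistors:
        if not (0 <= x < shape[1] and 0 <= y < shape[0]):
            raise ValueError(f"spot ({x}, {y}) out of bounds for shape {shape}")
    frames = np.full((n_frames, *shape), schedule.background, dtype=np.float32)
    for (x, y, appear, disappear, amp) in schedule.events:
        if disappear > n_frames:
            raise ValueError("event extends past the end of the movie")
        _render_spot(frames, x, y, amp, schedule.psf_sigma, appear, disappear)
    for (x, y, appear, amp) in schedule.persistors:
        _render_spot(frames, x, y, amp, schedule.psf_sigma, appear, n_frames)
    rng = np.random.default_rng(schedule.seed)
    if schedule.noise_model == "gaussian":
        if schedule.noise_sd > 0:
            noise = rng.standard_normal(size=frames.shape, dtype=np.float32)
            noise *= schedule.noise_sd
            frames += noise
    elif schedule.noise_model == "poisson":
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(np.float32)
    else:
        raise ValueError(f"unknown noise model {schedule.noise_model!r}")
    movie = Movie(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size,
                  stimulation_frame=stimulation_frame)
    n_intervals = n_frames // interval_length
    truth_events = []
    for (x, y, appear, disappear, amp) in schedule.events:
        first = appear // interval_length
        last = (disappear - 1) // interval_length
        truth_events.append({
            "x": x, "y": y,
            "appear_frame": appear, "disappear_frame": disappear,
            "first_interval": first, "last_interval": last,
            "completed": disappear < n_frames and last < n_intervals - 1,
            "amplitude": amp,
        })
    truth = {
        "n_frames": n_frames, "shape": list(shape),
        "interval_length": interval_length,
        "n_intervals": n_intervals,
        "seed": schedule.seed,
        "events": truth_events,
        "n_completed": sum(e["completed"] for e in truth_events),
        "persistors": [{"x": x, "y": y, "appear_frame": a, "amplitude": amp}
                       for (x, y, a, amp) in schedule.persistors],
    }
    return movie, truth


# ---------------------------------------------------------------------------
# ITC isotherms
# ---------------------------------------------------------------------------

def paper_itc_protocol(syringe_conc: float = 0.7e-3,
                       cell_conc: float = 50e-6,
                       cell_volume: float = 200e-6,
                       n_injections: int = 20,
                       injection_volume: float = 2e-6,
                       temperature: float = 298.15) -> TitrationProtocol:
    """The study's titration layout: 0.7 mM peptide into 50 μM protein at
    25 °C, 20 × 2 μl injections into a 200 μl cell."""
    return TitrationProtocol(
        cell_volume=cell_volume,
        syringe_concentration=syringe_conc,
        cell_concentration=cell_conc,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=temperature,
    )


def gen_isotherm(truth: dict, protocol: TitrationProtocol | None = None,
                 noise_sd: float = 0.0, seed: int = 0) -> tuple[Isotherm, dict]:
    """Seeded noisy isotherm plus the generating truth record.

    ``truth`` is ``{"kd": M, "n": ..., "dh": kcal/mol}``; with
    ``noise_sd = 0`` the output equals the noiseless forward model.
    """
    protocol = protocol or paper_itc_protocol()
    iso = simulate_isotherm(truth, protocol, noise_sd=noise_sd,
                            rng=np.random.default_rng(seed))
    record = dict(truth)
    record.update({"noise_sd_ucal": noise_sd, "seed": seed})
    return iso, record


def simulate_fusion_cohort(n_cells_a: int = 15, n_cells_b: int = 17,
                           rate_a: float = 15.0, rate_b: float = 9.0,
                           shape: tuple[int, int] = (64, 64),
                           n_frames: int = 1000, snr: float = 8.0,
                           seed: int = 0) -> dict:
    """Two-condition cohort run end-to-end through the detection pipeline.

    Each cell draws its scheduled completed-event count from a Poisson
    with the condition's rate (events per acquisition), renders a movie,
    and is scored by the full detect→cluster→call→density pipeline over
    the whole frame.  Returns per-cell densities and scheduled counts for
    both groups.  Mirrors a rescue experiment in which one condition
    fuses at a reduced rate.
    """
    from .fusion_events import DetectionConfig, detect_events, events_per_area

    rng = np.random.default_rng(seed)
    config = DetectionConfig()
    mask = np.ones(shape, dtype=bool)
    out = {"rate_a": rate_a, "rate_b": rate_b}
    for name, n_cells, rate in (("a", n_cells_a, rate_a),
                                ("b", n_cells_b, rate_b)):
        densities, scheduled = [], []
        for _ in range(n_cells):
            n_events = int(rng.poisson(rate))
            sched = random_schedule(
                n_events=n_events, n_persistors=2, shape=shape,
                n_frames=n_frames, snr=snr,
                seed=int(rng.integers(2 ** 31)))
            movie, truth = gen_movie(sched, shape=shape, n_frames=n_frames)
            events = detect_events(movie, config)
            densities.append(events_per_area(events, movie, mask,
                                             evoked_only=False))
            scheduled.append(truth["n_completed"])
        out[name] = {"densities": np.asarray(densities),
                     "scheduled": scheduled}
    return out


# ---------------------------------------------------------------------------
# prediction bundles
# ---------------------------------------------------------------------------

@dataclass
class TriageScenario:
    """Design of a synthetic prediction bundle for one candidate pair.

    The receptor is an idealised extended backbone trace; the partner is
    an α-helix laid against it (the helix-on-domain geometry of a short
    motif docking onto a folded bait).  ``partner_displacement`` gives a
    rigid z-offset per model (Å) on top of the base pose;
    ``interchain_stripe_width`` > 0 confines the low-error inter-chain
    PAE signal to that many receptor residues, the rest of the block
    sitting at ``background_pae_level``.
    """

    receptor_size: int = 120
    partner_size: int = 20
    designed_iptm: tuple = (0.6, 0.6, 0.6)
    interchain_pae_level: float = 5.0
    background_pae_level: float = 28.0
    partner_displacement: tuple = (0.0, 0.0, 0.0)
    coordinate_noise_sd: float = 0.0
    interchain_stripe_width: int = 0
    partner_offset: tuple | None = None  # overrides the default placement
    pair_id: str = "bait-candidate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor_size < 3 or self.partner_size < 3:
            raise ValueError("chains need at least 3 residues")
        if self.interchain_pae_level < 0 or self.background_pae_level < 0:
            raise ValueError("PAE levels must be non-negative")
        if len(self.partner_displacement) != len(self.designed_iptm):
            raise ValueError("one displacement per model required")


def _receptor_backbone(n_res: int) -> np.ndarray:
    """Cα trace of an extended chain: 3.8 Å steps along x with a gentle
    zigzag in y."""
    ca = np.zeros((n_res, 3))
    ca[:, 0] = np.arange(n_res) * 3.8
    ca[:, 1] = 1.0 * (np.arange(n_res) % 2)
    return ca


def _helix_backbone(n_res: int, offset: np.ndarray) -> np.ndarray:
    """Cα trace of an ideal α-helix (rise 1.5 Å, 100°/residue, radius
    2.3 Å) with its axis along x, translated by ``offset``."""
    t = np.arange(n_res)
    angle = np.deg2rad(100.0) * t
    ca = np.stack([1.5 * t, 2.3 * np.cos(angle), 2.3 * np.sin(angle)], axis=1)
    return ca + offset


def _residue_atoms(ca: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Idealised heavy-atom set around one Cα (N, CA, C, O, CB)."""
    return [
        ("N", ca + np.array([-1.2, 0.8, 0.0])),
        ("CA", ca),
        ("C", ca + np.array([1.2, 0.8, 0.0])),
        ("O", ca + np.array([1.4, 2.0, 0.0])),
        ("CB", ca + np.array([0.0, -1.0, 1.0])),
    ]


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _write_model(path: Path, receptor_ca: np.ndarray,
                 partner_ca: np.ndarray) -> None:
    structure = gemmi.Structure()
    structure.name = "synthetic"
    model = gemmi.Model("1")
    for chain_name, trace in (("A", receptor_ca), ("B", partner_ca)):
        chain = gemmi.Chain(chain_name)
        for i, ca in enumerate(trace, start=1):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(i, " ")
            for atom_name, pos in _residue_atoms(ca):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_ELEMENT[atom_name])
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                atom.b_iso = 50.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    if path.suffix.lower() == ".cif":
        structure.make_mmcif_document().write_file(str(path))
    else:
        structure.write_pdb(str(path))


def _design_pae(scenario: TriageScenario) -> np.ndarray:
    nr, np_ = scenario.receptor_size, scenario.partner_size
    n = nr + np_
    idx = np.arange(n)
    # intra-chain blocks: error grows with sequence separation up to the
    # background plateau
    pae = np.minimum(np.abs(idx[:, None] - idx[None, :]).astype(float),
                     scenario.background_pae_level)
    inter = np.full((nr, np_), scenario.interchain_pae_level)
    if scenario.interchain_stripe_width > 0:
        inter[:] = scenario.background_pae_level
        w = min(scenario.interchain_stripe_width, nr)
        start = nr // 2 - w // 2
        inter[start:start + w, :] = scenario.interchain_pae_level
    pae[:nr, nr:] = inter
    pae[nr:, :nr] = inter.T
    return pae


def gen_prediction_bundle(scenario: TriageScenario, out_dir,
                          file_format: str = "pdb") -> tuple[PredictionBundle, dict]:
    """Write a synthetic ranked-model bundle to disk and load it back.

    Produces per-rank coordinate files (PDB or mmCIF) and score JSONs
    (alternating between the two accepted PAE dialects), plus a manifest.
    Returns the bundle re-read through the standard readers together with
    a manifest dict; raises if the designed chains collide.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    receptor_ca = _receptor_backbone(scenario.receptor_size)
    mid = receptor_ca[scenario.receptor_size // 2]
    if scenario.partner_offset is not None:
        base_offset = np.asarray(scenario.partner_offset, dtype=float)
    else:
        base_offset = mid + np.array([-0.75 * scenario.partner_size, 7.5, 0.0])
    pae = _design_pae(scenario)
    plddt = np.concatenate([np.full(scenario.receptor_size, 85.0),
                            np.full(scenario.partner_size, 70.0)])
    suffix = ".cif" if file_format == "cif" else ".pdb"
    model_entries = []
    for rank, (iptm, dz) in enumerate(
            zip(scenario.designed_iptm, scenario.partner_displacement), start=1):
        partner_ca = _helix_backbone(scenario.partner_size, base_offset)
        partner_ca = partner_ca + np.array([0.0, 0.0, dz])
        # collision check on the designed pose, before measurement-like noise
        d2 = ((receptor_ca[:, None, :] - partner_ca[None, :, :]) ** 2).sum(-1)
        if d2.min() < 4.0:  # < 2 Å between Cα traces: chains collide
            raise ValueError("impossible geometry: receptor and partner overlap")
        if scenario.coordinate_noise_sd > 0:
            partner_ca = partner_ca + rng.normal(
                0.0, scenario.coordinate_noise_sd, size=partner_ca.shape)
        model_path = out_dir / f"rank_{rank}{suffix}"
        scores_path = out_dir / f"scores_rank_{rank}.json"
        _write_model(model_path, receptor_ca, partner_ca)
        pae_key = "pae" if rank % 2 == 1 else "predicted_aligned_error"
        with open(scores_path, "w") as fh:
            json.dump({pae_key: pae.tolist(), "iptm": iptm, "ptm": 0.8 * iptm,
                       "plddt": plddt.tolist()}, fh)
        model_entries.append({"model_path": model_path.name,
                              "scores_path": scores_path.name})
    manifest = {
        "pair_id": scenario.pair_id,
        "chain_map": {"bait": ["A"], "candidate": ["B"]},
        "models": model_entries,
        "scenario": asdict(scenario),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle = load_prediction_bundle(
        [out_dir / m["model_path"] for m in model_entries],
        [out_dir / m["scores_path"] for m in model_entries],
        manifest["chain_map"], pair_id=scenario.pair_id)
    return bundle, manifest
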