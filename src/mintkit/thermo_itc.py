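"""One-site ITC binding analysis and thermodynamic conversions.

Forward-simulates and fits the single-site (1:1) isothermal titration
calorimetry isotherm and derives the standard thermodynamic quantities:

    Kd  — dissociation constant (M)
    n   — binding stoichiometry
    ΔH  — binding enthalpy (kcal/mol)
    ΔG  — Gibbs free energy, RT·ln(Kd / 1 M) (kcal/mol)
    −TΔS = ΔG − ΔH (kcal/mol)

The forward model tracks total moles of macromolecule (cell species) and
ligand (syringe species) in the calorimeter cell through a titration,
applying the displaced-volume ("perfusion") dilution convention: each
injection of volume dV into a cell of constant active volume V0 dilutes
every pre-injection concentration by V0 / (V0 + dV) while the injected
ligand enters at Cs · dV / (V0 + dV).  The bound-complex concentration at
each post-injection composition is the exact quadratic root of the
single-site mass-action equilibrium, and the heat of injection i is

    q_i = ΔH · V0 · ([MX]_i − f_i · [MX]_{i−1})

i.e. the enthalpy of the complex newly formed in the active volume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "DILUTION_CONVENTION",
    "TitrationProtocol",
    "Isotherm",
    "BindingFit",
    "simulate_isotherm",
    "fit_one_site",
    "delta_g_from_kd",
    "entropy_term",
    "fold_change_kd",
    "read_isotherm_csv",
    "write_fit_report",
    "REFERENCE_ITC_TABLE",
    "check_reference_consistency",
    "check_entropy_identity",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.9872e-3

#: 25 °C, the temperature of every titration analysed here.
STANDARD_TEMPERATURE_K = 298.15

#: Identifier of the dilution bookkeeping used by the forward model,
#: recorded in every fit report.
DILUTION_CONVENTION = "displaced-volume (perfusion)"

KCAL_TO_UCAL = 1e9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and cell composition of one titration.

    Parameters
    ----------
    cell_volume : float
        Active cell volume in litres.
    syringe_concentration : float
        Total syringe-species (ligand) concentration, molar.
    cell_concentration : float
        Total cell-species (macromolecule) concentration before the first
        injection, molar.
    injection_volumes : sequence of float
        Per-injection volumes in litres; at least two injections.
    temperature : float
        Temperature in kelvin, default 298.15 (25 °C).
    """

    cell_volume: float
    syringe_concentration: float
    cell_concentration: float
    injection_volumes: tuple[float, ...]
    temperature: float = STANDARD_TEMPERATURE_K

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes",
                           tuple(float(v) for v in self.injection_volumes))
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be strictly positive")
        if self.syringe_concentration <= 0 or self.cell_concentration <= 0:
            raise ValueError("concentrations must be strictly positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("a titration needs at least 2 injections")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be strictly positive")
        if not (273.0 <= self.temperature <= 373.0):
            raise ValueError("temperature must lie in [273, 373] K")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def compositions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Total concentrations after each injection.

        Returns ``(macromolecule_total, ligand_total, dilution_factors)``
        arrays of length ``n_injections`` under the displaced-volume
        convention.
        """
        v0 = self.cell_volume
        m = np.empty(self.n_injections)
        x = np.empty(self.n_injections)
        f = np.empty(self.n_injections)
        m_prev = self.cell_concentration
        x_prev = 0.0
        for i, dv in enumerate(self.injection_volumes):
            fi = v0 / (v0 + dv)
            m[i] = m_prev * fi
            x[i] = x_prev * fi + self.syringe_concentration * dv / (v0 + dv)
            f[i] = fi
            m_prev, x_prev = m[i], x[i]
        return m, x, f


@dataclass(frozen=True)
class Isotherm:
    """A titration record: protocol plus integrated per-injection heats (μcal)."""

    protocol: TitrationProtocol
    heats: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", tuple(float(q) for q in self.heats))
        if len(self.heats) != self.protocol.n_injections:
            raise ValueError(
                f"got {len(self.heats)} heats for "
                f"{self.protocol.n_injections} injections")

    @property
    def molar_ratios(self) -> np.ndarray:
        """Ligand-total / macromolecule-total after each injection."""
        m, x, _ = self.protocol.compositions()
        return x / m


@dataclass(frozen=True)
class BindingFit:
    """One-site fit result with self-consistent derived thermodynamics.

    ``dg`` and ``minus_tds`` are derived from ``kd`` and ``dh`` at the fit
    temperature, so ``dg == dh + minus_tds`` and ``dg == RT·ln(kd)`` hold to
    rounding error by construction.
    """

    kd: float
    n: float
    dh: float
    dg: float
    minus_tds: float
    temperature: float
    uncertainties: dict = field(default_factory=dict)
    converged: bool = True
    offset: float = 0.0

    @classmethod
    def from_parameters(cls, kd: float, n: float, dh: float,
                        temperature: float = STANDARD_TEMPERATURE_K,
                        uncertainties: dict | None = None,
                        converged: bool = True,
                        offset: float = 0.0) -> "BindingFit":
        dg = delta_g_from_kd(kd, temperature)
        return cls(kd=kd, n=n, dh=dh, dg=dg, minus_tds=entropy_term(dg, dh),
                   temperature=temperature, uncertainties=uncertainties or {},
                   converged=converged, offset=offset)


# ---------------------------------------------------------------------------
# thermodynamic identities
# ---------------------------------------------------------------------------

def delta_g_from_kd(kd: float, temperature: float = STANDARD_TEMPERATURE_K) -> float:
    """Gibbs free energy of binding, RT·ln(Kd / 1 M), in kcal/mol.

    Negative for any sub-molar dissociation constant; zero at the 1 M
    standard state.
    """
    if kd <= 0:
        raise ValueError("kd must be strictly positive")
    if temperature <= 0:
        raise ValueError("temperature must be strictly positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def entropy_term(dg: float, dh: float) -> float:
    """The entropic contribution −TΔS = ΔG − ΔH, in kcal/mol."""
    return dg - dh


def fold_change_kd(reference: BindingFit, perturbed: BindingFit) -> float:
    """Ratio of dissociation constants, ``perturbed.kd / reference.kd``.

    Used to express ligand-competition effects, e.g. the loss of Sx1a
    affinity for Munc18-1 in the presence of the Mint1 peptide.
    """
    if not (reference.converged and perturbed.converged):
        raise ValueError("fold change requires two converged fits")
    if reference.kd == 0:
        raise ValueError("reference kd must be non-zero")
    return perturbed.kd / reference.kd


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _bound_complex(m_tot: np.ndarray, x_tot: np.ndarray,
                   kd: float, n: float) -> np.ndarray:
    """Exact bound-complex concentration for single-site binding.

    Solves ``[MX] = ([sites] + X + Kd − sqrt(([sites]+X+Kd)² − 4·[sites]·X))/2``
    with ``[sites] = n·M_tot``, the numerically stable root of the
    mass-action quadratic.
    """
    sites = n * m_tot
    b = sites + x_tot + kd
    disc = b * b - 4.0 * sites * x_tot
    disc = np.maximum(disc, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def simulate_isotherm(params: dict, protocol: TitrationProtocol,
                      noise_sd: float = 0.0,
                      rng: np.random.Generator | int | None = None) -> Isotherm:
    """Forward-simulate per-injection heats (μcal) for a 1:1 isotherm.

    Parameters
    ----------
    params : dict
        ``{"kd": M, "n": stoichiometry, "dh": kcal/mol}``.
    protocol : TitrationProtocol
        Injection schedule and concentrations.
    noise_sd : float
        Standard deviation of zero-mean Gaussian noise added to each heat,
        in μcal.
    rng : numpy Generator or int seed, optional
        Source of randomness when ``noise_sd > 0``.
    """
    kd, n, dh = float(params["kd"]), float(params["n"]), float(params["dh"])
    if kd <= 0 or n <= 0:
        raise ValueError("kd and n must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = _model_heats_ucal(protocol, kd, n, dh)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        heats = heats + gen.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(protocol=protocol, heats=tuple(heats))


def _model_heats_ucal(protocol: TitrationProtocol,
                      kd: float, n: float, dh: float,
                      offset: float = 0.0) -> np.ndarray:
    m, x, f = protocol.compositions()
    mx = _bound_complex(m, x, kd, n)
    mx_prev = np.concatenate(([0.0], mx[:-1]))
    dmx = mx - f * mx_prev
    q_kcal = dh * protocol.cell_volume * dmx
    return q_kcal * KCAL_TO_UCAL + offset


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess(iso: Isotherm) -> tuple[float, float, float]:
    """Heuristic start: n = 1, ΔH from the first heat, Kd at half-saturation."""
    proto = iso.protocol
    q = np.asarray(iso.heats)
    cell_moles = proto.cell_volume * proto.cell_concentration
    dh0 = q[0] / KCAL_TO_UCAL / cell_moles if cell_moles > 0 else -1.0
    dh0 = dh0 if abs(dh0) > 1e-12 else -1.0
    # molar ratio at which cumulative heat reaches half its asymptote
    cum = np.cumsum(q)
    half = 0.5 * cum[-1]
    ratios = iso.molar_ratios
    idx = int(np.argmin(np.abs(cum - half)))
    kd0 = max(proto.cell_concentration * max(ratios[idx], 0.1) * 0.1, 1e-12)
    return kd0, 1.0, dh0


def fit_one_site(iso: Isotherm, initial_guess: dict | None = None,
                 fit_offset: bool = False,
                 discard_first: bool = False) -> BindingFit:
    """Least-squares fit of (Kd, n, ΔH) to an integrated-heat isotherm.

    Minimises squared residuals against the noiseless forward model in
    log-Kd space with three jittered multi-starts to avoid local minima.
    Standard errors come from the local curvature of the residual surface.
    Never raises on optimizer failure: returns ``converged=False`` instead.

    Parameters
    ----------
    iso : Isotherm
        Observed titration (≥ 5 injections).
    initial_guess : dict, optional
        Overrides for the heuristic start, keys among ``kd``, ``n``, ``dh``.
    fit_offset : bool
        Also fit a constant per-injection heat-of-dilution offset (μcal).
    discard_first : bool
        Exclude the first injection from the residuals.
    """
    if iso.protocol.n_injections < 5:
        raise ValueError("fitting requires at least 5 injections")
    q_obs = np.asarray(iso.heats)
    weight = np.ones_like(q_obs)
    if discard_first:
        weight[0] = 0.0

    scale = np.max(np.abs(q_obs))
    if scale < 1e-12:  # no signal at all: nothing to fit
        return BindingFit.from_parameters(
            kd=1.0, n=1.0, dh=0.0, temperature=iso.protocol.temperature,
            converged=False)

    kd0, n0, dh0 = _initial_guess(iso)
    if initial_guess:
        kd0 = float(initial_guess.get("kd", kd0))
        n0 = float(initial_guess.get("n", n0))
        dh0 = float(initial_guess.get("dh", dh0))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = _model_heats_ucal(
            iso.protocol, math.exp(p["log_kd"].value), p["n"].value,
            p["dh"].value, p["offset"].value)
        return (model - q_obs) * weight

    best = None
    rng = np.random.default_rng(0)  # jitter of the deterministic multi-start
    for start in range(3):
        p = lmfit.Parameters()
        jit = 1.0 if start == 0 else float(np.exp(rng.normal(0, 0.7)))
        p.add("log_kd", value=math.log(kd0 * jit), min=math.log(1e-13),
              max=math.log(10.0))
        p.add("n", value=n0 * (1.0 if start == 0 else float(rng.uniform(0.7, 1.4))),
              min=0.05, max=20.0)
        p.add("dh", value=dh0 * (1.0 if start == 0 else float(rng.uniform(0.5, 1.5))))
        p.add("offset", value=0.0, vary=fit_offset)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return BindingFit.from_parameters(
            kd=kd0, n=n0, dh=dh0, temperature=iso.protocol.temperature,
            converged=False)

    kd = math.exp(best.params["log_kd"].value)
    n = best.params["n"].value
    dh = best.params["dh"].value
    se = {}
    if best.params["log_kd"].stderr is not None:
        se["kd"] = kd * best.params["log_kd"].stderr  # delta method
    for name in ("n", "dh", "offset"):
        if best.params[name].stderr is not None:
            se[name] = best.params[name].stderr
    converged = bool(best.success) and bool(np.isfinite(kd))
    return BindingFit.from_parameters(
        kd=kd, n=n, dh=dh, temperature=iso.protocol.temperature,
        uncertainties=se, converged=converged,
        offset=best.params["offset"].value)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_isotherm_csv(csv_path, meta_path=None) -> Isotherm:
    """Read a titration from CSV (+ optional sidecar JSON).

    The CSV has one row per injection with columns ``injection_volume_uL``
    and ``heat_ucal``. Protocol metadata (``cell_volume_uL``,
    ``syringe_conc_uM``, ``cell_conc_uM``, ``temperature_C``) comes either
    from the sidecar JSON or from ``key,value`` header rows prefixed ``#``.
    """
    meta: dict = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    else:
        with open(csv_path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition(",")
                    meta[key.strip()] = float(value)
    df = pd.read_csv(csv_path, comment="#")
    required = {"injection_volume_uL", "heat_ucal"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    for key in ("cell_volume_uL", "syringe_conc_uM", "cell_conc_uM"):
        if key not in meta:
            raise ValueError(f"missing protocol metadata field {key!r}")
    protocol = TitrationProtocol(
        cell_volume=meta["cell_volume_uL"] * 1e-6,
        syringe_concentration=meta["syringe_conc_uM"] * 1e-6,
        cell_concentration=meta["cell_conc_uM"] * 1e-6,
        injection_volumes=tuple(df["injection_volume_uL"] * 1e-6),
        temperature=meta.get("temperature_C", 25.0) + 273.15,
    )
    return Isotherm(protocol=protocol, heats=tuple(df["heat_ucal"]))


def write_fit_report(fit: BindingFit, iso: Isotherm, json_path, curve_path=None) -> dict:
    """Write the JSON fit report (and optional observed-vs-fitted CSV)."""
    report = {
        "kd_uM": fit.kd * 1e6,
        "n": fit.n,
        "dh_kcal_mol": fit.dh,
        "dg_kcal_mol": fit.dg,
        "minus_tds_kcal_mol": fit.minus_tds,
        "se_kd_uM": fit.uncertainties.get("kd", float("nan")) * 1e6,
        "se_n": fit.uncertainties.get("n", float("nan")),
        "se_dh_kcal_mol": fit.uncertainties.get("dh", float("nan")),
        "converged": fit.converged,
        "temperature_K": fit.temperature,
        "dilution_convention": DILUTION_CONVENTION,
    }
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if curve_path is not None:
        fitted = _model_heats_ucal(iso.protocol, fit.kd, fit.n, fit.dh, fit.offset)
        pd.DataFrame({
            "molar_ratio": iso.molar_ratios,
            "heat_obs_ucal": iso.heats,
            "heat_fit_ucal": fitted,
        }).to_csv(curve_path, index=False)
    return report


# ---------------------------------------------------------------------------
# published reference measurements
# ---------------------------------------------------------------------------

#: Published thermodynamic parameters of the Munc18-1/Mint and Mint1-PTB
#: binding measurements (Kd in μM; energies in kcal/mol at printed
#: precision; se_* are the printed ± uncertainties, 0 where none was
#: printed).  Used to cross-check the thermodynamic identities, not
#: fitted here.
REFERENCE_ITC_TABLE = pd.DataFrame(
    [
        # table, row, kd_uM, se_kd, n, dh, se_dh, minus_tds, se_tds, dg, se_dg
        ("munc18_mint", "Mint1_1 (261-282)", 16.3, 4.2, 0.8, -8.8, 0.6, 2.8, 1.2, -6.5, 0.1),
        ("munc18_mint", "Mint1_1c (266-282)", 23.1, 1.9, 1.0, -1.2, 0.2, -5.4, 0.2, -6.39, 0.01),
        ("munc18_mint", "Mint1_4 (263-282)", 12.9, 0.0, 1.3, -2.30, 0.0, -4.38, 0.0, -6.70, 0.0),
        ("munc18_mint", "Mint1_5 (265-282)", 5.6, 0.0, 1.3, -3.48, 0.0, -3.69, 0.0, -7.17, 0.0),
        ("munc18_mint", "Mint1_6 (267-282)", 4.0, 0.0, 1.2, -1.29, 0.0, -6.08, 0.0, -7.37, 0.0),
        ("munc18_mint", "Mint1_7 (261-280)", 19.1, 0.0, 1.0, -1.78, 0.0, -4.67, 0.0, -6.44, 0.0),
        ("munc18_mint", "Mint1_14 (A275A/E276A)", 216.0, 0.0, 1.0, -57.6, 0.0, 52.6, 0.0, -5.00, 0.0),
        ("munc18_mint", "Mint1_2 (257-286)", 26.0, 0.0, 1.3, -4.21, 0.0, -3.41, 0.0, -7.62, 0.0),
        ("munc18_mint", "Mint1_3 (phosphomimic)", 14.0, 0.0, 1.1, -6.5, 0.0, -0.103, 0.0, -6.60, 0.0),
        ("munc18_mint", "Mint2_2 (phosphomimic)", 200.0, 0.0, 1.0, -17.2, 0.0, 12.2, 0.0, -5.05, 0.0),
        ("sx1a_competition", "Sx1a", 0.07, 0.2, 1.0, -22.5, 2.4, 11.4, 2.3, -11.1, 0.0),
        ("sx1a_competition", "Sx1a + Mint1", 0.27, 0.5, 1.0, -29.7, 1.9, 20.7, 2.4, -9.0, 0.3),
        ("sx1a_competition", "Mint1", 8.7, 0.2, 1.0, -7.9, 0.01, 0.9, 0.02, -6.9, 0.01),
        ("sx1a_competition", "Mint1 + Sx1a", 20.6, 0.7, 1.0, -8.9, 1.9, 2.5, 1.7, -6.4, 0.1),
        ("sx1a_competition", "Sx1a (d317-333)", 0.11, 0.0, 1.0, -18.6, 0.0, 9.1, 0.0, -9.5, 0.0),
        ("sx1a_competition", "Sx1a + Mint1 (d317-333)", 0.09, 0.0, 1.0, -18.8, 0.0, 9.2, 0.0, -9.6, 0.0),
        ("ptb_peptides", "TJAP1 (9-22)", 20.9, 2.4, 1.0, -8.9, 0.9, 2.5, 0.9, -6.4, 0.1),
        ("ptb_peptides", "TJAP1 + APP", 29.4, 9.5, 1.0, -7.1, 1.6, 1.4, 1.8, -6.2, 0.2),
        ("ptb_peptides", "APP (750-769)", 0.31, 0.01, 1.0, -15.6, 0.7, 6.7, 0.6, -8.9, 0.01),
        ("ptb_peptides", "APP + TJAP1", 0.58, 0.01, 1.0, -11.8, 0.1, 1.7, 1.1, -8.5, 0.01),
    ],
    columns=["table", "row", "kd_uM", "se_kd_uM", "n", "dh_kcal_mol",
             "se_dh", "minus_tds_kcal_mol", "se_tds", "dg_kcal_mol", "se_dg"],
)


def _print_rounding(value: float) -> float:
    """Half-ulp of a value printed to its visible decimal places."""
    text = f"{value}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10.0 ** (-decimals)


def check_entropy_identity(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag reference rows where ΔG − (ΔH + (−TΔS)) exceeds the printed
    uncertainties plus print rounding.

    The three quantities were averaged over replicates independently, so
    the identity need not hold exactly for the printed means; rows whose
    residual cannot be absorbed by the printed ± values are flagged.
    """
    table = REFERENCE_ITC_TABLE if table is None else table
    out = table.copy()
    out["identity_residual"] = (
        out["dg_kcal_mol"]
        - (out["dh_kcal_mol"] + out["minus_tds_kcal_mol"])
    ).abs()
    slack = (out["se_dg"] + out["se_dh"] + out["se_tds"]
             + out["dg_kcal_mol"].map(_print_rounding)
             + out["dh_kcal_mol"].map(_print_rounding)
             + out["minus_tds_kcal_mol"].map(_print_rounding))
    out["identity_holds"] = out["identity_residual"] <= slack
    return out


def check_reference_consistency(table: pd.DataFrame | None = None,
                                temperature: float = STANDARD_TEMPERATURE_K,
                                tolerance: float = 0.05) -> pd.DataFrame:
    """Flag reference rows whose printed ΔG disagrees with RT·ln(Kd).

    Returns the table with ``dg_calc_kcal_mol`` and boolean ``consistent``
    columns. Inconsistent rows are flagged, never corrected: the printed
    values stand as published.
    """
    table = REFERENCE_ITC_TABLE if table is None else table
    out = table.copy()
    out["dg_calc_kcal_mol"] = [
        delta_g_from_kd(kd * 1e-6, temperature) for kd in out["kd_uM"]
    ]
    out["consistent"] = (out["dg_calc_kcal_mol"] - out["dg_kcal_mol"]).abs() <= tolerance
    return out
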