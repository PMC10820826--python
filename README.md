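# mintkit

Analysis toolkit for protein-interactome studies that combine isothermal
titration calorimetry (ITC), AlphaFold2-Multimer screening, and TIRF
pHluorin vesicle-fusion imaging — the three computational workflows behind
dissecting how the neuronal Mint adaptors (Mint1/Mint2, X11/APBA) engage
Munc18-1 and their wider partner network.

It provides, as a library and a `mintkit` command line:

1. **`thermo_itc`** — forward simulation and least-squares fitting of the
   one-site (1:1) binding isotherm, and the standard thermodynamic
   conversions. For total macromolecule concentration $M_t$, total ligand
   $X_t$, stoichiometry $n$ and dissociation constant $K_d$, the bound
   complex after each injection is the exact quadratic root

   $$[MX] = \tfrac{1}{2}\left(nM_t + X_t + K_d - \sqrt{(nM_t + X_t + K_d)^2 - 4nM_tX_t}\right),$$

   with displaced-volume dilution applied per injection, and

   $$\Delta G = RT\ln(K_d/1\,\mathrm{M}), \qquad -T\Delta S = \Delta G - \Delta H,$$

   with $R = 1.9872\times10^{-3}$ kcal mol⁻¹ K⁻¹. Fold changes in $K_d$
   quantify ligand competition (e.g. the ~34-fold loss of Syntaxin1a
   affinity for Munc18-1 in the presence of the Mint1 acidic helical
   motif).

2. **`complex_triage`** — screening of ranked predicted-complex bundles
   into direct-interactor verdicts from (i) the across-model mean iPTM
   (gate at 0.3), (ii) inter-chain predicted-aligned-error (PAE) block
   statistics (a "strong off-diagonal signal" operationalised as minimum
   inter-chain PAE ≤ 10 Å with ≥ 1% of pooled block entries below 10 Å),
   (iii) multi-model consistency as the median candidate-chain Cα RMSD
   after Kabsch superposition on the bait backbone, and (iv) interface
   contacts classified as electrostatic, hydrogen-bond/polar or
   hydrophobic.

3. **`fusion_events`** — detection of completed vesicle-fusion events in
   TIRF movies (10 Hz, 106 nm/pixel): 100-frame interval averaging,
   scale-normalised Laplacian-of-Gaussian puncta detection, spatiotemporal
   density clustering (neighbours within one pixel spatially and two
   intervals temporally), disappearance-based event calling, 10 s
   cumulative release curves, per-μm² evoked densities, and two-sided
   Mann–Whitney U group comparisons (exact null when $n_an_b \le 400$
   without ties).

4. **`synthetic_data`** — seeded generators with machine-readable ground
   truth for all three stages: noisy titrations at the study conditions
   (0.7 mM peptide into 50 μM protein), prediction bundles with designed
   iPTM/PAE and an idealised helix-on-receptor geometry, and 3000-frame
   movies with scheduled appearing/disappearing puncta.

## Worked example

Simulate a titration at the study's conditions (Kd = 16.3 μM, ΔH = −8.8
kcal/mol, 20 × 2 μl of 0.7 mM peptide into 200 μl of 50 μM protein, 2%
heat noise) and fit it back:

```bash
mintkit itc-simulate --kd 16.3e-6 --dh -8.8 --noise-sd 0.2 --seed 1 --out demo
mintkit itc-fit demo/isotherm.csv --meta demo/isotherm.meta.json --out demo/fit
```

```json
{
  "kd_uM": 16.620174467455914,
  "n": 1.000214224937972,
  "dh_kcal_mol": -8.786653570325784,
  "dg_kcal_mol": -6.520219663299304,
  "minus_tds_kcal_mol": 2.26643390702648,
  "se_kd_uM": 1.1369471060456937,
  "se_n": 0.021827085111611695,
  "se_dh_kcal_mol": 0.26588103918230055,
  "converged": true,
  "temperature_K": 298.15,
  "dilution_convention": "displaced-volume (perfusion)"
}
```

The fitted Kd (16.6 ± 1.1 μM) recovers the generating 16.3 μM within its
standard error; ΔG = RT·ln Kd ≈ −6.5 kcal/mol and −TΔS = ΔG − ΔH ≈ +2.3
kcal/mol are derived self-consistently — an enthalpy-driven, entropically
penalised binding typical of an induced-fit helical peptide.

Other entry points follow the same pattern:

```bash
mintkit simulate bundle --seed 1 --out bundle     # synthetic prediction bundle
mintkit triage screen.json --out summary.csv      # per-pair verdict table
mintkit simulate movie --seed 1 --out movie       # synthetic TIRF acquisition
mintkit fusion-call movie/movie.tif --meta movie/movie.meta.json --out calls
mintkit fusion-compare groupA.csv groupB.csv      # Mann–Whitney U on densities
```

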