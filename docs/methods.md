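# Methods

This note documents the models, conventions and numerical choices behind
each stage of the toolkit, what the synthetic data do and do not emulate,
and the known limitations.

## One-site ITC model (`thermo_itc`)

**Forward model.** A titration is a sequence of injections of ligand
(syringe species, total concentration $C_s$) into a cell of constant
active volume $V_0$ holding the macromolecule. The single-site binding
scheme gives the bound-complex concentration after injection $i$ as the
numerically stable root of the mass-action quadratic with site
concentration $nM_i$ and total ligand $X_i$. The heat of injection $i$ is

    q_i = ΔH · V0 · ([MX]_i − f_i·[MX]_{i−1}),

the enthalpy of complex newly formed in the active volume, where $f_i$
is the dilution factor of that injection.

**Dilution convention.** The displaced-volume ("perfusion") bookkeeping:
each injection of volume $dV$ dilutes all pre-injection concentrations by
$f = V_0/(V_0+dV)$ and delivers ligand at $C_s\,dV/(V_0+dV)$ — the
well-mixed-then-overflow model that dominant instrument software uses.
The convention is stamped into every fit report so downstream users know
what they fitted. Vendor conventions differ in detail (some apply a
half-injection correction); for the 1% injection-to-cell volume ratios
used here the difference is far below the fitted parameter uncertainty.

**Fitting.** Nonlinear least squares (lmfit/Levenberg–Marquardt) over
(log Kd, n, ΔH) — log-Kd parametrisation keeps Kd positive and makes the
optimisation well-scaled across the nM–mM range. Initialisation: n = 1,
ΔH from the first heat over cell moles, Kd near the observed
half-saturation; three jittered multi-starts (deterministic jitter)
guard against local minima. Standard errors come from the local
curvature of the residual surface (delta method for Kd). An optional
constant per-injection offset models heats of dilution (off by default);
first-injection discard is a flag (off by default). Optimiser failure is
reported as `converged = false`, never an exception. All-zero heats
carry no information about Kd and return `converged = false`.

**Conversions.** ΔG = RT·ln(Kd/1 M) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹
and T defaulting to 298.15 K (all experiments at 25 °C); −TΔS = ΔG − ΔH.
Both identities hold to 1e-9 kcal/mol by construction in every
`BindingFit`. Heats are μcal on input/output, energies kcal/mol.

**Reference measurements.** The published thermodynamic tables for the
Munc18-1/Mint, Sx1a-competition and Mint1-PTB peptide titrations are
bundled as a cross-check dataset. Two consistency screens are applied and
rows failing them are *flagged, never corrected*:

* ΔG vs RT·ln Kd at 298.15 K, tolerance ±0.05 kcal/mol (print
  precision). 17/20 rows agree; three (one row whose printed Kd of
  0.07 μM contradicts both its own ΔG of −11.1 kcal/mol and the
  7.9 nM quoted in the accompanying text, and two peptide rows) do not.
* ΔH + (−TΔS) vs ΔG within the printed ± uncertainties plus half-ulp
  print rounding (the three quantities are replicate averages computed
  independently, so the identity need not bind their printed means).
  19/20 rows agree; one competition row does not.

## Predicted-complex triage (`complex_triage`)

**Inputs.** Ranked models as PDB or mmCIF (read with gemmi), score JSONs
in either common dialect (`pae` or `predicted_aligned_error`, plus
`iptm`/`ptm`/`plddt`), and a manifest listing per-rank file pairs with a
bait/candidate chain map. Author residue numbering is preserved; the
(chain, residue) ↔ PAE-index map is explicit. Missing iPTM loads as
absent; PAE/coordinate dimension mismatches are rejected naming both
counts.

**Gates.** The verdict gate encodes a screening judgment that is
qualitative in practice, so every threshold is configuration:

* iPTM ≥ 0.3 applied to the across-model *mean* (a per-model gate is
  available by switch);
* PAE signal: minimum inter-chain PAE ≤ 10 Å *and* ≥ 1% of the pooled
  off-diagonal block entries < 10 Å. PAE is treated as asymmetric and
  both inter-chain blocks are pooled, making the statistics invariant to
  bait/candidate labelling.

Model consistency and interface contacts are reported as supporting
evidence but do not gate — mirroring a two-stage screen in which pairs
passing the confidence gates get closer manual scrutiny. pLDDT is
reported, not gated.

**Consistency RMSD.** For every model pair, Kabsch superposition (SVD,
proper rotation enforced) on the shared bait Cα atoms, then the
candidate-chain Cα RMSD without further fitting; the median over pairs
is robust to one divergent model among three. Residues missing a Cα in
either model of a pair are skipped.

**Contacts.** Inter-chain heavy-atom pairs within 4.0 Å (kd-tree),
grouped per residue pair and classified with standard structural-biology
cutoffs: electrostatic if an Asp/Glu side-chain O is within 4.0 Å of an
Arg/Lys/His side-chain N; hydrogen-bond/polar if an N/O–N/O pair is
within 3.5 Å; hydrophobic if all contributing pairs are carbon–carbon;
anything else is "other". Precedence: electrostatic > polar >
hydrophobic.

## Fusion-event detection (`fusion_events`)

**Pipeline.** (1) Split the acquisition into fixed 100-frame intervals
(10 s at 10 Hz) and average each; a trailing partial interval is
dropped. (2) Compute the scale-normalised bright-spot LoG response
−σ²·∇²G(σ)∗I at σ = 1.5 px (a diffraction-limited spot at 106 nm/px);
puncta are strict 8-neighbour local maxima above threshold, at integer
pixel positions. The image median is subtracted before filtering so the
response is exactly invariant to a global additive offset (the discrete
truncated kernel does not annihilate constants on its own). The default
threshold is 5× the robust noise sd of the response (1.4826·MAD).
(3) Cluster (x, y, t) puncta with DBSCAN at min_samples = 1 on
per-axis-scaled coordinates under the Chebyshev metric — two puncta are
neighbours iff |Δx| ≤ 1 px, |Δy| ≤ 1 px and |Δt| ≤ 2 intervals — giving
exactly the connected components of that neighbour graph; components
smaller than 3 puncta are discarded as noise (a credible docked vesicle
persists ≥ ~3 intervals; configurable down to 1). A scaled-Euclidean
neighbourhood is available by switch. The temporal axis is
interval-indexed: "two pixels temporally" is read as two 100-frame
intervals, since the [x, y, t] array is built from interval projections.
(4) A cluster is a *completed* fusion event iff its last interval
precedes the final interval; its event time is the end of that interval.
Clusters persisting to the end are censored, never counted.

The pipeline contains no randomness: identical movie and configuration
give identical events.

**Summaries.** Completed events are binned into 10 s bins (30 bins,
0–290 s, for a 300 s acquisition) with a cumulative sum; densities are
completed events (at or after the stimulation time, when one is set) per
μm² of footprint. The default footprint is the largest connected
component of an Otsu threshold on the time-mean image; external masks
are accepted (synthetic cohorts use the full frame, since their flat
background carries no footprint information).

**Mann–Whitney U.** U from midrank sums. Exact two-sided p when
n_a·n_b ≤ 400 with no ties: the null pmf is the Gaussian-binomial
coefficient computed by exact polynomial arithmetic, and p =
2·P(U ≤ min(U, U′)) capped at 1. Otherwise a normal approximation with
tie correction and 0.5 continuity correction. U + U′ = n_a·n_b always.

## Synthetic data (`synthetic_data`)

**Movies** default to the acquisition geometry of the imaging assay:
128×128 px, 3000 frames, 10 Hz, 106 nm pixels, Gaussian spots of
σ = 1.5 px on a constant background of 100 counts with seeded Gaussian
noise (sd 10 counts; Poisson optional). Spot amplitude is expressed as
SNR × noise sd so detection thresholds are scale-free. The random
scheduler places spots ≥ 6 px apart (distinct vesicles never merge into
one cluster), draws event durations of 4–10 intervals, and never lets a
scheduled event reach the final interval, so every scheduled event is a
callable completion; two persistors run to the movie end. Ground truth
(positions, frames, interval indices, completion) is emitted alongside.
Not emulated: EMCCD gain and read-noise structure, photobleaching,
drift, vesicle motion, and cell-shaped footprints — so passing detection
tests demonstrates the pipeline's correctness on its own model of the
data, not robustness to every imaging artefact.

**Titrations** wrap the forward model at the study conditions (0.7 mM
into 50 μM, 20 × 2 μl, 25 °C) with seeded heat noise.

**Prediction bundles** build an idealised receptor (extended Cα trace at
3.8 Å spacing with N/C/O/CB placed at fixed offsets) and an ideal
α-helix partner (rise 1.5 Å, 100°/residue, radius 2.3 Å) laid 7.5 Å
above the receptor mid-segment — the helix-on-domain geometry of a short
motif docking onto a folded bait. PAE matrices use intra-chain error
growing with sequence separation up to a background plateau and a
constant designed inter-chain level (optionally confined to a stripe of
receptor residues); iPTM values are designed per model. Per-model rigid
displacements and coordinate noise exercise the consistency metric; a
designed pose that collides (< 2 Å between chains) is rejected.
Coordinates and scores round-trip through the standard readers (PDB
precision 1e-3 Å). Confidence statistics are designed, not sampled from
real predictor behaviour.

## Problem sizes in tests and the acceptance script

Detection recall/precision uses 20 seeded full-geometry movies
(128×128×3000, SNR 5, 12 scheduled events + 2 persistors). The
two-condition cohort study uses the experiment's group sizes (15 vs 17
cells) with per-cell scheduled event counts Poisson-distributed at rates
15 vs 9 per acquisition (a 40% difference) on reduced movies (64×64 px,
1000 frames, 10 intervals) — the package's chosen desk-scale geometry,
which preserves the per-interval statistics of the full acquisition —
over 50 repetitions in the test suite and 30 in the acceptance script.
The ITC recovery study uses 100 noisy replicates at 2% of the peak heat.

## Known limitations

* The ITC module fits only the single-site model: no multi-site,
  sequential or competitive-displacement schemes, and no raw power-trace
  integration (inputs are integrated heats).
* Triage thresholds encode one reasonable quantification of a visual
  judgment; they are defaults to be tuned per screen, not universal
  constants.
* Event detection does no trajectory linking, photobleaching correction
  or drift correction; a vesicle that moves more than one pixel between
  intervals fragments its cluster.
* The cohort generator models between-cell variability as Poisson counts
  only; real per-cell differences in footprint area, expression level
  and noise are not represented.
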