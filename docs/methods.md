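# Methods

`vesiclefill` analyses and models the re-acidification and glutamate
loading of recycling synaptic vesicles (SVs) as observed with luminal
fluorescent reporters in cultured hippocampal neurons.  This note
documents the models, the parameter choices, the synthetic data used for
validation, and the numerical and design decisions.

## Reporter photophysics (module `traces`)

SynaptopHluorin (SpH) fluorescence titrates with luminal pH following a
Hill-type Henderson–Hasselbalch curve.  With traces normalized between
the resting baseline (luminal pH 5.6) and the climax of stimulation
(surface pH 7.3),

    ΔF(pH) = [f(pH) − f(5.6)] · (1 + 10^{nH(pKa − 7.3)}),
    f(pH)  = 1 / (1 + 10^{nH(pKa − pH)}),

with pKa = 7.09 and nH = 1.35.  ΔF(5.6) = 0 and ΔF(7.3) ≈ 0.985 by
construction; the map is strictly increasing on pH ∈ [3, 10] and is
inverted in closed form.  Note that with these constants ΔF = 1/e
corresponds to pH 6.74, not to pH 6.4 (which corresponds to ΔF ≈ 0.145);
the implementation follows the printed equations throughout.

Re-acidification kinetics are quantified by least-squares fits of
a + b·exp(−t/τ) with τ > 0; the initial τ comes from a log-linear
regression against a plateau guess (mean of the last 10 % of the
segment).  Segments with no decaying component are reported as
non-converged rather than raising.  CypHer-channel traces (quenched at
neutral pH) are sign-inverted before normalization.  Normalization modes
("stim-end" and "quench-first-point") are affine, so fitted τ is
invariant under the choice of mode.

Boutons are sorted into VGLUT-inhibited versus uninhibited classes by
comparing recovery fractions (1 − plateau ΔF) between a control run and a
run after Rose Bengal application; the recovery threshold defaults to
0.5, a value not constrained by data — on clean synthetic populations the
classification is insensitive to it over a wide range.

## Bouton detection (module `spotdetect`)

Functional boutons are detected on the stimulation difference image
(mean of the last frames of stimulation minus mean of baseline frames)
with an undecimated à trous wavelet transform: at scale j the B3-spline
kernel [1,4,6,4,1]/16, dilated by 2^(j−1) and applied separably with
mirror boundaries, smooths the previous approximation, and the detail
plane is the difference of successive smooths.  The transform is exactly
invertible by summation, which the test suite asserts on random images.

The detection mask is the support of the multiscale product of detail
planes 2..k (plane 1 is noise dominated), each hard-thresholded at
ld · k_MAD · σ_j with σ_j the plane's robust noise (MAD/0.6745),
k = 4, ld = 1.0 and k_MAD = 3 by default.  The exact thresholding rule
behind the published "detection level" is not reproducible from the
available description; the MAD-scaled multiscale product is this
package's declared substitute, with ld exposed as the scaling knob.
Components are 8-connected, sub-PSF components (< 4 px) are discarded,
and experiments with 50 or fewer boutons are rejected (strict
inequality).  Per-bouton traces are component means per frame minus the
median of a surrounding ring that excludes all detected components, so
any uniform background offset cancels exactly.

## Dual-ratiometric Cl⁻/pH sensor (module `clophensor`)

The vesicular ClopHensor-type sensor reports R_pH = F488/F458 and
R_Cl = F458/F565.  Inversion uses

    pH    = pKa + log10((R_pH − R_A)/(R_B − R_pH)),
    [Cl⁻] = Kd_Cl(pH) · (R_Cl − R_free)/(R_bound(pH) − R_Cl),

with R_bound(pH) = M·pH + R_bound,pH0 and
Kd_Cl(pH) = ¹Kd_Cl · (1 + 10^{pKa−pH}) / 10^{pKa−pH}.  The sensor pKa is
7.49 and M = 0.061 per pH unit.  The remaining constants are not
published for the vesicular fusion; the synthetic defaults
(R_A = 0.4, R_B = 2.4, R_free = 0.8, R_bound,pH0 = 1.9, ¹Kd = 9.7 mM)
are chosen so that Kd at the resting luminal pH 5.6 is ≈ 9.8 mM, making
the 90 %-saturation bound 9·Kd ≈ 88.4 mM — consistent with the
saturation regime reported for transporter-deficient vesicles.  The
resting luminal pH used when inverting vesicular R_Cl measurements is
taken as 5.6; this is an assumption, not a fitted quantity.

Calibration fitting is two-stage for identifiability: the R_pH sigmoid
first (pKa, R_A, R_B), then the chloride arm across pH groups
(R_free, R_bound,pH0, M, ¹Kd) with pKa held fixed.  95 % confidence
intervals come from the asymptotic fit covariance under a multiplicative
per-ratio noise model.

Because Kd rises steeply above the sensor pKa, a fixed chloride-arm
ratio implies a larger concentration at more alkaline pH; below about
pH 6.5 the Kd curve is nearly flat and the weak R_bound slope dominates,
so the relation is only guaranteed monotone above the acidic range.

## Single-vesicle flux model (module `fluxmodel`)

### State and conserved quantities

One vesicle of fixed volume 20×10⁻²¹ l and membrane capacitance 50 aF.
State: total added protons (free + buffer-bound, relative to the engulfed
state), glutamate, Cl⁻, cation count, and net charge, all as molecule
counts.  ΔΨ = net charge × e / C.  Free H⁺ is a fractional count (a
vesicle at pH 7.3 holds ~6×10⁻⁴ free protons).  Luminal buffers are at
fast equilibrium: at every step the pH solves the proton-conservation
equation by a bracketed root solve (pH ∈ [3, 9.8], tolerance 1e−10).
Buffers: engulfed HEPES (pKa 7.55), histidine (6.0), TRIS (8.3),
gluconate (3.7) and methanesulfonate (−1.2) as configured, the protein
matrix (13 mM histidine-like pKa 6.0 and 47 mM glutamate-like pKa 4.0
residues), and the glutamate imported during loading (pKa 4.0).  The
matrix histidine pKa is switchable; 6.0 reproduces the ~150 buffered
protons per 0.9 pH-unit drop that anchors the pump-rate estimate, the
alternative reading (pKa 4) gives ~130.

### Fluxes

* **V-ATPase.**  J = n_pumps · rate_max · s_load(pmf) · s_volt(ΔΨ), with
  n_pumps = 1.5 and rate_max = 200 H⁺/s.  The load curve
  s_load = 1 − (pmf/pmf_stall)³ is flat at low proton-motive force and
  steep near stall; pmf = ΔΨ + (RT·ln10/F)(pH_cyt − pH_lum) and
  pmf_stall = 106.5 mV = (RT·ln10/F)·1.8, so at ΔΨ = 0 pumping
  equilibrates exactly at luminal pH 5.5.  A linear load curve would
  halve the pump rate already at half-stall, which is incompatible with
  the ~300 H⁺/s aggregate influx inferred during loading; the cubic
  exponent is exposed (`pump_stall_exponent`).  The multiplicative
  voltage gate s_volt (sigmoid, half-block 50 mV, width 0.8 mV) encodes
  the observation that chloride-driven charging alone — which can reach
  at most the Cl⁻ Nernst potential, ≈ 57 mV for 129.5 mM against a
  14 mM cytosol — stalls pumping when glutamate transport is inhibited,
  while the pump still runs during normal loading at 20–45 mV.
* **VGLUT glutamate/H⁺ exchange.**  n_vglut = 10 transporters at
  rate_max = 20 glutamate/s import glutamate⁻ and export n_H = 1.5 H⁺
  each (between the 1:1 and 1:2 coupling limits).  The drive factor is
  clip(−ΔG/(0.2·RT), 0, 1) with
  ΔG/RT = ln([glu]_lum/[glu]_cyt) − (1+n_H)·FΔΨ/RT
  + n_H·ln10·(pH_lum − pH_cyt): a forward-biased cycle that runs at full
  speed until within a fraction of RT of equilibrium, as required to
  sustain the ~180 glutamate/s aggregate rate the flux budget implies.
  The cytosolic glutamate activity defaults to 10 mM.  An osmotic brake
  clip(1 − Δosm/4.5 mM, 0, 1) acts on the anion-side excess
  Δosm = [glu] + [Cl⁻] − [anions]_engulfed: the vesicle is engulfed
  isotonic and can accommodate only a small excess before water entry
  would swell it (volume is held fixed).  With the engulfed 129.5 mM of
  anions this makes ≈ 120 mM the osmotic fixed point of loading once
  Cl⁻ has fallen to the cytosolic level.  An optional luminal-Cl⁻
  activation factor [Cl]/([Cl]+Kd) is available but off by default.
* **Cl⁻ channel.**  A channel-like anion conductance carried by the
  transporter copies, computed with the Goldman–Hodgkin–Katz flux
  equation (well behaved for an empty lumen, where a linear
  conductance–driving-force product diverges); permeability 0.8
  molecules/s per mM per copy.  Rose Bengal zeroes glutamate transport
  but scales the channel only by 0.8.
* **Counterion leak.**  A VGLUT-independent ohmic counterion pathway
  (0.5 charges/s per mV, reversal 0 mV) that inactivates above ≈ 48 mV.
  This element is required by the data set itself: charge and proton
  conservation force final glutamate = (buffer-bound H⁺) + (Cl⁻
  released) ≈ 140 mM in any model containing only the pump, the
  exchanger and the Cl⁻ channel, so the measured endpoint combination
  (≈120 mM glutamate, luminal Cl⁻ at the cytosolic level, pH 5.5) is
  unreachable without a dissipative pathway.  Independently, vesicles
  lacking the transporter altogether still acidify rapidly, which
  requires the same kind of pathway; and its voltage-inactivation is
  forced by the observation that Rose-Bengal-treated vesicles (parked at
  the Cl⁻-charged potential) do not acidify at all.  The
  transporter-free ("ko") preset uses a stronger leak (30 charges/s/mV)
  so that acidification is leak-shunted and an order of magnitude faster
  than control.

### Calibration

Printed quantities are used as-is: volume, capacitance, copy numbers,
unit rates (200 H⁺/s, 20 glutamate/s), stoichiometry 1.5, buffer
concentrations and pKa values, pmf_stall, cytosolic Cl⁻ 14 mM, external
pH 7.3.  The unprinted parameters (Cl⁻ permeability, leak conductance
and gate, pump voltage gate, drive margin, osmotic headroom, cytosolic
glutamate) were calibrated once, jointly, against the four published
endpoints — control τ ≈ 4.9 s, uncoupled τ ≈ 0.5 s, steady-state pH 5.5,
final glutamate ≈ 120 mM — and then frozen; they are not adjusted per
scenario.

### Integration

Adaptive explicit Heun with per-step buffer re-equilibration.  The step
is accepted when the Heun–Euler discrepancy in membrane potential is
below 0.2 mV; steps halve on rejection (floor 10⁻⁷ s) and grow
gradually (cap 10 ms, well inside the explicit stability limit of the
millisecond-scale ΔΨ relaxation).  Charge and species ledgers are
accumulated with the same quadrature as the state, so conservation holds
to round-off; `ledger_residuals` exposes the residuals and the test
suite asserts them below 10⁻⁶ of a charge/molecule.  A 60 s control run
integrates in a few seconds.

### Known limitations

* Coupled Cl⁻-substitution scenarios (low engulfed Cl⁻, transporter
  active, no Rose Bengal) simulate fast (≈ 0.5 s) because with neither
  luminal Cl⁻ nor osmotic headroom the exchanger is nearly silent and
  the condition degenerates to the pump-only case.  The measured
  kinetics in that condition are an order of magnitude slower,
  attributed to massive proton antiport without net glutamate
  accumulation; a futile exchange of that kind cannot be added without
  simultaneously destroying the control endpoints through the same
  charge-closure argument given above, so it is left out and the
  discrepancy is documented rather than patched.
* For the same reason the gluconate/HEPES plateau series reproduces the
  published ordering (plateau pH decreasing as HEPES drops 25→20→5 mM)
  but compressed in magnitude: the counterion pathways that allow full
  re-acidification in the uncoupled condition also operate here.
* The model window is ~1 min post-endocytosis; slower dissipative
  processes that equilibrate resting vesicles over minutes are outside
  it.
* Cations other than the generic counterion, ClC-type exchangers, and
  osmotic volume changes are not modelled; fractional copy numbers act
  as deterministic rate scalings.

## Synthetic data (module `synthgen`)

The generator emulates the study's observables with known ground truth:

* **Traces.**  Baseline + amplitude × pool curve: piecewise-linear rise
  over the stimulation train (200 AP at 20 Hz by default, i.e. 10 s),
  then plateau + (1 − plateau)·exp(−t/τ); with an acid-quench window the
  surface component is removed at quench onset and the retained
  endocytosed fraction decays with the same τ.  Default noise is
  additive Gaussian with σ = 2 % of the peak amplitude (no noise figures
  are published; the default is set so detection and fitting behave
  comfortably above threshold).  Classes: glutamatergic (full recovery),
  inhibited (plateau ΔF 0.985), GABAergic (CypHer channel).
* **Image stacks.**  Gaussian spots (unit-peak, σ = 1.5 px at the
  2×2-binned scale) on a constant background with Gaussian or Poisson
  noise; the noise-free integrated spot intensity equals
  trace × 2π σ².  Spots are placed by seeded rejection sampling with a
  6 σ minimum separation — overlapping boutons are deliberately not
  generated (segmentation of overlaps is out of scope).
* **Calibration tables.**  (pH, Cl⁻, R_pH, R_Cl) grids from the forward
  sensor model with multiplicative noise.

All generators take explicit integer seeds and are bit-reproducible;
every artifact carries a serializable `GroundTruth` record.  Synthetic
data do not emulate bleaching, drift, vignetting, chromatic offsets or
camera-specific noise, so passing tests demonstrate correctness of the
algorithms under the stated model, not robustness to those artefacts.

## Pipeline and reproducibility

`pipeline.run` chains generate/ingest → detect → extract → normalize →
fit → invert → report with a single seed; identical configurations give
byte-identical reports.  Population statistics are mean ± s.e.m. across
boutons within an experiment.  `scripts/acceptance.py` re-runs the
calibrated simulator from scratch and writes the fitted control and
uncoupled time constants and the control endpoints as JSON.
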