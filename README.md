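# vesiclefill

Quantitative analysis and biophysical modelling of glutamate loading into
recycling synaptic vesicles, built around live-cell imaging with luminal
pH- and chloride-sensitive fluorescent reporters in hippocampal neurons.

Synaptic vesicles retrieved by endocytosis engulf ~130 mM extracellular
Cl⁻ and re-acidify while the vesicular glutamate transporter (VGLUT)
refills them.  The package implements the full analysis chain for such
experiments and the mechanistic model that explains them — VGLUT acting
as a glutamate/H⁺ exchanger with a channel-like Cl⁻ conductance, so that
Cl⁻ efflux both powers the initial membrane potential and is exchanged,
nearly one for one, against incoming glutamate:

* **`vesiclefill.synthgen`** — synthetic fluorescence traces, Gaussian-spot
  image stacks and sensor calibration tables with persisted ground truth
  (every analysis step here is validated by parameter recovery).
* **`vesiclefill.spotdetect`** — functional-bouton detection on
  stimulation difference images with the à trous (starlet) B3-spline
  wavelet transform (depth k = 4, detection level l_d = 1.0), plus
  ring-background-corrected trace extraction.
* **`vesiclefill.traces`** — ΔF normalization, mono-exponential
  re-acidification fits, the Hill/Henderson–Hasselbalch ΔF↔pH map
  (pKa 7.09, n_H 1.35, reference pHs 5.6/7.3) and Rose-Bengal bouton
  sorting.
* **`vesiclefill.clophensor`** — calibration and inversion of the
  dual-ratiometric Cl⁻/pH sensor:
  pH = pKa + log₁₀((R_pH − R_A)/(R_B − R_pH)) and
  [Cl⁻] = K_d(pH)·(R_Cl − R_free)/(R_bound(pH) − R_Cl) with
  pH-dependent K_d.
* **`vesiclefill.fluxmodel`** — a single-vesicle electro-chemical
  simulator (V-ATPase with proton-motive-force stall, VGLUT
  glutamate/nH⁺ exchange with n_H = 1.5, GHK Cl⁻ channel flux, luminal
  buffers at fast equilibrium, membrane capacitance 50 aF, volume
  20 zl) plus the closed-form proton/charge budget calculators.
* **`vesiclefill.pipeline`** — validated end-to-end runs behind the
  `vesiclefill` command-line tool.

## Worked example

Simulate the control condition — a vesicle that engulfed 129.5 mM Cl⁻
in 25 mM HEPES at pH 7.3 — and fit its predicted fluorescence decay:

```
$ vesiclefill simulate --scenario control
{
  "scenario": "control",
  "tau_s": 4.8266358885301015,
  "final_ph": 5.505842231265379,
  "final_glu_mM": 119.77431679147278,
  "final_cl_mM": 14.22071187361691,
  "final_psi_mv": 0.3525446967401355
}
```

The vesicle re-acidifies with a mono-exponential time constant of ≈4.8 s
from pH 7.3 to a steady state of pH ≈5.5, finishing with ≈120 mM
glutamate while luminal Cl⁻ has dropped to the cytosolic level
(≈14 mM) and the membrane potential has returned to ~0 mV — loading is
electrically and osmotically near-neutral.  Blocking glutamate transport
and substituting Cl⁻ by an impermeant anion uncouples the transporter
from the pump, and acidification collapses to the pump/buffer limit:

```
$ vesiclefill simulate --scenario uncoupled
{
  "scenario": "uncoupled",
  "tau_s": 0.5014563804992108,
  ...
}
```

which matches the closed-form budget: ~156 protons buffered between
pH 7.3 and 6.4, pumped by 1.5 V-ATPases at ~200 H⁺/s each
(`vesiclefill budget` prints these numbers).

A full synthetic end-to-end run — render 100 boutons as an image stack,
detect them by wavelet thresholding, extract and fit every trace:

```
$ python -c "
from vesiclefill import pipeline
cfg = pipeline.validate_config({
    'synthetic': {'mode': 'stack', 'n_boutons': 100,
                  'field_size': (256, 256), 'tau_s': 4.9},
    'output_dir': 'out', 'seed': 3})
r = pipeline.run(cfg)
print(r['n_detected'], r['tau_mean_s'], r['plateau_ph_mean'])"
100 4.896500679163684 5.4540379578203435
```

All 100 boutons are recovered and the fitted mean τ reproduces the
generating value within the noise.  Other subcommands: `synth`,
`detect`, `fit`, `calibrate`, `invert-cl`, `suite` (all named scenario
presets in one table) and `run` (YAML/JSON config).

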