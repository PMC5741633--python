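"""End-to-end orchestration: generate/ingest → detect → extract → fit →
invert → report, behind a validated configuration.

A run takes exactly one input source — a TIFF stack, a trace CSV, or a
synthetic-data specification — pushes it through bouton detection (for
stacks), trace normalization, mono-exponential fitting and ΔF→pH
inversion, and writes a JSON report plus CSV tables.  Runs are
deterministic given the configured seed; for synthetic sources the report
includes truth-versus-estimate comparisons.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import fluxmodel, spotdetect, synthgen, traces as traces_mod
from .errors import ConfigError
from .protocol import make_protocol
from .spotdetect import DetectionParams
from .traces import PhotophysicsParams

log = logging.getLogger("vesiclefill")

__all__ = ["RunConfig", "validate_config", "run"]


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    frame_rate_hz: float = 5.0
    n_aps: int = 200
    ap_rate_hz: float = 20.0
    quench: bool = False
    baseline_s: float = 5.0
    post_stim_s: float = 60.0


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = Field("traces", pattern="^(traces|stack)$")
    n_boutons: int = 100
    tau_s: float = 4.9
    amplitude: float = 50.0
    noise_sd: float = synthgen.DEFAULT_NOISE_SD
    inhibited_fraction: float = 0.0
    field_size: tuple[int, int] = (256, 256)
    psf_sigma: float = synthgen.DEFAULT_PSF_SIGMA
    background: float = 100.0


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(4, ge=1)
    ld: float = Field(1.0, gt=0)
    min_boutons: int = Field(50, ge=0)
    connectivity: int = Field(8, json_schema_extra={"enum": [4, 8]})
    k_mad: float = Field(3.0, gt=0)
    min_area_px: int = Field(4, ge=1)


class PhotophysicsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pka: float = 7.09
    nh: float = 1.35
    ph_rest: float = 5.6
    ph_surface: float = 7.3


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    stack_path: str | None = None
    traces_path: str | None = None
    synthetic: SyntheticConfig | None = None
    protocol: ProtocolConfig = ProtocolConfig()
    detection: DetectionConfig = DetectionConfig()
    photophysics: PhotophysicsConfig = PhotophysicsConfig()
    scenarios: list[str] = []
    output_dir: str = "vesiclefill_out"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        sources = [s is not None for s in
                   (self.stack_path, self.traces_path, self.synthetic)]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: stack_path, traces_path "
                "or synthetic"
            )
        for p in (self.stack_path, self.traces_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input file {p!r} does not exist")
        return self


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`.

    All schema violations are collected into one :class:`ConfigError`.
    """
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines))


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run(config: RunConfig) -> dict:
    """Execute a full analysis run and write the report.

    Returns the report dict (also written to ``output_dir/report.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pp = PhotophysicsParams(**config.photophysics.model_dump())
    det = DetectionParams(**config.detection.model_dump())
    proto_cfg = config.protocol
    report: dict = {"seed": config.seed}

    truth = None
    if config.synthetic is not None:
        t0 = _stage("synthesize")
        syn = config.synthetic
        protocol = make_protocol(
            proto_cfg.frame_rate_hz, proto_cfg.n_aps, proto_cfg.ap_rate_hz,
            quench=proto_cfg.quench, baseline_s=proto_cfg.baseline_s,
            post_stim_s=proto_cfg.post_stim_s)
        kinetics = {
            "glutamatergic": synthgen.KineticParams(
                tau_s=syn.tau_s, amplitude=syn.amplitude),
            "inhibited": synthgen.KineticParams(
                tau_s=syn.tau_s, amplitude=syn.amplitude, plateau_df=0.985),
        }
        fractions = {"glutamatergic": 1.0 - syn.inhibited_fraction,
                     "inhibited": syn.inhibited_fraction}
        truth_traces, truth = synthgen.simulate_truth_traces(
            protocol, kinetics, syn.n_boutons, class_fractions=fractions,
            noise_sd=syn.noise_sd, seed=config.seed)
        if syn.mode == "stack":
            stack, truth = synthgen.render_image_stack(
                truth_traces, truth, field_size=syn.field_size,
                psf_sigma=syn.psf_sigma, background=syn.background,
                seed=config.seed + 1)
            bouton_traces = _detect_and_extract(stack, protocol, det, report)
            if bouton_traces is None:
                report["rejected"] = True
                _write_report(out, report)
                return report
        else:
            bouton_traces = truth_traces
        (out / "ground_truth.json").write_text(truth.to_json())
        log.info("synthesize done in %.2f s", time.perf_counter() - t0)
    elif config.stack_path is not None:
        t0 = _stage("load stack")
        stack = tifffile.imread(config.stack_path).astype(float)
        protocol = make_protocol(
            proto_cfg.frame_rate_hz, proto_cfg.n_aps, proto_cfg.ap_rate_hz,
            quench=proto_cfg.quench, baseline_s=proto_cfg.baseline_s,
            post_stim_s=proto_cfg.post_stim_s)
        bouton_traces = _detect_and_extract(stack, protocol, det, report)
        if bouton_traces is None:
            report["rejected"] = True
            _write_report(out, report)
            return report
    else:
        t0 = _stage("load traces")
        protocol = make_protocol(
            proto_cfg.frame_rate_hz, proto_cfg.n_aps, proto_cfg.ap_rate_hz,
            quench=proto_cfg.quench, baseline_s=proto_cfg.baseline_s,
            post_stim_s=proto_cfg.post_stim_s)
        bouton_traces = synthgen.read_traces_csv(config.traces_path)

    t0 = _stage("fit")
    rows = []
    a, b = protocol.post_stim_frames
    for tr in bouton_traces:
        try:
            ntr = traces_mod.normalize_trace(tr, protocol)
        except traces_mod.DegenerateTraceError:
            continue
        if b - a < 5:
            continue
        fit = traces_mod.fit_monoexponential(ntr.time_s[a:b], ntr.f[a:b])
        ph = np.nan
        if fit.converged:
            lo = traces_mod.deltaF_from_pH(traces_mod.PH_MIN, pp)
            hi = traces_mod.deltaF_from_pH(traces_mod.PH_MAX, pp)
            ph = traces_mod.pH_from_deltaF(
                min(max(fit.plateau, lo), hi), pp)
        rows.append({
            "bouton_id": tr.bouton_id,
            "tau_s": fit.tau_s if fit.converged else np.nan,
            "plateau_dF": fit.plateau if fit.converged else np.nan,
            "plateau_pH": ph,
            "converged": fit.converged,
            "class": tr.meta.get("class", "") if tr.meta else "",
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "bouton_fits.csv", index=False)
    ok = table[table["converged"]] if len(table) else table
    report["n_boutons"] = int(len(table))
    report["n_converged"] = int(len(ok))
    if len(ok):
        report["tau_mean_s"] = float(ok["tau_s"].mean())
        report["tau_sem_s"] = float(ok["tau_s"].sem()) if len(ok) > 1 else 0.0
        report["plateau_ph_mean"] = float(ok["plateau_pH"].mean())
    if truth is not None and len(ok):
        truth_df = pd.DataFrame(truth.bouton_params)
        merged = ok.merge(truth_df, on="bouton_id", suffixes=("", "_true"))
        recovering = merged[merged["class_true"] == "glutamatergic"]
        report["truth_comparison"] = {
            "tau_true_s": float(truth_df["tau_s"].iloc[0]),
            "tau_recovered_mean_s": float(recovering["tau_s"].mean())
            if len(recovering) else float("nan"),
        }
    log.info("fit done in %.2f s", time.perf_counter() - t0)

    if config.scenarios:
        t0 = _stage("simulate")
        suite = fluxmodel.scenario_suite(config.scenarios)
        suite.to_csv(out / "scenario_suite.csv", index=False)
        report["scenarios"] = suite.to_dict(orient="records")
        log.info("simulate done in %.2f s", time.perf_counter() - t0)

    _write_report(out, report)
    return report


def _detect_and_extract(stack, protocol, det, report):
    """Difference image → wavelet mask → acceptance → trace extraction."""
    t0 = _stage("detect")
    diff = spotdetect.difference_image(stack, protocol)
    planes = spotdetect.atrous_transform(diff, det.k)
    mask = spotdetect.detection_mask(planes, det)
    report["n_detected"] = mask.n_components
    if not spotdetect.accept_experiment(mask, det):
        log.warning("experiment rejected: %d boutons (need > %d)",
                    mask.n_components, det.min_boutons)
        return None
    traces = spotdetect.extract_traces(
        stack, mask, frame_rate_hz=protocol.frame_rate_hz)
    log.info("detect done in %.2f s (%d boutons)",
             time.perf_counter() - t0, mask.n_components)
    return traces


def _write_report(out: Path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(type(o))

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=default,
                   allow_nan=True))
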