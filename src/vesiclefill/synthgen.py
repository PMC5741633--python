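"""Synthetic data with persisted ground truth for every pipeline input.

Three generators cover the pipeline's inputs end to end:

* per-bouton fluorescence traces following the canonical stimulation
  response (linear rise during the AP train, mono-exponential surface
  removal / re-acidification afterwards, optional acid-quench segment);
* multi-frame image stacks of Gaussian-spot boutons on a noisy background,
  rendered from those traces;
* dual-ratio calibration tables produced by the forward sensor model.

Every artifact carries a :class:`GroundTruth` record of all generating
parameters so downstream recovery can be tested quantitatively.  All
randomness flows through explicit integer seeds; identical seeds and
parameters give bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .clophensor import ClopHCalibration, ratios_from_state
from .errors import InvalidArgumentError
from .protocol import SolutionSpec, StimulusProtocol, make_protocol  # noqa: F401  (re-export)
from .traces import BoutonTrace

__all__ = [
    "KineticParams", "GroundTruth",
    "make_protocol", "StimulusProtocol", "SolutionSpec",
    "simulate_truth_traces", "render_image_stack",
    "make_cl_calibration_dataset",
    "write_stack_tiff", "write_traces_csv", "read_traces_csv",
]

#: default relative additive noise (sd as a fraction of the peak amplitude)
DEFAULT_NOISE_SD = 0.02

#: default isotropic PSF sigma in (2x2-binned) pixels
DEFAULT_PSF_SIGMA = 1.5


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetics of one bouton class.

    ``plateau_df`` is the ΔF level the trace settles at after stimulation
    (0 for fully recovering boutons, ~0.985 for RB-inhibited boutons that
    never re-acidify).  ``quench_retained`` is the fraction of the peak
    signal that survives the instantaneous surface quench (the newly
    endocytosed, not-yet-acidified pool).
    """

    tau_s: float = 4.9
    amplitude: float = 50.0
    plateau_df: float = 0.0
    baseline: float = 100.0
    quench_retained: float = 0.6
    channel: str = "SpH"


@dataclass
class GroundTruth:
    """Record of every generating parameter of one synthetic dataset."""

    seed: int
    kind: str = "traces"
    bouton_positions: list = field(default_factory=list)   # (row, col) pairs
    bouton_params: list = field(default_factory=list)      # per-bouton dicts
    calibration: dict | None = None
    flux_params: dict | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["bouton_positions"] = [tuple(p) for p in d["bouton_positions"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def _pool_curve(t: np.ndarray, protocol: StimulusProtocol,
                kp: KineticParams) -> np.ndarray:
    """Normalized response (0 at baseline, 1 at the climax of stimulation)."""
    t0, t1 = protocol.stim_start_s, protocol.stim_end_s
    r = np.zeros_like(t)
    rising = (t >= t0) & (t < t1)
    r[rising] = (t[rising] - t0) / (t1 - t0)
    post = t >= t1
    if protocol.quench_window is not None:
        tq = protocol.quench_window[0] / protocol.frame_rate_hz
        pre_q = post & (t < tq)
        r[pre_q] = 1.0
        in_q = t >= tq
        decay = np.exp(-(t[in_q] - tq) / kp.tau_s)
        level = kp.quench_retained * (kp.plateau_df +
                                      (1.0 - kp.plateau_df) * decay)
        r[in_q] = level
    else:
        decay = np.exp(-(t[post] - t1) / kp.tau_s)
        r[post] = kp.plateau_df + (1.0 - kp.plateau_df) * decay
    return r


def simulate_truth_traces(
    protocol: StimulusProtocol,
    kinetics: dict[str, KineticParams],
    n_boutons: int,
    class_fractions: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[list[BoutonTrace], GroundTruth]:
    """Generate ``n_boutons`` traces with known per-bouton kinetics.

    ``kinetics`` maps class names (e.g. ``"glutamatergic"``, ``"inhibited"``,
    ``"gabaergic"``) to their parameters; ``class_fractions`` gives the
    sampling probabilities (defaults to uniform over the classes).
    ``noise_sd`` is additive Gaussian noise relative to the peak amplitude.
    """
    if n_boutons < 1:
        raise InvalidArgumentError("n_boutons must be >= 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if not kinetics:
        raise InvalidArgumentError("kinetics must be non-empty")
    names = sorted(kinetics)
    if class_fractions is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        probs = np.array([class_fractions.get(n, 0.0) for n in names])
        if probs.sum() <= 0:
            raise InvalidArgumentError("class_fractions sum to zero")
        probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    t = protocol.frame_times_s
    assignments = rng.choice(len(names), size=n_boutons, p=probs)
    traces, params = [], []
    for bid in range(n_boutons):
        cls = names[assignments[bid]]
        kp = kinetics[cls]
        r = _pool_curve(t, protocol, kp)
        f = kp.baseline + kp.amplitude * r
        if kp.channel == "CypHer":
            f = kp.baseline - kp.amplitude * r
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd * kp.amplitude, size=f.shape)
        traces.append(BoutonTrace(bouton_id=bid, time_s=t, f=f,
                                  channel=kp.channel,
                                  meta={"class": cls}))
        params.append({"bouton_id": bid, "class": cls,
                       "tau_s": kp.tau_s, "amplitude": kp.amplitude,
                       "plateau_df": kp.plateau_df,
                       "baseline": kp.baseline, "channel": kp.channel})
    truth = GroundTruth(seed=int(seed), kind="traces", bouton_params=params,
                        extra={"noise_sd": noise_sd,
                               "n_boutons": int(n_boutons)})
    return traces, truth


# ---------------------------------------------------------------------------
# image-stack rendering
# ---------------------------------------------------------------------------

def _place_boutons(rng: np.random.Generator, n: int,
                   field_size: tuple[int, int], margin: float,
                   min_sep: float) -> list[tuple[float, float]]:
    """Rejection-sample spot centres with a minimum pairwise separation."""
    positions: list[tuple[float, float]] = []
    h, w = field_size
    for _ in range(20000):
        if len(positions) == n:
            break
        cand = (margin + rng.random() * (h - 2 * margin),
                margin + rng.random() * (w - 2 * margin))
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep ** 2
               for p in positions):
            positions.append(cand)
    if len(positions) < n:
        raise InvalidArgumentError(
            f"could not place {n} boutons in a {field_size} field with "
            f"min separation {min_sep}"
        )
    return positions


def render_image_stack(
    traces: list[BoutonTrace],
    truth: GroundTruth,
    field_size: tuple[int, int] = (128, 128),
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    background: float = 100.0,
    noise_model: str = "gaussian",
    noise_sd: float = 2.0,
    seed: int = 0,
    positions: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render traces as Gaussian spots on a constant background.

    Frame ``f`` is ``background + Σ_i trace_i(f)·G(x − x_i; psf_sigma)``
    plus noise, where the Gaussian has unit peak so that the noise-free
    integrated spot intensity equals ``trace_value · 2π·psf_sigma²``.
    Spots are placed with a seeded rejection sampler unless explicit
    ``positions`` are given.  Returns the float stack (frames, rows, cols)
    and an updated ground-truth record.
    """
    if psf_sigma <= 0:
        raise InvalidArgumentError("psf_sigma must be > 0")
    if noise_model not in ("gaussian", "poisson"):
        raise InvalidArgumentError("noise_model must be gaussian or poisson")
    h, w = field_size
    rng = np.random.default_rng(seed)
    margin = max(4.0 * psf_sigma, 4.0)
    if positions is None:
        positions = _place_boutons(rng, len(traces), field_size, margin,
                                   min_sep=6.0 * psf_sigma)
    for r, c in positions:
        if not (0 <= r < h and 0 <= c < w):
            raise InvalidArgumentError(f"bouton position {(r, c)} outside "
                                       f"field {field_size}")
    n_frames = traces[0].time_s.size
    stack = np.full((n_frames, h, w), float(background))
    half = int(np.ceil(5.0 * psf_sigma))
    for tr, (r0, c0) in zip(traces, positions):
        ri, ci = int(round(r0)), int(round(c0))
        rs = slice(max(ri - half, 0), min(ri + half + 1, h))
        cs = slice(max(ci - half, 0), min(ci + half + 1, w))
        rr, cc = np.mgrid[rs, cs]
        g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * psf_sigma ** 2))
        stack[:, rs, cs] += tr.f[:, None, None] * g[None, :, :]
    if noise_model == "gaussian" and noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    elif noise_model == "poisson":
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    out_truth = dataclasses.replace(
        truth, kind="stack",
        bouton_positions=[(float(r), float(c)) for r, c in positions],
        extra={**truth.extra, "field_size": list(field_size),
               "psf_sigma": psf_sigma, "background": background,
               "noise_model": noise_model, "image_noise_sd": noise_sd,
               "render_seed": int(seed)},
    )
    return stack, out_truth


# ---------------------------------------------------------------------------
# calibration datasets
# ---------------------------------------------------------------------------

def make_cl_calibration_dataset(
    cal_truth: ClopHCalibration,
    ph_grid,
    cl_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tabulate (pH, [Cl-], R_pH, R_Cl) on a grid via the forward sensor
    model, with optional multiplicative Gaussian noise on both ratios."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    cl_grid = np.asarray(cl_grid, dtype=float)
    if ph_grid.size == 0 or cl_grid.size == 0:
        raise InvalidArgumentError("grids must be non-empty")
    if np.any(cl_grid < 0):
        raise InvalidArgumentError("cl_grid must be >= 0")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ph, cl = (a.ravel() for a in np.meshgrid(ph_grid, cl_grid, indexing="ij"))
    ph = np.tile(ph, n_replicates)
    cl = np.tile(cl, n_replicates)
    r_ph, r_cl = ratios_from_state(ph, cl, cal_truth)
    if noise_sd > 0:
        r_ph = r_ph * (1.0 + rng.normal(0.0, noise_sd, r_ph.shape))
        r_cl = r_cl * (1.0 + rng.normal(0.0, noise_sd, r_cl.shape))
    df = pd.DataFrame({"ph": ph, "cl_mM": cl, "r_ph": r_ph, "r_cl": r_cl})
    truth = GroundTruth(seed=int(seed), kind="calibration",
                        calibration=cal_truth.to_dict(),
                        extra={"noise_sd": noise_sd,
                               "n_replicates": int(n_replicates)})
    return df, truth


# ---------------------------------------------------------------------------
# external formats
# ---------------------------------------------------------------------------

def write_stack_tiff(path, stack: np.ndarray) -> None:
    """Write a stack as multi-page 16-bit unsigned TIFF (values clipped)."""
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def write_traces_csv(path, traces: list[BoutonTrace]) -> None:
    rows = []
    for tr in traces:
        for t, f in zip(tr.time_s, tr.f):
            rows.append({"time_s": t, "bouton_id": tr.bouton_id,
                         "channel": tr.channel, "F": f})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path) -> list[BoutonTrace]:
    df = pd.read_csv(path)
    traces = []
    for (bid, chan), grp in df.groupby(["bouton_id", "channel"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(BoutonTrace(bouton_id=int(bid),
                                  time_s=grp["time_s"].to_numpy(),
                                  f=grp["F"].to_numpy(), channel=str(chan)))
    return traces
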