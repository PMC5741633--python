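"""Bouton fluorescence trace kinetics and the ΔF ↔ pH photophysics map.

The pH-sensitive reporter (a superecliptic pHluorin fused to synaptobrevin 2)
titrates with a Hill-type Henderson–Hasselbalch curve.  With traces
normalized between the resting baseline (luminal pH 5.6) and the climax of
stimulation (surface pH 7.3),

    ΔF(pH) = [ f(pH) − f(5.6) ] · (1 + 10^{nH (pKa − 7.3)}),
    f(pH)  = 1 / (1 + 10^{nH (pKa − pH)}),

with pKa = 7.09 and Hill coefficient nH = 1.35, so ΔF(5.6) = 0 and
ΔF(7.3) ≈ 0.985.  The inverse map recovers the average luminal pH of the
recycling reporter pool from any normalized fluorescence level, and the
re-acidification time course is quantified by a mono-exponential fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import (DegenerateTraceError, InvalidArgumentError,
                     OutOfRangeError)
from .protocol import StimulusProtocol

__all__ = [
    "PhotophysicsParams", "BoutonTrace", "ExpFit",
    "normalize_trace", "fit_monoexponential",
    "deltaF_from_pH", "pH_from_deltaF", "plateau_pH", "classify_boutons",
]

PH_MIN, PH_MAX = 3.0, 10.0  # invertible range enforced on the ΔF↔pH map


@dataclass(frozen=True)
class PhotophysicsParams:
    """Hill/Henderson–Hasselbalch constants of the pHluorin reporter."""

    pka: float = 7.09
    nh: float = 1.35
    ph_rest: float = 5.6      # resting luminal pH -> ΔF = 0
    ph_surface: float = 7.3   # surface/extracellular pH -> ΔF ≈ 0.985

    def __post_init__(self):
        if self.nh <= 0:
            raise InvalidArgumentError("nh must be > 0")
        if not self.ph_rest < self.ph_surface:
            raise InvalidArgumentError("ph_rest must be < ph_surface")

    def _f(self, ph):
        return 1.0 / (1.0 + 10.0 ** (self.nh * (self.pka - np.asarray(ph, dtype=float))))


@dataclass
class BoutonTrace:
    """Time-stamped fluorescence of one bouton in one channel.

    ``channel`` is ``"SpH"`` (bright at neutral pH) or ``"CypHer"``
    (quenched at neutral pH, i.e. negative-going during stimulation).
    """

    bouton_id: int
    time_s: np.ndarray
    f: np.ndarray
    channel: str = "SpH"
    normalized: bool = False
    border_flagged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time_s.shape != self.f.shape:
            raise InvalidArgumentError("time_s and f must have equal length")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise InvalidArgumentError("time_s must be strictly increasing")
        if self.channel not in ("SpH", "CypHer"):
            raise InvalidArgumentError("channel must be 'SpH' or 'CypHer'")


@dataclass(frozen=True)
class ExpFit:
    """Result of a mono-exponential decay fit a + b·exp(−t/τ)."""

    tau_s: float
    amplitude: float
    plateau: float
    residual_rms: float
    converged: bool


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_trace(trace: BoutonTrace, protocol: StimulusProtocol,
                    mode: str = "stim-end") -> BoutonTrace:
    """Normalize a raw trace to ΔF units.

    ``mode="stim-end"``: ΔF(t) = (F − mean baseline) / (mean end-of-stim −
    mean baseline), i.e. baseline ↦ 0 and the climax of stimulation ↦ 1.
    ``mode="quench-first-point"``: additionally rescale so that the first
    frame of the post-stimulus acid-quench window is 1 (used to compare
    re-acidification kinetics across conditions with different amplitudes).

    CypHer traces are sign-inverted before normalization (the dye is
    quenched at neutral pH, so its stimulation response is negative-going).
    """
    f = trace.f.astype(float)
    if trace.channel == "CypHer":
        f = -f
    b0, b1 = protocol.baseline_window
    e0, e1 = protocol.stim_end_window()
    if b1 <= b0 or e1 <= e0:
        raise InvalidArgumentError("empty baseline or stimulation-end window")
    f0 = f[b0:b1].mean()
    fmax = f[e0:e1].mean()
    rng = fmax - f0
    scale = max(abs(f.max() - f.min()), abs(fmax), 1.0)
    if abs(rng) < 1e-12 * scale:
        raise DegenerateTraceError(
            f"bouton {trace.bouton_id}: zero dynamic range between baseline "
            f"and end of stimulation"
        )
    df = (f - f0) / rng
    if mode == "quench-first-point":
        if protocol.quench_window is None:
            raise InvalidArgumentError(
                "quench-first-point mode requires a quench window"
            )
        q0 = protocol.quench_window[0]
        ref = df[q0]
        if abs(ref) < 1e-12:
            raise DegenerateTraceError("first quench frame has ΔF = 0")
        df = df / ref
    elif mode != "stim-end":
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    return replace(trace, f=df, channel="SpH" if trace.channel == "CypHer"
                   else trace.channel, normalized=True)


# ---------------------------------------------------------------------------
# mono-exponential fitting
# ---------------------------------------------------------------------------

def _monoexp(t, a, b, tau):
    return a + b * np.exp(-t / tau)


def fit_monoexponential(time_s: np.ndarray, f: np.ndarray) -> ExpFit:
    """Least-squares fit of a + b·exp(−t/τ) with τ > 0 to a decay segment.

    The initial τ comes from a log-linear regression on (f − plateau guess),
    the plateau guess being the mean of the last 10 % of the segment.  A
    segment with no decaying component (fitted b ≤ 0 or failure to converge)
    is reported with ``converged=False`` rather than raising.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(f, dtype=float)
    if t.size < 5:
        raise InvalidArgumentError("segment must have >= 5 points")
    t = t - t[0]
    tail = max(int(0.1 * t.size), 1)
    a0 = y[-tail:].mean()
    resid0 = y - a0
    b0 = resid0[0]
    failed = ExpFit(math.nan, math.nan, math.nan, math.nan, False)
    if b0 <= 0:
        return failed
    # log-linear initial slope estimate on the positive part of the residual
    pos = resid0 > max(1e-3 * b0, 1e-12)
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(resid0[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3 or 1.0
    else:
        tau0 = (t[-1] - t[0]) / 3 or 1.0
    tau0 = min(max(tau0, 1e-3), 10 * (t[-1] + 1e-9))
    try:
        popt, _ = curve_fit(
            _monoexp, t, y, p0=(a0, b0, tau0),
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return failed
    a, b, tau = popt
    if b <= 1e-12 or not np.isfinite(tau):
        return failed
    rms = float(np.sqrt(np.mean((y - _monoexp(t, *popt)) ** 2)))
    return ExpFit(tau_s=float(tau), amplitude=float(b), plateau=float(a),
                  residual_rms=rms, converged=True)


# ---------------------------------------------------------------------------
# ΔF ↔ pH map
# ---------------------------------------------------------------------------

def deltaF_from_pH(ph, pp: PhotophysicsParams = PhotophysicsParams()):
    """Normalized fluorescence ΔF at luminal pH (scalar or array).

    ΔF(ph_rest) = 0 and ΔF(ph_surface) ≈ 0.985 for the default constants.
    """
    ph = np.asarray(ph, dtype=float)
    if np.any(ph < PH_MIN) or np.any(ph > PH_MAX):
        raise OutOfRangeError(f"pH outside [{PH_MIN}, {PH_MAX}]")
    out = (pp._f(ph) - pp._f(pp.ph_rest)) * \
        (1.0 + 10.0 ** (pp.nh * (pp.pka - pp.ph_surface)))
    return float(out) if out.ndim == 0 else out


def pH_from_deltaF(df, pp: PhotophysicsParams = PhotophysicsParams()):
    """Exact algebraic inverse of :func:`deltaF_from_pH`."""
    df = np.asarray(df, dtype=float)
    lo = deltaF_from_pH(PH_MIN, pp)
    hi = deltaF_from_pH(PH_MAX, pp)
    if np.any(df < lo) or np.any(df > hi):
        raise OutOfRangeError(
            f"ΔF outside invertible range [{lo:.4g}, {hi:.4g}]"
        )
    denom = 1.0 + 10.0 ** (pp.nh * (pp.pka - pp.ph_surface))
    fval = pp._f(pp.ph_rest) + df / denom
    out = pp.pka - np.log10(1.0 / fval - 1.0) / pp.nh
    return float(out) if out.ndim == 0 else out


def plateau_pH(trace: BoutonTrace, protocol: StimulusProtocol,
               pp: PhotophysicsParams = PhotophysicsParams()) -> tuple[float, ExpFit]:
    """Steady-state luminal pH from the post-stimulus plateau of a trace.

    The trace is normalized ("stim-end" mode), its post-stimulus segment is
    fitted mono-exponentially, and the fitted plateau ΔF is mapped to pH.
    Returns ``(pH, fit)``; a non-converged fit propagates as pH = nan.
    """
    tr = trace if trace.normalized else normalize_trace(trace, protocol)
    a, b = protocol.post_stim_frames
    if b - a < 5:
        raise InvalidArgumentError("post-stimulus segment has < 5 frames")
    fit = fit_monoexponential(tr.time_s[a:b], tr.f[a:b])
    if not fit.converged:
        return math.nan, fit
    lo = deltaF_from_pH(PH_MIN, pp)
    hi = deltaF_from_pH(PH_MAX, pp)
    plateau = min(max(fit.plateau, lo), hi)
    return pH_from_deltaF(plateau, pp), fit


# ---------------------------------------------------------------------------
# bouton classification (VGLUT-inhibition sorting)
# ---------------------------------------------------------------------------

def classify_boutons(traces_probe: list[BoutonTrace],
                     traces_post_rb: list[BoutonTrace],
                     protocol: StimulusProtocol,
                     protocol_rb: StimulusProtocol | None = None,
                     recovery_threshold: float = 0.5) -> dict[int, str]:
    """Sort boutons by their response to the VGLUT inhibitor Rose Bengal.

    Each bouton is recorded twice: a control run and a run after RB
    application.  The recovery fraction of a run is 1 − ΔF at the fitted
    post-stimulus plateau.  A bouton is ``"inhibited"`` (VGLUT-positive,
    re-acidification blocked by RB) when its RB-run recovery falls below
    ``recovery_threshold`` while its control recovery is at or above it;
    otherwise it is ``"uninhibited"``.
    """
    protocol_rb = protocol_rb or protocol
    probe = {t.bouton_id: t for t in traces_probe}
    post = {t.bouton_id: t for t in traces_post_rb}
    if set(probe) != set(post):
        raise InvalidArgumentError(
            "probe and post-RB trace sets must cover the same bouton ids"
        )

    def recovery(tr, proto):
        ntr = tr if tr.normalized else normalize_trace(tr, proto)
        a, b = proto.post_stim_frames
        fit = fit_monoexponential(ntr.time_s[a:b], ntr.f[a:b])
        plateau = fit.plateau if fit.converged else float(np.mean(ntr.f[b - max((b - a) // 10, 1):b]))
        return 1.0 - plateau

    labels = {}
    for bid in probe:
        rec_ctrl = recovery(probe[bid], protocol)
        rec_rb = recovery(post[bid], protocol_rb)
        inhibited = rec_rb < recovery_threshold <= rec_ctrl
        labels[bid] = "inhibited" if inhibited else "uninhibited"
    return labels
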