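"""Stimulation/acquisition protocols and extracellular solution specifications.

A :class:`StimulusProtocol` describes one imaging experiment on a single time
axis: a baseline window, a field-stimulation pulse train (e.g. 200 action
potentials at 20 Hz), and optionally a rapid acid-quench window that starts
immediately after the end of stimulation.  Frame indices are 0-based and
windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import InvalidArgumentError

#: total substitutable anion concentration of the standard bath (mM):
#: 119 NaCl + 2x2 CaCl2 + 2x2 MgCl2 + 2.5 KCl.
TOTAL_ANION_MM = 129.5

_SUBSTITUTES = ("none", "gluconate", "methanesulfonate", "iodide")


@dataclass(frozen=True)
class SolutionSpec:
    """Ionic composition of the solution engulfed during endocytosis.

    ``chloride_mM + substitute_mM`` equals the standard total anion
    concentration (129.5 mM) in every preset; custom combinations are allowed
    but concentrations must be non-negative.
    """

    chloride_mM: float = TOTAL_ANION_MM
    substitute_anion: str = "none"
    substitute_mM: float = 0.0
    hepes_mM: float = 25.0
    histidine_mM: float = 0.0
    tris_mM: float = 0.0
    ph_external: float = 7.3

    def __post_init__(self):
        if self.substitute_anion not in _SUBSTITUTES:
            raise InvalidArgumentError(
                f"substitute_anion must be one of {_SUBSTITUTES}, "
                f"got {self.substitute_anion!r}"
            )
        for name in ("chloride_mM", "substitute_mM", "hepes_mM",
                     "histidine_mM", "tris_mM"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.substitute_anion == "none" and self.substitute_mM > 0:
            raise InvalidArgumentError(
                "substitute_mM > 0 requires a named substitute_anion"
            )

    @classmethod
    def standard(cls, hepes_mM: float = 25.0,
                 histidine_mM: float = 0.0) -> "SolutionSpec":
        """Normal-chloride bath (129.5 mM Cl-)."""
        return cls(hepes_mM=hepes_mM, histidine_mM=histidine_mM)

    @classmethod
    def substituted(cls, chloride_mM: float, anion: str,
                    hepes_mM: float = 25.0,
                    histidine_mM: float = 0.0) -> "SolutionSpec":
        """Bath with Cl- partially replaced by a large impermeant anion,
        keeping the total anion concentration at 129.5 mM."""
        if not 0 <= chloride_mM <= TOTAL_ANION_MM:
            raise InvalidArgumentError(
                f"chloride_mM must be in [0, {TOTAL_ANION_MM}]"
            )
        return cls(chloride_mM=chloride_mM, substitute_anion=anion,
                   substitute_mM=TOTAL_ANION_MM - chloride_mM,
                   hepes_mM=hepes_mM, histidine_mM=histidine_mM)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of one imaging run: acquisition, stimulation, optional quench."""

    frame_rate_hz: float
    n_frames: int
    baseline_window: tuple[int, int]
    stim_start_s: float
    stim_duration_s: float
    quench_window: tuple[int, int] | None = None
    solution: SolutionSpec = field(default_factory=SolutionSpec)

    def __post_init__(self):
        if self.frame_rate_hz <= 0:
            raise InvalidArgumentError("frame_rate_hz must be > 0")
        if self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")
        windows = [("baseline_window", self.baseline_window)]
        if self.quench_window is not None:
            windows.append(("quench_window", self.quench_window))
        for name, (a, b) in windows:
            if not (0 <= a < b <= self.n_frames):
                raise InvalidArgumentError(
                    f"{name} {a, b} not within [0, {self.n_frames})"
                )
        if self.stim_duration_s <= 0:
            raise InvalidArgumentError("stim_duration_s must be > 0")

    # -- derived timing ----------------------------------------------------
    @property
    def frame_times_s(self):
        import numpy as np
        return np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def stim_end_s(self) -> float:
        return self.stim_start_s + self.stim_duration_s

    def frames_in(self, t0: float, t1: float) -> tuple[int, int]:
        """Half-open frame range covering times [t0, t1)."""
        a = int(math.ceil(t0 * self.frame_rate_hz - 1e-9))
        b = int(math.ceil(t1 * self.frame_rate_hz - 1e-9))
        return max(a, 0), min(max(b, a), self.n_frames)

    @property
    def stim_frames(self) -> tuple[int, int]:
        return self.frames_in(self.stim_start_s, self.stim_end_s)

    def stim_end_window(self, n_avg: int = 3) -> tuple[int, int]:
        """The last ``n_avg`` frames of the stimulation period (the maximum
        fluorescence change used for difference imaging / normalization)."""
        a, b = self.stim_frames
        return max(b - n_avg, a), b

    @property
    def post_stim_frames(self) -> tuple[int, int]:
        a, _ = self.frames_in(self.stim_end_s, self.n_frames / self.frame_rate_hz)
        return a, self.n_frames


def make_protocol(frame_rate_hz: float, n_aps: int, ap_rate_hz: float,
                  quench: bool = False, *,
                  baseline_s: float = 5.0, post_stim_s: float = 60.0,
                  solution: SolutionSpec | None = None) -> StimulusProtocol:
    """Build a protocol for ``n_aps`` action potentials at ``ap_rate_hz``.

    The stimulation duration is ``n_aps / ap_rate_hz``.  When ``quench`` is
    set, the acid-quench window starts immediately after the end of
    stimulation and extends to the end of the recording.
    """
    if frame_rate_hz <= 0 or ap_rate_hz <= 0:
        raise InvalidArgumentError("rates must be > 0")
    if n_aps <= 0 or int(n_aps) != n_aps:
        raise InvalidArgumentError("n_aps must be a positive integer")
    stim_duration_s = n_aps / ap_rate_hz
    n_frames = int(round((baseline_s + stim_duration_s + post_stim_s)
                         * frame_rate_hz))
    proto = StimulusProtocol(
        frame_rate_hz=frame_rate_hz,
        n_frames=n_frames,
        baseline_window=(0, max(int(baseline_s * frame_rate_hz), 1)),
        stim_start_s=baseline_s,
        stim_duration_s=stim_duration_s,
        quench_window=None,
        solution=solution or SolutionSpec(),
    )
    if quench:
        q0, _ = proto.frames_in(proto.stim_end_s, n_frames / frame_rate_hz)
        proto = StimulusProtocol(
            frame_rate_hz=frame_rate_hz, n_frames=n_frames,
            baseline_window=proto.baseline_window,
            stim_start_s=baseline_s, stim_duration_s=stim_duration_s,
            quench_window=(q0, n_frames), solution=proto.solution,
        )
    return proto
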