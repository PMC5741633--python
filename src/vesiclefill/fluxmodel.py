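"""Single-vesicle electro-chemical flux model and closed-form ion budgets.

The model integrates, for one synaptic vesicle (volume 20 zl, membrane
capacitance 50 aF), the coupled dynamics of

* the V-ATPase proton pump (~1.5 copies, ~200 H+/s each at zero load),
  slowed linearly by the proton-motive force pmf = ΔΨ + (RT·ln10/F)·ΔpH and
  additionally blocked by a steep membrane-voltage gate — the vesicle
  engulfs ~129.5 mM Cl-, and channel-mediated Cl- efflux alone can charge
  the membrane far enough to stall pumping when glutamate uptake is
  inhibited;
* the vesicular glutamate transporter (~10 copies, ~20 glutamate/s each),
  modelled as a glutamate-/nH+ exchanger (nH = 1.5, i.e. between the 1:1
  and 1:2 coupling limits) with a thermodynamically consistent driving
  factor 1 − exp(ΔG/RT) and an osmotic brake on excess luminal load;
* a channel-like Cl- conductance carried by the transporter itself
  (GHK flux; Rose Bengal blocks glutamate transport but only scales the
  anion conductance by ~0.8);
* luminal proton buffers at fast equilibrium (Henderson–Hasselbalch,
  per-step monotone root solve), including the endogenous protein matrix
  (13 mM histidine-like pKa 6, 47 mM glutamate-like pKa 4 residues),
  exogenous HEPES/histidine/TRIS, weakly buffering anion substitutes
  (gluconate pKa 3.7, methanesulfonate pKa −1.2), and the glutamate
  imported during loading (pKa 4).

Free H+ is a fractional count (a vesicle at pH 7.3 holds ~0.0006 free
protons); membrane potential follows the net charge on the capacitance.
Charge and proton ledgers are accumulated alongside the state so that
conservation can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import IntegrationError, InvalidArgumentError
from .protocol import SolutionSpec, TOTAL_ANION_MM
from .traces import PhotophysicsParams, deltaF_from_pH, fit_monoexponential

__all__ = [
    "BufferSpecies", "FluxParams", "VesicleState", "TimeCourse",
    "buffer_bound_fraction", "bound_protons", "infer_pump_rate",
    "charges_for_voltage", "molecules_from_concentration",
    "nernst_potential", "buffers_from_solution", "default_matrix_buffers",
    "simulate", "scenario", "scenario_suite", "proton_budget_report",
    "SCENARIO_NAMES",
]

# physical constants
E_CHARGE = 1.602176634e-19      # C
AVOGADRO = 6.02214076e23        # 1/mol
R_GAS = 8.314462618             # J/(mol K)
FARADAY = 96485.33212           # C/mol

GLUTAMATE_PKA = 4.0             # luminal glutamate gamma-carboxyl buffer


@dataclass(frozen=True)
class BufferSpecies:
    """One luminal proton buffer (exogenous solute or matrix residue)."""

    name: str
    concentration_mM: float
    pka: float
    mobile: bool = True

    def __post_init__(self):
        if self.concentration_mM < 0:
            raise InvalidArgumentError("concentration_mM must be >= 0")


@dataclass(frozen=True)
class FluxParams:
    """Pump/transporter/channel parameters of the vesicle model.

    Copy numbers, unit rates, volume and capacitance are the published
    per-vesicle estimates.  ``pmf_stall_mv`` defaults to
    (RT·ln10/F)·(7.3 − 5.5) ≈ 106.5 mV so that with ΔΨ = 0 the pump
    equilibrates exactly at luminal pH 5.5.  ``v_block_mv``/``v_block_slope_mv``
    parameterize the steep voltage gate of the pump; ``cl_permeability`` is
    the per-transporter Cl- channel permeability (molecules/s per mM at zero
    voltage); ``glu_cyt_mM`` is an effective cytosolic glutamate activity
    calibrated jointly with the 1.5 H+/glutamate stoichiometry so that
    glutamate equilibrates near 120 mM once the proton-motive force is spent.
    """

    volume_l: float = 20e-21
    capacitance_f: float = 50e-18
    n_pumps: float = 1.5
    pump_rate_max: float = 200.0          # H+/s per pump
    n_vglut: float = 10.0
    vglut_rate_max: float = 20.0          # glutamate/s per transporter
    n_h: float = 1.5                      # H+ exported per glutamate
    cl_permeability: float = 0.8          # per VGLUT copy, /s/mM
    rb_block: bool = False
    rb_cl_factor: float = 0.8
    pmf_stall_mv: float = 106.5
    pump_stall_exponent: float = 3.0      # load curve 1 - (pmf/stall)^q
    v_block_mv: float = 50.0
    v_block_slope_mv: float = 0.8
    vglut_drive_margin_rt: float = 0.2    # RT units of ΔG over which the
    #                                       transport rate ramps to maximum
    cl_activation_kd_mM: float = 0.0      # optional luminal Cl- activation
    #                                       of glutamate transport (0 = off)
    osm_max_excess_mM: float = 4.5        # osmotic headroom over the
    #                                       engulfed anion load
    temperature_k: float = 298.0
    ph_cyt: float = 7.3
    cl_cyt_mM: float = 14.0
    glu_cyt_mM: float = 10.0
    counterion_leak_per_mv: float = 0.5   # charges/s per mV, 0 mV reversal
    leak_gate_mv: float = 48.0            # leak inactivates above this ΔΨ
    leak_gate_width_mv: float = 2.0
    matrix_his_pka: float = 6.0

    def __post_init__(self):
        for name in ("pump_rate_max", "vglut_rate_max", "cl_permeability",
                     "n_pumps", "n_vglut", "counterion_leak_per_mv"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not 1.0 <= self.n_h <= 2.0:
            raise InvalidArgumentError("n_h must be in [1, 2]")
        if self.pmf_stall_mv <= 0:
            raise InvalidArgumentError("pmf_stall_mv must be > 0")
        if self.volume_l <= 0 or self.capacitance_f <= 0:
            raise InvalidArgumentError("volume and capacitance must be > 0")

    @property
    def count_per_mM(self) -> float:
        return 1e-3 * self.volume_l * AVOGADRO

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VesicleState:
    """Luminal state snapshot (all species as molecule counts)."""

    ph: float
    psi_mv: float
    free_h: float
    bound_h: dict
    cl_count: float
    glu_count: float
    impermeant_anion_count: float
    cation_count: float
    net_charge: float


@dataclass
class TimeCourse:
    """Simulated trajectory with conservation ledgers."""

    time_s: np.ndarray
    ph: np.ndarray
    psi_mv: np.ndarray
    cl_mM: np.ndarray
    glu_mM: np.ndarray
    df: np.ndarray                 # predicted normalized SpH fluorescence
    ledger: dict                   # cumulative flux totals (counts)
    final_state: VesicleState
    params: FluxParams
    solution: SolutionSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "ph": self.ph, "psi_mv": self.psi_mv,
            "cl_mM": self.cl_mM, "glu_mM": self.glu_mM, "df": self.df,
        })


# ---------------------------------------------------------------------------
# closed-form budget calculators
# ---------------------------------------------------------------------------

def buffer_bound_fraction(ph, pka):
    """Protonated fraction 1/(1 + 10^(pH − pKa)) of a buffer."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def bound_protons(buffers: list[BufferSpecies], ph_start: float,
                  ph_end: float, volume_l: float = 20e-21) -> float:
    """H+ taken up by the listed buffers when the lumen acidifies from
    ``ph_start`` to ``ph_end`` (counts; positive for acidification)."""
    if ph_end >= ph_start:
        if ph_end == ph_start:
            return 0.0
        raise InvalidArgumentError("ph_end must be < ph_start")
    total = 0.0
    for b in buffers:
        n = b.concentration_mM * 1e-3 * volume_l * AVOGADRO
        total += n * (buffer_bound_fraction(ph_end, b.pka)
                      - buffer_bound_fraction(ph_start, b.pka))
    return float(total)


def infer_pump_rate(bound_count: float, tau_s: float,
                    n_pumps: float) -> float:
    """Initial H+ pumping rate per pump from the buffered-proton count and
    the acidification time constant."""
    if tau_s <= 0 or n_pumps <= 0:
        raise InvalidArgumentError("tau_s and n_pumps must be > 0")
    return bound_count / (tau_s * n_pumps)


def charges_for_voltage(capacitance_f: float, voltage_v: float) -> float:
    """Elementary charges needed to hold ``voltage_v`` on the capacitance."""
    if capacitance_f <= 0:
        raise InvalidArgumentError("capacitance must be > 0")
    return capacitance_f * voltage_v / E_CHARGE


def molecules_from_concentration(conc_mM: float, volume_l: float) -> float:
    """Molecule count at a given concentration in the vesicle volume."""
    if conc_mM < 0:
        raise InvalidArgumentError("conc_mM must be >= 0")
    return conc_mM * 1e-3 * volume_l * AVOGADRO


def nernst_potential(z: int, conc_out_mM: float, conc_in_mM: float,
                     temperature_k: float = 298.0) -> float:
    """Nernst reversal potential (mV, inside minus outside convention)."""
    if conc_out_mM <= 0 or conc_in_mM <= 0:
        raise InvalidArgumentError("concentrations must be > 0")
    return (R_GAS * temperature_k / (z * FARADAY)
            * math.log(conc_out_mM / conc_in_mM) * 1e3)


# ---------------------------------------------------------------------------
# buffer sets
# ---------------------------------------------------------------------------

SUBSTITUTE_PKA = {"gluconate": 3.7, "methanesulfonate": -1.2}

HEPES_PKA = 7.55
HISTIDINE_PKA = 6.0
TRIS_PKA = 8.3


def default_matrix_buffers(his_pka: float = 6.0) -> list[BufferSpecies]:
    """Endogenous luminal protein-matrix buffers: histidine-like (13 mM)
    and glutamate-like (47 mM) residues."""
    return [
        BufferSpecies("matrix_histidine", 13.0, his_pka, mobile=False),
        BufferSpecies("matrix_glutamate", 47.0, GLUTAMATE_PKA, mobile=False),
    ]


def buffers_from_solution(solution: SolutionSpec,
                          matrix_his_pka: float = 6.0,
                          include_matrix: bool = True) -> list[BufferSpecies]:
    """Buffer list for a vesicle that engulfed the given solution."""
    out: list[BufferSpecies] = []
    if solution.hepes_mM > 0:
        out.append(BufferSpecies("HEPES", solution.hepes_mM, HEPES_PKA))
    if solution.histidine_mM > 0:
        out.append(BufferSpecies("histidine", solution.histidine_mM,
                                 HISTIDINE_PKA))
    if solution.tris_mM > 0:
        out.append(BufferSpecies("TRIS", solution.tris_mM, TRIS_PKA))
    if solution.substitute_mM > 0 and \
            solution.substitute_anion in SUBSTITUTE_PKA:
        out.append(BufferSpecies(solution.substitute_anion,
                                 solution.substitute_mM,
                                 SUBSTITUTE_PKA[solution.substitute_anion]))
    if include_matrix:
        out.extend(default_matrix_buffers(matrix_his_pka))
    return out


# ---------------------------------------------------------------------------
# simulator internals
# ---------------------------------------------------------------------------

def _ghk_flux_in(perm: float, z: int, psi_v: float, c_out: float,
                 c_in: float, rt_f: float) -> float:
    """GHK (constant-field) flux into the lumen, counts/s, for permeability
    ``perm`` in counts/s per mM at zero voltage."""
    if perm == 0.0:
        return 0.0
    u = z * psi_v / rt_f
    if abs(u) < 1e-9:
        return perm * (c_out - c_in)
    u = min(max(u, -60.0), 60.0)
    return -perm * u * (c_out - c_in * math.exp(u)) / (1.0 - math.exp(u))


class _Engine:
    """Derivative/pH-solve machinery bound to one (params, solution) pair."""

    def __init__(self, params: FluxParams, solution: SolutionSpec,
                 ph_init: float):
        self.p = params
        self.sol = solution
        self.ph_init = ph_init
        self.rt_f = R_GAS * params.temperature_k / FARADAY     # volts
        self.rt_ln10_f_mv = self.rt_f * math.log(10.0) * 1e3   # mV per pH
        self.per_mM = params.count_per_mM
        self.buffers = buffers_from_solution(
            solution, matrix_his_pka=params.matrix_his_pka)
        self.buf_n = np.array([b.concentration_mM * self.per_mM
                               for b in self.buffers])
        self.buf_pka = np.array([b.pka for b in self.buffers])
        self.buf_f0 = buffer_bound_fraction(ph_init, self.buf_pka)
        self.h_free0 = 10.0 ** (-ph_init) * params.volume_l * AVOGADRO * 1e3

    # fast-equilibrium pH from conserved total added H+ ---------------------
    def _h_balance(self, ph: float, h_added: float, glu_count: float):
        h_free = 10.0 ** (-ph) * self.p.volume_l * AVOGADRO * 1e3
        bound = float(np.sum(self.buf_n *
                             (buffer_bound_fraction(ph, self.buf_pka)
                              - self.buf_f0)))
        bound += glu_count * buffer_bound_fraction(ph, GLUTAMATE_PKA)
        return h_free - self.h_free0 + bound - h_added

    def solve_ph(self, h_added: float, glu_count: float) -> float:
        lo, hi = 3.0, 9.8
        if self._h_balance(lo, h_added, glu_count) <= 0:
            return lo
        if self._h_balance(hi, h_added, glu_count) >= 0:
            return hi
        return brentq(self._h_balance, lo, hi,
                      args=(h_added, glu_count), xtol=1e-10)

    # instantaneous fluxes --------------------------------------------------
    def fluxes(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Return (dy/dt, raw flux vector, pH, ΔΨ[mV]) at state ``y``.

        State ``y`` = (added H+, glutamate, Cl-, cation, net charge), all in
        molecule/elementary-charge counts.  Raw fluxes are
        (pump H+ in, VGLUT H+ out, VGLUT glutamate in, Cl- in, cation in).
        """
        p = self.p
        h_added, glu, cl, cat, q = y
        ph = self.solve_ph(h_added, glu)
        psi_v = q * E_CHARGE / p.capacitance_f
        psi_mv = psi_v * 1e3

        # V-ATPase: load curve flat at low pmf, steep near stall, times a
        # steep membrane-voltage gate
        pmf_mv = psi_mv + self.rt_ln10_f_mv * (p.ph_cyt - ph)
        load = min(max(pmf_mv / p.pmf_stall_mv, 0.0), 1.0)
        s_thermo = 1.0 - load ** p.pump_stall_exponent
        x = min(max((psi_mv - p.v_block_mv) / p.v_block_slope_mv, -50.0), 50.0)
        s_volt = 1.0 / (1.0 + math.exp(x))
        j_pump = p.n_pumps * p.pump_rate_max * s_thermo * s_volt

        # VGLUT glutamate/H+ exchange
        j_glu = 0.0
        if not p.rb_block and p.n_vglut > 0 and p.vglut_rate_max > 0:
            glu_mM = max(glu, 0.0) / self.per_mM
            dg_rt = (math.log(max(glu_mM, 1e-9) / p.glu_cyt_mM)
                     - (1.0 + p.n_h) * psi_v / self.rt_f
                     + p.n_h * math.log(10.0) * (ph - p.ph_cyt))
            drive = min(max(-dg_rt / p.vglut_drive_margin_rt, 0.0), 1.0)
            # osmotic load tracked on the anion side (glutamate replacing
            # engulfed anions); the cation complement follows passively
            osm_excess = (glu + cl) / self.per_mM - self.cl0_mM
            f_osm = min(max(1.0 - max(osm_excess, 0.0)
                            / p.osm_max_excess_mM, 0.0), 1.0)
            cl_mM = max(cl, 0.0) / self.per_mM
            f_act = 1.0
            if p.cl_activation_kd_mM > 0:
                f_act = cl_mM / (cl_mM + p.cl_activation_kd_mM)
            j_glu = p.n_vglut * p.vglut_rate_max * drive * f_osm * f_act
        j_h_out = p.n_h * j_glu

        # Cl- channel (GHK); carried by VGLUT copies.  Rose Bengal blocks
        # glutamate transport but only mildly reduces the channel mode.
        p_cl = p.n_vglut * p.cl_permeability
        if p.rb_block:
            p_cl *= p.rb_cl_factor
        cl_in = _ghk_flux_in(p_cl, -1, psi_v, p.cl_cyt_mM,
                             max(cl, 0.0) / self.per_mM, self.rt_f)

        # VGLUT-independent counterion leak (ohmic, 0 mV reversal) with
        # voltage inactivation above ~leak_gate_mv.  It represents the
        # dissipative pathway that lets transporter-free vesicles acidify;
        # its inactivation at the chloride-charged potential is required by
        # the observation that Rose Bengal alone keeps vesicles alkaline.
        # Implemented as efflux of engulfed monovalent cations.
        xg = min(max((psi_mv - p.leak_gate_mv) / p.leak_gate_width_mv,
                     -50.0), 50.0)
        g_leak = p.counterion_leak_per_mv / (1.0 + math.exp(xg))
        cat_in = -g_leak * psi_mv

        flux = np.array([j_pump, j_h_out, j_glu, cl_in, cat_in])
        dy = np.array([
            j_pump - j_h_out,                      # added H+
            j_glu,                                 # glutamate
            cl_in,                                 # Cl-
            cat_in,                                # cation
            j_pump - j_h_out - j_glu - cl_in + cat_in,  # net charge
        ])
        return dy, flux, ph, psi_mv


def simulate(params: FluxParams = FluxParams(),
             solution: SolutionSpec | None = None,
             duration_s: float = 60.0,
             dt_out: float = 0.05,
             ph_init: float | None = None,
             pp: PhotophysicsParams = PhotophysicsParams(),
             psi_tol_mv: float = 0.2,
             dt_max: float = 0.01,
             dt_min: float = 1e-7,
             max_steps: int = 5_000_000) -> TimeCourse:
    """Integrate the vesicle model from endocytosis to ``duration_s``.

    The vesicle starts at the external pH with the engulfed solution, zero
    membrane potential and zero luminal glutamate.  Integration is adaptive
    explicit Heun with per-step buffer re-equilibration; step size is
    controlled so the membrane-potential error stays below ``psi_tol_mv``.
    """
    solution = solution or SolutionSpec()
    if duration_s <= 0 or dt_out <= 0:
        raise InvalidArgumentError("duration_s and dt_out must be > 0")
    ph0 = solution.ph_external if ph_init is None else ph_init
    eng = _Engine(params, solution, ph0)
    per_mM = params.count_per_mM
    cl0_mM = solution.chloride_mM
    if solution.substitute_anion == "iodide":
        # iodide is treated as channel-permeant, like chloride
        cl0_mM += solution.substitute_mM
        eng.sol = replace(solution, substitute_anion="none",
                          substitute_mM=0.0)
    cat0_mM = TOTAL_ANION_MM
    eng.cl0_mM = cl0_mM
    y = np.array([0.0, 0.0, cl0_mM * per_mM, cat0_mM * per_mM, 0.0])
    ledger = np.zeros(5)

    rec_t, rec_ph, rec_psi, rec_cl, rec_glu = [], [], [], [], []

    def record(t, ph, psi):
        rec_t.append(t)
        rec_ph.append(ph)
        rec_psi.append(psi)
        rec_cl.append(y[2] / per_mM)
        rec_glu.append(y[1] / per_mM)

    t = 0.0
    dt = 1e-4
    next_out = 0.0
    d1, f1, ph, psi = eng.fluxes(y)
    e_per_c = E_CHARGE / params.capacitance_f * 1e3  # mV per charge
    for _ in range(max_steps):
        if t >= next_out - 1e-12:
            record(t, ph, psi)
            next_out += dt_out
        if t >= duration_s:
            break
        dt = min(dt, duration_s - t + 1e-12)
        y_eul = y + dt * d1
        d2, f2, ph2, psi2 = eng.fluxes(y_eul)
        y_new = y + 0.5 * dt * (d1 + d2)
        err_psi = abs(y_new[4] - y_eul[4]) * e_per_c
        if err_psi > psi_tol_mv and dt > dt_min:
            dt = max(dt * 0.5, dt_min)
            continue
        ledger += 0.5 * dt * (f1 + f2)
        y = y_new
        t += dt
        d1, f1, ph, psi = eng.fluxes(y)
        grow = 1.3 if err_psi < 0.3 * psi_tol_mv else 1.05
        dt = min(dt * grow, dt_max)
    else:
        raise IntegrationError(
            f"step limit {max_steps} reached at t = {t:.3f} s"
        )

    time = np.array(rec_t)
    ph_arr = np.array(rec_ph)
    df = deltaF_from_pH(np.clip(ph_arr, 3.0, 10.0), pp)
    bound = {
        b.name: float(n * (buffer_bound_fraction(ph, b.pka)
                           - buffer_bound_fraction(ph0, b.pka)))
        for b, n in zip(eng.buffers, eng.buf_n)
    }
    bound["imported_glutamate"] = float(
        y[1] * buffer_bound_fraction(ph, GLUTAMATE_PKA))
    final = VesicleState(
        ph=float(ph), psi_mv=float(psi),
        free_h=float(10.0 ** (-ph) * params.volume_l * AVOGADRO * 1e3),
        bound_h=bound,
        cl_count=float(y[2]), glu_count=float(y[1]),
        impermeant_anion_count=float(eng.sol.substitute_mM * per_mM),
        cation_count=float(y[3]), net_charge=float(y[4]),
    )
    ledger_dict = {
        "pump_h_in": float(ledger[0]),
        "vglut_h_out": float(ledger[1]),
        "vglut_glu_in": float(ledger[2]),
        "cl_in": float(ledger[3]),
        "cation_in": float(ledger[4]),
        "h_added_state": float(y[0]),
        "net_charge_state": float(y[4]),
        "cl0_count": float(cl0_mM * per_mM),
        "cation0_count": float(cat0_mM * per_mM),
    }
    return TimeCourse(time_s=time, ph=ph_arr, psi_mv=np.array(rec_psi),
                      cl_mM=np.array(rec_cl), glu_mM=np.array(rec_glu),
                      df=df, ledger=ledger_dict, final_state=final,
                      params=params, solution=eng.sol)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scenario(name: str) -> tuple[FluxParams, SolutionSpec]:
    """Named experimental presets.

    ``control``          129.5 mM engulfed Cl-, 25 mM HEPES, VGLUT active.
    ``rb``               VGLUT glutamate transport blocked (Rose Bengal),
                         normal Cl-, 10 mM histidine added.
    ``rb_gluc_hepesN``   RB + Cl- substituted by 119 mM gluconate, HEPES at
                         N mM (N in 25, 20, 5).
    ``rb_mes_hepesN``    RB + 119 mM methanesulfonate, HEPES N (25 or 5).
    ``uncoupled``        alias of ``rb_mes_hepes25`` (pump-only regime).
    ``ko``               transporter absent; acidification proceeds through
                         a VGLUT-independent counterion leak.
    ``gluc_clN``         no RB, Cl- reduced to N mM with gluconate
                         substitution at 25 mM HEPES (N in 129.5, 100, 70,
                         40, 10.5).
    ``mes_cl10.5``       no RB, 119 mM methanesulfonate, 25 mM HEPES.
    """
    base = FluxParams()
    rb = replace(base, rb_block=True)
    if name == "control":
        return base, SolutionSpec.standard(hepes_mM=25.0)
    if name == "rb":
        return rb, SolutionSpec.standard(hepes_mM=25.0, histidine_mM=10.0)
    if name.startswith("rb_gluc_hepes"):
        h = float(name.removeprefix("rb_gluc_hepes"))
        return rb, SolutionSpec.substituted(10.5, "gluconate", hepes_mM=h,
                                            histidine_mM=10.0)
    if name.startswith("rb_mes_hepes"):
        h = float(name.removeprefix("rb_mes_hepes"))
        return rb, SolutionSpec.substituted(10.5, "methanesulfonate",
                                            hepes_mM=h, histidine_mM=10.0)
    if name == "uncoupled":
        return scenario("rb_mes_hepes25")
    if name == "ko":
        return (replace(base, n_vglut=0.0, counterion_leak_per_mv=30.0),
                SolutionSpec.standard(hepes_mM=25.0))  # leak-dominated
    if name.startswith("gluc_cl"):
        cl = float(name.removeprefix("gluc_cl"))
        if cl >= TOTAL_ANION_MM:
            return base, SolutionSpec.standard(hepes_mM=25.0)
        return base, SolutionSpec.substituted(cl, "gluconate", hepes_mM=25.0)
    if name == "mes_cl10.5":
        return base, SolutionSpec.substituted(10.5, "methanesulfonate",
                                              hepes_mM=25.0)
    raise InvalidArgumentError(f"unknown scenario {name!r}")


SCENARIO_NAMES = [
    "control", "rb",
    "rb_gluc_hepes25", "rb_gluc_hepes20", "rb_gluc_hepes5",
    "rb_mes_hepes25", "rb_mes_hepes5", "ko",
    "gluc_cl129.5", "gluc_cl100", "gluc_cl70", "gluc_cl40", "gluc_cl10.5",
    "mes_cl10.5",
]


def ledger_residuals(tc: TimeCourse) -> dict:
    """Conservation residuals (counts) between state and flux ledgers.

    All residuals are zero to integration round-off for a correct run:
    net charge = pumped H+ − exported H+ − glutamate − Cl- + counterion,
    added H+ = pumped − exported, and each species matches its cumulative
    flux.
    """
    led = tc.ledger
    fs = tc.final_state
    return {
        "charge": fs.net_charge - (led["pump_h_in"] - led["vglut_h_out"]
                                   - led["vglut_glu_in"] - led["cl_in"]
                                   + led["cation_in"]),
        "protons": led["h_added_state"] - (led["pump_h_in"]
                                           - led["vglut_h_out"]),
        "glutamate": fs.glu_count - led["vglut_glu_in"],
        "chloride": fs.cl_count - led["cl0_count"] - led["cl_in"],
        "cation": fs.cation_count - led["cation0_count"]
                  - led["cation_in"],
    }


def fit_timecourse_tau(tc: TimeCourse):
    """Mono-exponential fit of the predicted fluorescence decay."""
    return fit_monoexponential(tc.time_s, tc.df)


def scenario_suite(names: list[str] | None = None,
                   duration_s: float = 60.0) -> pd.DataFrame:
    """Run the named presets and tabulate τ, plateau pH and final contents."""
    rows = []
    for name in names or SCENARIO_NAMES:
        p, sol = scenario(name)
        tc = simulate(p, sol, duration_s=duration_s)
        fit = fit_timecourse_tau(tc)
        rows.append({
            "scenario": name,
            "tau_s": fit.tau_s if fit.converged else math.nan,
            "fit_converged": fit.converged,
            "plateau_ph": float(tc.ph[-1]),
            "final_glu_mM": float(tc.glu_mM[-1]),
            "final_cl_mM": float(tc.cl_mM[-1]),
            "final_psi_mv": float(tc.psi_mv[-1]),
            "final_df": float(tc.df[-1]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# closed-form budget report
# ---------------------------------------------------------------------------

def proton_budget_report(volume_l: float = 20e-21,
                         capacitance_f: float = 50e-18) -> dict:
    """The closed-form per-vesicle proton/charge budget.

    Uses the uncoupled-condition buffer list (25 mM HEPES + 10 mM exogenous
    histidine + matrix residues) for the 7.3 → 6.4 buffered-proton count.
    """
    buffers = [BufferSpecies("HEPES", 25.0, HEPES_PKA),
               BufferSpecies("histidine", 10.0, HISTIDINE_PKA),
               *default_matrix_buffers()]
    bound_73_64 = bound_protons(buffers, 7.3, 6.4, volume_l)
    pump_rate = infer_pump_rate(150.0, 0.5, 1.5)
    return {
        "bound_protons_7.3_to_6.4": bound_73_64,
        "pump_rate_per_vatpase_s": pump_rate,
        "h_influx_5s": pump_rate * 1.5 * 5.0,
        "vglut_transport_rate_s": 890.0 / (5.0 * 10.0),
        "charges_for_100mV": charges_for_voltage(capacitance_f, 0.1),
        "glutamate_molecules_at_120mM":
            molecules_from_concentration(120.0, volume_l),
        "isosmotic_max_mM":
            1800.0 / (volume_l * AVOGADRO) * 1e3,
        "nernst_cl_145_14_mV": nernst_potential(-1, 145.0, 14.0),
    }
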