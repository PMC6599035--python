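"""Hodgkin-Huxley-ensemble myocyte models and atrial <-> sinus-node conversion.

The cell model is entirely config-driven: a membrane capacitance, a set of
ionic currents (each a maximal conductance, reversal potential and a product
of HH gates with Boltzmann steady states and bell-shaped time constants),
and a phenomenological sarcoplasmic-reticulum Ca2+ subsystem (uptake and
release fluxes; diagnostic only — it does not feed back on the membrane
currents). Membrane potential obeys ``dV/dt = -(sum(I) + I_stim)/C_m`` with
currents in pA, capacitance in pF, time in ms.

The proteomics-driven conversion between phenotypes is expressed as a
:class:`ScalingTable` of auditable actions (scale a conductance by an
SN/RA LFQ ratio, set a fraction, shift a gate's half-activation voltage,
insert or remove a current, set the capacitance). Tables invert exactly, so
an atrial -> SN -> atrial round trip recovers the original parameter set
field by field.

The shipped atrial and sinus-node configurations are synthetic minimal
parameterizations authored for this package (the cited published models'
equations are not redistributed here); they reproduce the qualitative
phenotypes the conversion is tested on — a quiescent, excitable atrial cell
and a spontaneously firing node cell with a pacemaker depolarization.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GateSpec",
    "CurrentSpec",
    "CalciumHandling",
    "CellModel",
    "SimulationSettings",
    "Trace",
    "APFeatures",
    "AutomaticityResult",
    "ScalingAction",
    "ScalingTable",
    "run_cell",
    "convert_atrial_to_sn",
    "convert_sn_to_atrial",
    "compute_scaling_from_lfq",
    "detect_automaticity",
    "extract_features",
    "load_cell_model",
    "load_scaling_table",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class GateSpec:
    """One HH gate: ``y_inf = 1/(1 + exp((V - (vh + shift))/k))`` raised to
    ``exponent``; first-order relaxation with bell-shaped ``tau`` (ms), or
    instantaneous when ``tau`` is None."""

    name: str
    exponent: float = 1.0
    vh: float = 0.0
    k: float = 1.0
    tau: dict | None = None  # {base, amp, vc, k1, k2} or None
    v_half_shift: float = 0.0

    def y_inf(self, v):
        return 1.0 / (
            1.0 + np.exp((np.asarray(v, dtype=float) - (self.vh + self.v_half_shift)) / self.k)
        )

    def tau_ms(self, v):
        t = self.tau
        v = np.asarray(v, dtype=float)
        return t["base"] + t["amp"] / (
            np.exp((v - t["vc"]) / t["k1"]) + np.exp(-(v - t["vc"]) / t["k2"])
        )

    @property
    def instantaneous(self) -> bool:
        return self.tau is None


@dataclass
class CurrentSpec:
    """One ionic current or flux scale.

    ``kind="ohmic"``: ``I = g_max * prod(gate^exp) * (V - E_rev)`` (pA with
    g in nS, V in mV). ``kind="constant"``: ``I = amplitude * prod(gates)``
    (pA) for pump-like currents.
    """

    name: str
    g_max: float = 0.0  # nS (or pA for kind="constant")
    E_rev: float = 0.0  # mV
    gates: list[GateSpec] = field(default_factory=list)
    kind: str = "ohmic"

    def __post_init__(self) -> None:
        self.gates = [g if isinstance(g, GateSpec) else GateSpec(**g) for g in self.gates]
        if any(g.exponent < 0 for g in self.gates):
            raise ValueError(f"{self.name}: gate exponents must be >= 0")


@dataclass
class CalciumHandling:
    """Phenomenological SR Ca2+ cycling (concentrations in uM, fluxes uM/ms).

    ``J_up = v_up * Cai/(Cai + K_up)`` (SERCA uptake into the SR) and
    ``J_rel = k_rel * CaSR * Cai^2/(Cai^2 + K_rel^2)`` (Ca-induced Ca
    release). Scaled by the conversion table via the ``J_up`` / ``J_rel``
    targets. Diagnostic subsystem: no feedback onto membrane currents.
    """

    v_up: float = 0.4
    k_rel: float = 0.002
    K_up: float = 0.25
    K_rel: float = 0.6
    influx_scale: float = 0.01  # uM per pA*ms of Ca current
    sr_volume_ratio: float = 15.0
    ca_current_names: list[str] = field(default_factory=lambda: ["I_CaL", "I_CaT"])
    cai0: float = 0.1
    casr0: float = 100.0


@dataclass
class CellModel:
    """A complete myocyte model configuration."""

    name: str
    C_m: float  # pF
    currents: dict[str, CurrentSpec]
    calcium: CalciumHandling = field(default_factory=CalciumHandling)
    initial_V: float = -78.0
    version: str = ""

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        self.currents = {
            k: (v if isinstance(v, CurrentSpec) else CurrentSpec(**v))
            for k, v in self.currents.items()
        }
        if not isinstance(self.calcium, CalciumHandling):
            self.calcium = CalciumHandling(**self.calcium)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return copy.deepcopy(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "CellModel":
        d = copy.deepcopy(d)
        d["currents"] = {k: CurrentSpec(**v) for k, v in d["currents"].items()}
        if "calcium" in d:
            d["calcium"] = CalciumHandling(**d["calcium"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CellModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def copy(self) -> "CellModel":
        return CellModel.from_dict(self.to_dict())

    def __eq__(self, other) -> bool:
        return isinstance(other, CellModel) and self.to_dict() == other.to_dict()


def load_cell_model(name: str) -> CellModel:
    """Load a shipped model config (``"atrial"`` or ``"sn"``)."""
    fname = {"atrial": "atrial_model.synthetic.json", "sn": "sn_model.synthetic.json"}[name]
    path = resources.files("sinode.data") / fname
    return CellModel.from_dict(json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationSettings:
    """Numerical settings.

    ``duration`` in seconds (default 20 s, run to steady state); output on a
    fixed ``dt`` grid (default 0.1 ms). Pacing (atrial use) applies a square
    stimulus of ``stim_amplitude`` pA for ``stim_duration`` ms every
    ``pacing_cl`` ms. Integration is adaptive and stiff-capable (LSODA) with
    dense output on the fixed grid.
    """

    dt: float = 0.1  # ms
    duration: float = 20.0  # s
    pacing_cl: float | None = None  # ms
    stim_amplitude: float = -2000.0  # pA (inward)
    stim_duration: float = 2.0  # ms
    rtol: float = 1e-6
    atol: float = 1e-6
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


@dataclass
class Trace:
    """Simulated membrane-potential time series with per-current traces."""

    time: np.ndarray  # ms
    V: np.ndarray  # mV
    currents: dict[str, np.ndarray]  # pA
    stim: np.ndarray  # pA
    states: dict[str, np.ndarray]
    dt: float

    def dvdt(self) -> np.ndarray:
        return np.gradient(self.V, self.time)


class _Runtime:
    """Vectorized evaluation tables compiled from a CellModel."""

    def __init__(self, model: CellModel):
        self.model = model
        self.gate_names: list[str] = []
        vh, k, shift = [], [], []
        tb, ta, tv, tk1, tk2 = [], [], [], [], []
        self.current_terms = []  # (name, kind, g, E, [(dyn_idx, exp)], [inst GateSpec])
        for cname, cur in model.currents.items():
            dyn_terms, inst_gates = [], []
            for g in cur.gates:
                if g.instantaneous:
                    inst_gates.append(g)
                else:
                    idx = len(self.gate_names)
                    self.gate_names.append(f"{cname}.{g.name}")
                    vh.append(g.vh + g.v_half_shift)
                    k.append(g.k)
                    t = g.tau
                    tb.append(t["base"])
                    ta.append(t["amp"])
                    tv.append(t["vc"])
                    tk1.append(t["k1"])
                    tk2.append(t["k2"])
                    dyn_terms.append((idx, g.exponent))
            self.current_terms.append((cname, cur.kind, cur.g_max, cur.E_rev, dyn_terms, inst_gates))
        self.vh = np.asarray(vh)
        self.k = np.asarray(k)
        self.tb = np.asarray(tb)
        self.ta = np.asarray(ta)
        self.tv = np.asarray(tv)
        self.tk1 = np.asarray(tk1)
        self.tk2 = np.asarray(tk2)
        self.n_gates = len(self.gate_names)
        cal = model.calcium
        self.ca_idx = [
            i for i, (nm, *_rest) in enumerate(self.current_terms)
            if nm in cal.ca_current_names
        ]

    def y_inf(self, v: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((v - self.vh) / self.k))

    def tau(self, v: float) -> np.ndarray:
        return self.tb + self.ta / (
            np.exp((v - self.tv) / self.tk1) + np.exp(-(v - self.tv) / self.tk2)
        )

    def currents_at(self, v: float, gates: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.current_terms))
        for i, (nm, kind, g_max, e_rev, dyn, inst) in enumerate(self.current_terms):
            gate_prod = 1.0
            for idx, expo in dyn:
                gate_prod *= gates[idx] ** expo
            for gs in inst:
                gate_prod *= float(gs.y_inf(v)) ** gs.exponent
            if kind == "ohmic":
                out[i] = g_max * gate_prod * (v - e_rev)
            else:
                out[i] = g_max * gate_prod
        return out

    def initial_state(self) -> np.ndarray:
        v0 = self.model.initial_V
        cal = self.model.calcium
        y0 = self.y_inf(v0) if self.n_gates else np.empty(0)
        return np.concatenate(([v0], y0, [cal.cai0, cal.casr0]))

    def rhs(self, t: float, y: np.ndarray, i_stim: float) -> np.ndarray:
        v = y[0]
        gates = y[1 : 1 + self.n_gates]
        cai, casr = y[-2], y[-1]
        cur = self.currents_at(v, gates)
        dv = -(cur.sum() + i_stim) / self.model.C_m
        dgates = (self.y_inf(v) - gates) / self.tau(v) if self.n_gates else np.empty(0)
        cal = self.model.calcium
        i_ca = sum(cur[i] for i in self.ca_idx)
        j_up = cal.v_up * cai / (cai + cal.K_up)
        j_rel = cal.k_rel * casr * cai**2 / (cai**2 + cal.K_rel**2)
        dcai = -cal.influx_scale * i_ca - j_up + j_rel
        dcasr = (j_up - j_rel) * cal.sr_volume_ratio  # SR pool, uM of SR volume
        return np.concatenate(([dv], dgates, [dcai, dcasr]))


def run_cell(model: CellModel, settings: SimulationSettings | None = None) -> Trace:
    """Integrate the model and sample on the fixed output grid.

    Stimulus edges bound the integration segments so the square pulse is
    represented exactly. Raises on divergence (|V| > 200 mV), reporting the
    last state.
    """
    settings = settings or SimulationSettings()
    rt = _Runtime(model)
    total_ms = settings.duration * 1e3
    dt = settings.dt

    # build (t_start, t_end, i_stim) segments
    segments: list[tuple[float, float, float]] = []
    if settings.pacing_cl is None:
        segments.append((0.0, total_ms, 0.0))
    else:
        cl, sd = settings.pacing_cl, settings.stim_duration
        t = 0.0
        while t < total_ms:
            on_end = min(t + sd, total_ms)
            segments.append((t, on_end, settings.stim_amplitude))
            off_end = min(t + cl, total_ms)
            if off_end > on_end:
                segments.append((on_end, off_end, 0.0))
            t += cl

    y = rt.initial_state()
    times_out, states_out, stim_out = [], [], []
    for t0, t1, amp in segments:
        n = max(int(math.ceil((t1 - t0) / dt)), 2)
        t_eval = np.linspace(t0, t1, n + 1)
        sol = solve_ivp(
            rt.rhs,
            (t0, t1),
            y,
            t_eval=t_eval,
            args=(amp,),
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in [{t0}, {t1}] ms: {sol.message}")
        if np.max(np.abs(sol.y[0])) > 200.0:
            raise RuntimeError(
                f"membrane potential diverged (|V| > 200 mV); last state: {sol.y[:, -1]}"
            )
        # drop the duplicated segment-start sample except for the first segment
        s = 0 if not times_out else 1
        times_out.append(sol.t[s:])
        states_out.append(sol.y[:, s:])
        stim_out.append(np.full(sol.t[s:].size, amp))
        y = sol.y[:, -1]

    t_all = np.concatenate(times_out)
    y_all = np.concatenate(states_out, axis=1)
    stim_all = np.concatenate(stim_out)

    # resample onto the uniform grid
    grid = np.arange(0.0, total_ms + dt / 2, dt)
    v_grid = np.interp(grid, t_all, y_all[0])
    gates_grid = np.vstack(
        [np.interp(grid, t_all, y_all[1 + i]) for i in range(rt.n_gates)]
    ) if rt.n_gates else np.empty((0, grid.size))
    stim_grid = np.interp(grid, t_all, stim_all)

    currents = {nm: np.empty(grid.size) for nm, *_ in rt.current_terms}
    for j in range(grid.size):
        cur = rt.currents_at(v_grid[j], gates_grid[:, j])
        for i, (nm, *_rest) in enumerate(rt.current_terms):
            currents[nm][j] = cur[i]
    states = {nm: gates_grid[i] for i, nm in enumerate(rt.gate_names)}
    states["Cai"] = np.interp(grid, t_all, y_all[-2])
    states["CaSR"] = np.interp(grid, t_all, y_all[-1])
    return Trace(time=grid, V=v_grid, currents=currents, stim=stim_grid, states=states, dt=dt)


# ---------------------------------------------------------------------------
# conversion between phenotypes
# ---------------------------------------------------------------------------


@dataclass
class ScalingAction:
    """One auditable conversion step.

    action in {"scale", "set_fraction", "shift_vhalf", "insert", "remove",
    "set_cm", "scale_calcium"}; ``value`` is the ratio / fraction / shift /
    new capacitance; ``gate`` names the gate for shifts; ``payload`` carries
    the CurrentSpec dict for insert (and records it for remove's inverse);
    ``reference`` stores the pre-action value so every action inverts
    exactly.
    """

    target: str
    action: str
    value: float | None = None
    gate: str | None = None
    payload: dict | None = None
    reference: float | None = None


@dataclass
class ScalingTable:
    """Ordered list of conversion actions with exact inversion."""

    actions: list[ScalingAction]

    def __post_init__(self) -> None:
        self.actions = [
            a if isinstance(a, ScalingAction) else ScalingAction(**a) for a in self.actions
        ]
        for a in self.actions:
            if a.action in ("scale", "set_fraction") and (a.value is None or a.value < 0):
                raise ValueError(f"{a.target}: ratio/fraction must be >= 0")

    @classmethod
    def from_json(cls, path) -> "ScalingTable":
        with open(path) as fh:
            return cls(json.load(fh)["actions"])

    def apply(self, model: CellModel) -> CellModel:
        m = model.copy()
        applied: list[ScalingAction] = []
        names = set(m.currents)
        unmatched = []
        for a in self.actions:
            if a.action == "insert":
                names.add(a.target)
            elif (
                a.action
                in ("scale", "set_fraction", "set_absolute", "shift_vhalf", "set_vhalf_shift", "remove")
                and a.target not in names
                and a.target not in ("J_up", "J_rel")
            ):
                unmatched.append(a.target)
            elif a.action == "remove":
                names.discard(a.target)
        if unmatched:
            raise KeyError(f"scaling entries for currents absent from the model: {unmatched}")
        for a in self.actions:
            a = ScalingAction(**asdict(a))
            if a.action == "set_cm":
                a.reference = m.C_m
                m.C_m = float(a.value)
            elif a.action == "scale_calcium":
                attr = {"J_up": "v_up", "J_rel": "k_rel"}[a.target]
                old = getattr(m.calcium, attr)
                a.reference = old
                setattr(m.calcium, attr, old * a.value)
            elif a.action == "set_calcium":
                attr = {"J_up": "v_up", "J_rel": "k_rel"}[a.target]
                a.reference = getattr(m.calcium, attr)
                setattr(m.calcium, attr, float(a.value))
            elif a.action == "scale":
                a.reference = m.currents[a.target].g_max
                m.currents[a.target].g_max *= a.value
            elif a.action == "set_fraction":
                a.reference = m.currents[a.target].g_max
                m.currents[a.target].g_max = a.reference * a.value
            elif a.action == "shift_vhalf":
                for g in m.currents[a.target].gates:
                    if g.name == a.gate:
                        a.reference = g.v_half_shift
                        g.v_half_shift += a.value
                        break
                else:
                    raise KeyError(f"gate {a.gate!r} not found on {a.target}")
            elif a.action == "set_vhalf_shift":
                for g in m.currents[a.target].gates:
                    if g.name == a.gate:
                        a.reference = g.v_half_shift
                        g.v_half_shift = float(a.value)
                        break
                else:
                    raise KeyError(f"gate {a.gate!r} not found on {a.target}")
            elif a.action == "insert":
                if a.target in m.currents:
                    raise KeyError(f"current {a.target!r} already present")
                m.currents[a.target] = CurrentSpec(**copy.deepcopy(a.payload))
            elif a.action == "remove":
                a.payload = asdict(m.currents[a.target])
                del m.currents[a.target]
            elif a.action == "set_absolute":
                if a.target not in m.currents:
                    raise KeyError(f"set_absolute target {a.target!r} absent from the model")
                a.reference = m.currents[a.target].g_max
                m.currents[a.target].g_max = float(a.value)
            elif a.action == "replace":
                new_payload = copy.deepcopy(a.payload)
                old = asdict(m.currents[a.target])
                m.currents[a.target] = CurrentSpec(**copy.deepcopy(new_payload))
                a.payload = {"new": new_payload, "old": old}
            else:
                raise ValueError(f"unknown action {a.action!r}")
            applied.append(a)
        self.applied_ = applied
        return m

    def invert(self) -> "ScalingTable":
        """Exact inverse table (requires :meth:`apply` to have run, so the
        pre-action references are recorded)."""
        src = getattr(self, "applied_", None) or self.actions
        inv: list[ScalingAction] = []
        for a in reversed(src):
            a = ScalingAction(**asdict(a))
            if a.action == "set_cm":
                inv.append(ScalingAction("C_m", "set_cm", a.reference))
            elif a.action in ("scale_calcium", "set_calcium"):
                if a.reference is not None:
                    inv.append(ScalingAction(a.target, "set_calcium", a.reference))
                elif a.value == 0:
                    raise ValueError(f"{a.target}: cannot invert a zero scaling")
                else:
                    inv.append(ScalingAction(a.target, "scale_calcium", 1.0 / a.value))
            elif a.action in ("scale", "set_fraction", "set_absolute"):
                if a.reference is not None:
                    inv.append(ScalingAction(a.target, "set_absolute", a.reference))
                elif a.action == "scale" and a.value:
                    inv.append(ScalingAction(a.target, "scale", 1.0 / a.value))
                else:
                    raise ValueError(
                        f"{a.target}: cannot invert {a.action!r} without the recorded "
                        "pre-action value (run apply() first)"
                    )
            elif a.action in ("shift_vhalf", "set_vhalf_shift"):
                if a.reference is not None:
                    inv.append(
                        ScalingAction(a.target, "set_vhalf_shift", a.reference, gate=a.gate)
                    )
                else:
                    inv.append(ScalingAction(a.target, "shift_vhalf", -a.value, gate=a.gate))
            elif a.action == "insert":
                inv.append(ScalingAction(a.target, "remove"))
            elif a.action == "remove":
                inv.append(ScalingAction(a.target, "insert", payload=a.payload))
            elif a.action == "replace":
                inv.append(ScalingAction(a.target, "replace", payload=a.payload["old"]))
        return ScalingTable(inv)


def load_scaling_table(name: str = "atrial_to_sn") -> ScalingTable:
    """Load the shipped conversion table (synthetic stand-in values)."""
    path = resources.files("sinode.data") / f"scaling_{name}.synthetic.json"
    return ScalingTable(json.loads(path.read_text())["actions"])


def convert_atrial_to_sn(atrial: CellModel, scaling: ScalingTable) -> CellModel:
    """Apply the proteomics-driven atrial -> sinus-node conversion.

    The shipped table encodes, in order: C_m 50 -> 25 pF; I_Na, I_CaL and
    I_Kr conductances scaled by SN/RA LFQ ratios; insertion of I_f (split by
    HCN isoform) and I_CaT with the I_CaT activation half-voltage shifted by
    -7 mV; I_Kur to 0% and I_to to 10%; SR uptake/release scaled. I_K1 is
    left unchanged by default (a reduction per Kir3.1/TASK1 may be added to
    a custom table).
    """
    for nm in ("I_f_HCN4", "I_CaT"):
        if nm in atrial.currents:
            raise ValueError(f"atrial model already contains {nm}")
    m = scaling.apply(atrial)
    m.name = "sn_like"
    return m


def convert_sn_to_atrial(
    sn: CellModel, scaling: ScalingTable, atrial_IK1: CurrentSpec | None = None
) -> CellModel:
    """Reverse conversion; optionally install the atrial I_K1 formulation.

    ``scaling`` is applied as given (pass ``forward_table.invert()`` for an
    exact round trip). The background inward-rectifier replacement follows
    the observation that the node model's I_K1 cannot by itself silence the
    cell.
    """
    m = scaling.apply(sn)
    if atrial_IK1 is not None:
        m.currents["I_K1"] = CurrentSpec(**asdict(atrial_IK1))
    m.name = "atrial_like"
    return m


def compute_scaling_from_lfq(
    results: pd.DataFrame,
    current_to_proteins: Mapping[str, Sequence[str]],
    pooling: str = "mean",
) -> dict[str, float]:
    """SN/RA linear-scale conductance ratios from volcano log2 fold changes.

    ``r(current) = 2 ** pooled(log2fc of mapped subunit proteins)``; pooling
    is the mean (default) or median of the subunit log2fc values. Unmapped
    currents are omitted with a warning-level log entry.
    """
    import logging

    log = logging.getLogger(__name__)
    if pooling not in ("mean", "median"):
        raise ValueError("pooling must be 'mean' or 'median'")
    out: dict[str, float] = {}
    for cur, prots in current_to_proteins.items():
        present = [p for p in prots if p in results.index]
        if not present:
            log.warning("no quantified proteins for current %s; omitted", cur)
            continue
        vals = results.loc[present, "log2fc"].to_numpy(dtype=float)
        pooled = float(np.mean(vals) if pooling == "mean" else np.median(vals))
        out[cur] = 2.0**pooled
    return out


# ---------------------------------------------------------------------------
# trace analysis
# ---------------------------------------------------------------------------


@dataclass
class AutomaticityResult:
    status: str  # "spontaneous" | "quiescent" | "inconclusive"
    spontaneous: bool | None
    rate_hz: float | None
    cycle_lengths_ms: np.ndarray


def _upstroke_times(
    time: np.ndarray, v: np.ndarray, threshold_mv: float = -20.0, dvdt_min: float = 5.0
) -> np.ndarray:
    """Times of upward threshold crossings with dV/dt above ``dvdt_min``
    mV/ms (= V/s)."""
    dvdt = np.gradient(v, time)
    cross = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
    return np.array([time[i] for i in cross if dvdt[i] > dvdt_min or dvdt[i + 1] > dvdt_min])


def detect_automaticity(
    trace: Trace,
    analysis_fraction: float = 0.25,
    threshold_mv: float = -20.0,
    dvdt_min: float = 5.0,
    cv_max: float = 0.10,
    expected_rate_hz: float | None = None,
) -> AutomaticityResult:
    """Decide whether an unpaced trace fires spontaneously.

    The final ``analysis_fraction`` of the trace is searched for upstrokes
    (dV/dt > 5 V/s crossing -20 mV); spontaneous means >= 2 upstrokes with a
    cycle-length coefficient of variation under 10%. When an expected rate
    is supplied and the window is shorter than two expected cycles the
    verdict is "inconclusive" rather than a boolean.
    """
    t0 = trace.time[-1] * (1.0 - analysis_fraction)
    sel = trace.time >= t0
    window = trace.time[-1] - t0
    if expected_rate_hz is not None and window < 2 * 1e3 / expected_rate_hz:
        return AutomaticityResult("inconclusive", None, None, np.array([]))
    ups = _upstroke_times(trace.time[sel], trace.V[sel], threshold_mv, dvdt_min)
    if ups.size < 2:
        return AutomaticityResult("quiescent", False, None, np.array([]))
    cls = np.diff(ups)
    cv = cls.std(ddof=0) / cls.mean()
    if cv < cv_max:
        return AutomaticityResult("spontaneous", True, 1e3 / cls.mean(), cls)
    return AutomaticityResult("quiescent", False, None, cls)


@dataclass
class APFeatures:
    """Action-potential characteristics averaged over the last two APs."""

    spontaneous: bool
    cycle_length_ms: float
    max_diastolic_potential_mv: float
    overshoot_mv: float
    apd50_ms: float
    apd90_ms: float
    dvdt_max_v_per_s: float
    diastolic_depolarization_rate_mv_per_s: float | None

    def __post_init__(self) -> None:
        if not (self.apd50_ms <= self.apd90_ms + 1e-9):
            raise ValueError("APD50 must not exceed APD90")


def extract_features(trace: Trace, spontaneous: bool | None = None) -> APFeatures:
    """Measure AP characteristics from the last two action potentials.

    MDP is the minimum potential between the last two upstrokes; APD50/90
    run from the time of maximal dV/dt to 50%/90% repolarization relative to
    the peak-to-MDP amplitude; the diastolic depolarization rate is the mean
    slope over the middle half of the final diastolic interval (unpaced
    traces only).
    """
    ups = _upstroke_times(trace.time, trace.V)
    if ups.size < 2:
        raise ValueError("need at least two action potentials in the trace")
    if spontaneous is None:
        spontaneous = bool(np.all(trace.stim == 0.0))
    t_lo, t_hi = ups[-2], ups[-1]
    cl = t_hi - t_lo
    dvdt = np.gradient(trace.V, trace.time)

    feats = []
    bounds = [(t_lo, t_hi), (t_hi, min(t_hi + cl, trace.time[-1]))]
    for a, b in bounds:
        sel = (trace.time >= a) & (trace.time <= b)
        t, v, dv = trace.time[sel], trace.V[sel], dvdt[sel]
        peak_i = int(np.argmax(v))
        peak = v[peak_i]
        mdp = float(v.min())
        up_i = int(np.argmax(dv))
        amp = peak - mdp
        apd = {}
        for frac in (0.5, 0.9):
            level = peak - frac * amp
            below = np.flatnonzero((v[peak_i:] <= level))
            apd[frac] = (t[peak_i + below[0]] - t[up_i]) if below.size else (t[-1] - t[up_i])
        feats.append((peak, mdp, dv[up_i], apd[0.5], apd[0.9]))

    peak = float(np.mean([f[0] for f in feats]))
    mdp = float(np.mean([f[1] for f in feats]))
    dvdt_max = float(np.mean([f[2] for f in feats]))
    apd50 = float(np.mean([f[3] for f in feats]))
    apd90 = float(np.mean([f[4] for f in feats]))

    ddr = None
    if spontaneous:
        # middle half of the final full diastole (MDP -> next upstroke)
        sel = (trace.time >= t_lo) & (trace.time <= t_hi)
        t, v = trace.time[sel], trace.V[sel]
        mdp_i = int(np.argmin(v))
        t_d0, t_d1 = t[mdp_i], t_hi
        span = t_d1 - t_d0
        sel2 = (trace.time >= t_d0 + 0.25 * span) & (trace.time <= t_d0 + 0.75 * span)
        if sel2.sum() >= 2:
            coef = np.polyfit(trace.time[sel2], trace.V[sel2], 1)
            ddr = float(coef[0] * 1e3)  # mV/ms -> mV/s
    return APFeatures(
        spontaneous=bool(spontaneous),
        cycle_length_ms=float(cl),
        max_diastolic_potential_mv=mdp,
        overshoot_mv=peak,
        apd50_ms=min(apd50, apd90),
        apd90_ms=apd90,
        dvdt_max_v_per_s=dvdt_max,
        diastolic_depolarization_rate_mv_per_s=ddr,
    )
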