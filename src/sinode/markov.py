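"""Single-ion-channel Markov schemes and Monte-Carlo simulation.

The copy-number anchor rests on a stochastic single-channel model of the
HCN4 funny-current channel: a two-state C <-> O scheme whose voltage
dependent rates derive from Hodgkin-Huxley gating (``alpha = y_inf/tau``,
``beta = (1 - y_inf)/tau`` — the unique 2-state chain whose occupancy
reproduces the HH gate). Four-state C <-> O <-> I1 <-> I2 chains with two
inactive states serve Cav1.2, Cav3.2 and ERG.

Simulation is a discrete-time jump process at ``dt_mc = 0.02 ms``: from
state *i*, each transition *i -> j* fires with probability ``r_ij * dt`` per
step. Within a constant-voltage protocol segment this chain is simulated
exactly by sampling geometric dwell times (same law, far fewer random
draws); a literal per-step sampler and a continuous-time Gillespie sampler
are provided as cross-checks. The deterministic limit — the master equation
``dp/dt = Q(V)^T p`` — is integrated by piecewise-constant matrix
exponentials, which is exact for step protocols.

Units: time ms, voltage mV, rates 1/ms, unitary conductance pS, current pA
(so ``i = g_u * 1e-3 * (V - E_rev)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Boltzmann",
    "BellTau",
    "MarkovScheme",
    "VoltageProtocol",
    "SweepSet",
    "hh_to_markov",
    "two_state_scheme",
    "four_state_scheme",
    "load_scheme",
    "simulate_unitary_mc",
    "simulate_unitary_per_step",
    "simulate_unitary_gillespie",
    "ensemble_average",
    "fit_unitary_conductance",
    "occupancy_ode",
    "channel_count_from_conductance",
    "HCN_ACTIVATION_PROTOCOL",
    "UNITARY_IV_PROTOCOLS",
]


# ---------------------------------------------------------------------------
# gating primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Boltzmann:
    """Steady-state gate ``y_inf(V) = 1 / (1 + exp((V - vh)/k))``.

    ``k > 0`` gives a hyperpolarization-activated (or inactivation) gate,
    ``k < 0`` a depolarization-activated one.
    """

    vh: float
    k: float

    def __call__(self, v):
        return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - self.vh) / self.k))


@dataclass(frozen=True)
class BellTau:
    """Bell-shaped time constant
    ``tau(V) = base + amp / (exp((V - vc)/k1) + exp(-(V - vc)/k2))`` (ms)."""

    base: float
    amp: float
    vc: float
    k1: float
    k2: float

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.base + self.amp / (
            np.exp((v - self.vc) / self.k1) + np.exp(-(v - self.vc) / self.k2)
        )


def hh_to_markov(
    y_inf: Callable[[float], float], tau: Callable[[float], float]
) -> tuple[Callable[[float], float], Callable[[float], float]]:
    """Convert an HH gate (y_inf, tau) into opening/closing rates.

    ``alpha(V) = y_inf(V)/tau(V)`` and ``beta(V) = (1 - y_inf(V))/tau(V)``,
    so that ``alpha/(alpha+beta) = y_inf`` and ``1/(alpha+beta) = tau``.
    Raises if ``tau <= 0`` or ``y_inf`` leaves [0, 1] where evaluated.
    """

    def _check(v):
        t = np.asarray(tau(v), dtype=float)
        y = np.asarray(y_inf(v), dtype=float)
        if np.any(t <= 0):
            raise ValueError("tau must be positive over the voltage range")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("y_inf must lie in [0, 1]")
        return y, t

    def alpha(v):
        y, t = _check(v)
        return y / t

    def beta(v):
        y, t = _check(v)
        return (1.0 - y) / t

    return alpha, beta


# ---------------------------------------------------------------------------
# schemes
# ---------------------------------------------------------------------------


@dataclass
class MarkovScheme:
    """A single-channel state scheme with voltage-dependent rates.

    ``transitions`` maps directed edges ``(i, j)`` (state indices) to rate
    functions of voltage (1/ms). Exactly one state conducts; the unitary
    current in that state is ``g_u * 1e-3 * (V - E_rev)`` pA.
    """

    name: str
    states: list[str]
    transitions: dict[tuple[int, int], Callable]
    conducting_state: str
    g_u: float  # pS
    E_rev: float  # mV

    def __post_init__(self) -> None:
        if self.conducting_state not in self.states:
            raise ValueError(f"conducting state {self.conducting_state!r} unknown")
        if self.g_u <= 0:
            raise ValueError("unitary conductance must be positive")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        return self.states.index(self.conducting_state)

    def rate_matrix(self, v: float) -> np.ndarray:
        """Generator matrix Q(V): Q[i, j] = rate i->j, rows sum to zero."""
        n = self.n_states
        q = np.zeros((n, n))
        for (i, j), fn in self.transitions.items():
            r = float(fn(v))
            if r < 0:
                raise ValueError(f"negative rate on edge {self.states[i]}->{self.states[j]}")
            q[i, j] = r
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def unitary_current(self, v) -> np.ndarray:
        """Open-level current (pA) at voltage v."""
        return self.g_u * 1e-3 * (np.asarray(v, dtype=float) - self.E_rev)

    def stationary_distribution(self, v: float) -> np.ndarray:
        q = self.rate_matrix(v)
        # null space of Q^T, normalized
        w, vec = np.linalg.eig(q.T)
        i = int(np.argmin(np.abs(w)))
        p = np.real(vec[:, i])
        p = np.abs(p)
        return p / p.sum()


def two_state_scheme(
    name: str,
    y_inf: Callable,
    tau: Callable,
    g_u: float,
    E_rev: float,
) -> MarkovScheme:
    """C <-> O scheme from a single HH activation gate."""
    alpha, beta = hh_to_markov(y_inf, tau)
    return MarkovScheme(
        name=name,
        states=["C", "O"],
        transitions={(0, 1): alpha, (1, 0): beta},
        conducting_state="O",
        g_u=g_u,
        E_rev=E_rev,
    )


def four_state_scheme(
    name: str,
    act_inf: Callable,
    act_tau: Callable,
    inact_inf: Callable,
    inact_tau: Callable,
    slow_inact_inf: Callable,
    slow_inact_tau: Callable,
    g_u: float,
    E_rev: float,
) -> MarkovScheme:
    """Linear C <-> O <-> I1 <-> I2 chain with two inactive states.

    The C<->O edge carries the activation gate; O<->I1 the fast and I1<->I2
    the slow inactivation gate (entering an inactive state at the gate's
    closing rate). The linear-chain topology is a modelling choice; only the
    state count is fixed by the scheme family.
    """
    a_on, a_off = hh_to_markov(act_inf, act_tau)
    f_on, f_off = hh_to_markov(inact_inf, inact_tau)
    s_on, s_off = hh_to_markov(slow_inact_inf, slow_inact_tau)
    return MarkovScheme(
        name=name,
        states=["C", "O", "I1", "I2"],
        transitions={
            (0, 1): a_on,
            (1, 0): a_off,
            (1, 2): f_off,  # inactivate at the gate's closing rate
            (2, 1): f_on,
            (2, 3): s_off,
            (3, 2): s_on,
        },
        conducting_state="O",
        g_u=g_u,
        E_rev=E_rev,
    )


def load_scheme(name: str) -> MarkovScheme:
    """Build a named scheme from the shipped JSON parameter file.

    Available: ``hcn4``, ``hcn1`` (2-state) and ``cav12``, ``cav32``,
    ``erg`` (4-state). Unitary conductances other than HCN4's 1.0 pS are
    placeholder values (flagged in the data file).
    """
    path = resources.files("sinode.data") / "markov_schemes.json"
    params = json.loads(path.read_text())
    if name not in params:
        raise KeyError(f"unknown scheme {name!r}; available: {sorted(params)}")
    p = params[name]
    if p["topology"] == "two_state":
        return two_state_scheme(
            name,
            Boltzmann(**p["activation"]["y_inf"]),
            BellTau(**p["activation"]["tau"]),
            p["g_u_pS"],
            p["E_rev_mV"],
        )
    return four_state_scheme(
        name,
        Boltzmann(**p["activation"]["y_inf"]),
        BellTau(**p["activation"]["tau"]),
        Boltzmann(**p["inactivation"]["y_inf"]),
        BellTau(**p["inactivation"]["tau"]),
        Boltzmann(**p["slow_inactivation"]["y_inf"]),
        BellTau(**p["slow_inactivation"]["tau"]),
        p["g_u_pS"],
        p["E_rev_mV"],
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


@dataclass
class VoltageProtocol:
    """Step voltage-clamp protocol: hold, then a list of (V_test, duration)."""

    holding_V: float
    steps: list[tuple[float, float]]  # (mV, ms)
    sample_dt: float = 0.02  # ms

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.steps):
            raise ValueError("step durations must be positive")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.steps)

    def segments(self, dt: float) -> list[tuple[float, int]]:
        """(voltage, n_steps) per segment at time step dt."""
        return [(v, int(round(d / dt))) for v, d in self.steps]

    def voltage_trace(self, dt: float) -> np.ndarray:
        return np.concatenate([np.full(n, v) for v, n in self.segments(dt)])

    def times(self, dt: float) -> np.ndarray:
        n = sum(n for _, n in self.segments(dt))
        return np.arange(n) * dt


#: Standard HCN activation protocol: hold -30 mV, hyperpolarize to -90 mV for 2000 ms.
HCN_ACTIVATION_PROTOCOL = VoltageProtocol(holding_V=-30.0, steps=[(-90.0, 2000.0)])

#: Family of hyperpolarizing test potentials for the unitary i-V relation.
UNITARY_IV_PROTOCOLS = {
    v: VoltageProtocol(holding_V=-30.0, steps=[(float(v), 2000.0)])
    for v in (-140.0, -130.0, -120.0, -110.0, -100.0, -90.0, -80.0, -70.0)
}


@dataclass
class SweepSet:
    """Simulated unitary-current sweeps (n_sweeps x n_samples, pA)."""

    times: np.ndarray
    sweeps: np.ndarray
    voltages: np.ndarray
    dt_mc: float
    seed: int
    scheme_name: str
    g_u: float
    E_rev: float

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


def _check_dt(scheme: MarkovScheme, voltages: Sequence[float], dt: float) -> None:
    worst = 0.0
    for v in voltages:
        q = scheme.rate_matrix(v)
        worst = max(worst, float(np.max(-np.diag(q))))
    if worst * dt >= 0.1:
        raise ValueError(
            f"max total exit rate {worst:.4g}/ms * dt {dt} ms = {worst * dt:.3g} "
            ">= 0.1; use a smaller dt_mc"
        )


def _initial_states(
    scheme: MarkovScheme, holding_v: float, n_sweeps: int, rng: np.random.Generator
) -> np.ndarray:
    p = scheme.stationary_distribution(holding_v)
    return rng.choice(scheme.n_states, size=n_sweeps, p=p)


def simulate_unitary_mc(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    n_sweeps: int = 100,
    seed: int = 0,
    dt_mc: float = 0.02,
) -> SweepSet:
    """Discrete-time jump simulation of unitary sweeps.

    Each sweep starts from the stationary distribution at the holding
    potential. Within each constant-voltage segment, dwell times of the
    per-step Bernoulli chain are geometric; they are sampled directly,
    which reproduces the per-step chain exactly while touching only the
    transition instants.
    """
    voltages = [protocol.holding_V] + [v for v, _ in protocol.steps]
    _check_dt(scheme, voltages, dt_mc)
    rng = np.random.default_rng(seed)
    segs = protocol.segments(dt_mc)
    n_total = sum(n for _, n in segs)
    occupancy = np.empty((n_sweeps, n_total), dtype=np.int8)
    states0 = _initial_states(scheme, protocol.holding_V, n_sweeps, rng)

    # per segment-voltage cache of (p_exit, destinations, cumulative probs)
    def seg_tables(v: float):
        tables = {}
        for i in range(scheme.n_states):
            dests, rates = [], []
            for (a, b), fn in scheme.transitions.items():
                if a == i:
                    dests.append(b)
                    rates.append(float(fn(v)) * dt_mc)
            rates = np.asarray(rates)
            p_exit = rates.sum()
            cum = np.cumsum(rates) / p_exit if p_exit > 0 else None
            tables[i] = (p_exit, np.asarray(dests, dtype=int), cum)
        return tables

    for sw in range(n_sweeps):
        state = int(states0[sw])
        pos = 0
        for v, n_steps in segs:
            tables = seg_tables(v)
            remaining = n_steps
            while remaining > 0:
                p_exit, dests, cum = tables[state]
                if p_exit == 0:
                    dwell = remaining
                else:
                    dwell = int(rng.geometric(p_exit))
                occ = min(dwell, remaining)
                occupancy[sw, pos : pos + occ] = state
                pos += occ
                remaining -= occ
                if dwell <= occ and p_exit > 0:
                    if dests.size == 1:
                        state = int(dests[0])
                    else:
                        state = int(dests[np.searchsorted(cum, rng.random())])
    v_t = protocol.voltage_trace(dt_mc)
    open_mask = occupancy == scheme.open_index
    sweeps = np.where(open_mask, scheme.unitary_current(v_t)[None, :], 0.0)
    return SweepSet(
        times=protocol.times(dt_mc),
        sweeps=sweeps,
        voltages=v_t,
        dt_mc=dt_mc,
        seed=seed,
        scheme_name=scheme.name,
        g_u=scheme.g_u,
        E_rev=scheme.E_rev,
    )


def simulate_unitary_per_step(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    n_sweeps: int = 10,
    seed: int = 0,
    dt_mc: float = 0.02,
) -> SweepSet:
    """Literal per-step Bernoulli sampler (reference implementation).

    Same law as :func:`simulate_unitary_mc`; O(steps) per sweep, intended
    for cross-checks on short protocols.
    """
    voltages = [protocol.holding_V] + [v for v, _ in protocol.steps]
    _check_dt(scheme, voltages, dt_mc)
    rng = np.random.default_rng(seed)
    segs = protocol.segments(dt_mc)
    n_total = sum(n for _, n in segs)
    occupancy = np.empty((n_sweeps, n_total), dtype=np.int8)
    states0 = _initial_states(scheme, protocol.holding_V, n_sweeps, rng)
    for sw in range(n_sweeps):
        state = int(states0[sw])
        pos = 0
        for v, n_steps in segs:
            trans = [
                (b, float(fn(v)) * dt_mc)
                for (a, b), fn in scheme.transitions.items()
                if a == state
            ]
            for _ in range(n_steps):
                occupancy[sw, pos] = state
                pos += 1
                u = rng.random()
                acc = 0.0
                for b, p in trans:
                    acc += p
                    if u < acc:
                        state = b
                        trans = [
                            (bb, float(fn(v)) * dt_mc)
                            for (aa, bb), fn in scheme.transitions.items()
                            if aa == state
                        ]
                        break
    v_t = protocol.voltage_trace(dt_mc)
    open_mask = occupancy == scheme.open_index
    sweeps = np.where(open_mask, scheme.unitary_current(v_t)[None, :], 0.0)
    return SweepSet(
        times=protocol.times(dt_mc),
        sweeps=sweeps,
        voltages=v_t,
        dt_mc=dt_mc,
        seed=seed,
        scheme_name=scheme.name,
        g_u=scheme.g_u,
        E_rev=scheme.E_rev,
    )


def simulate_unitary_gillespie(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    n_sweeps: int = 10,
    seed: int = 0,
    sample_dt: float = 0.02,
) -> SweepSet:
    """Exact continuous-time (Gillespie) simulation, sampled on a grid.

    The continuous-time limit of the discrete chain; used as an independent
    cross-check of the dt-discretized samplers.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(int(round(d / sample_dt)) for _, d in protocol.steps)
    occupancy = np.empty((n_sweeps, n_total), dtype=np.int8)
    states0 = _initial_states(scheme, protocol.holding_V, n_sweeps, rng)
    for sw in range(n_sweeps):
        state = int(states0[sw])
        pos = 0
        for v, dur in protocol.steps:
            n_samples = int(round(dur / sample_dt))
            t = 0.0
            filled = 0
            while filled < n_samples:
                rates = [
                    (b, float(fn(v)))
                    for (a, b), fn in scheme.transitions.items()
                    if a == state
                ]
                total = sum(r for _, r in rates)
                dwell = rng.exponential(1.0 / total) if total > 0 else np.inf
                end = min(t + dwell, dur)
                upto = min(int(np.ceil(end / sample_dt)), n_samples)
                occupancy[sw, pos + filled : pos + upto] = state
                filled = upto
                t = end
                if t >= dur:
                    break
                u = rng.random() * total
                acc = 0.0
                for b, r in rates:
                    acc += r
                    if u < acc:
                        state = b
                        break
            pos += n_samples
    v_t = protocol.voltage_trace(sample_dt)
    open_mask = occupancy == scheme.open_index
    sweeps = np.where(open_mask, scheme.unitary_current(v_t)[None, :], 0.0)
    return SweepSet(
        times=protocol.times(sample_dt),
        sweeps=sweeps,
        voltages=v_t,
        dt_mc=sample_dt,
        seed=seed,
        scheme_name=scheme.name,
        g_u=scheme.g_u,
        E_rev=scheme.E_rev,
    )


# ---------------------------------------------------------------------------
# analysis of sweeps
# ---------------------------------------------------------------------------


def ensemble_average(sweep_set: SweepSet) -> np.ndarray:
    """Pointwise mean current across sweeps (pA)."""
    if sweep_set.n_sweeps < 1:
        raise ValueError("need at least one sweep")
    return sweep_set.sweeps.mean(axis=0)


def fit_unitary_conductance(sweeps_by_voltage: Mapping[float, SweepSet]) -> float:
    """Slope of the unitary open-level i-V relation, in pS.

    Per test voltage, the open-level current is the maximum-magnitude
    current observed while the channel is open across all sweeps; a least
    squares line of current (pA) against voltage (mV) is fitted through
    those points. Voltages without any opening are dropped.
    """
    if len(sweeps_by_voltage) < 3:
        raise ValueError("need sweeps at >= 3 test voltages")
    vs, amps = [], []
    for v, ss in sweeps_by_voltage.items():
        nonzero = ss.sweeps[ss.sweeps != 0.0]
        if nonzero.size == 0:
            continue
        amps.append(nonzero[np.argmax(np.abs(nonzero))])
        vs.append(v)
    if len(vs) < 2:
        raise ValueError(
            "channel never opened at enough voltages; simulate longer or more sweeps"
        )
    slope = np.polyfit(np.asarray(vs), np.asarray(amps), 1)[0]  # pA/mV = nS
    return float(slope * 1e3)  # pS


# ---------------------------------------------------------------------------
# master equation and channel counting
# ---------------------------------------------------------------------------


def occupancy_ode(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    n_channels: int = 1,
    sample_dt: float | None = None,
) -> dict:
    """State-occupancy probabilities and expected whole-cell current.

    Integrates ``dp/dt = Q(V)^T p`` with piecewise-constant V via matrix
    exponential propagation (exact for step protocols). Initial condition is
    the stationary distribution at the holding potential. Returns times,
    probabilities (n_samples x n_states), open probability and the expected
    current ``N * p_open * g_u * (V - E_rev)`` (pA).
    """
    dt = sample_dt if sample_dt is not None else protocol.sample_dt
    p = scheme.stationary_distribution(protocol.holding_V)
    probs = []
    v_all = []
    for v, dur in protocol.steps:
        n = int(round(dur / dt))
        prop = expm(scheme.rate_matrix(v).T * dt)
        for _ in range(n):
            probs.append(p.copy())
            v_all.append(v)
            p = prop @ p
    probs = np.asarray(probs)
    v_all = np.asarray(v_all)
    sums = probs.sum(axis=1)
    if np.max(np.abs(sums - 1.0)) > 1e-8:
        raise RuntimeError("probability conservation violated in master-equation solve")
    p_open = probs[:, scheme.open_index]
    current = n_channels * p_open * scheme.unitary_current(v_all)
    return {
        "times": np.arange(len(v_all)) * dt,
        "probabilities": probs,
        "p_open": p_open,
        "current": current,
        "voltages": v_all,
    }


def channel_count_from_conductance(g_cell_nS: float, g_u_pS: float) -> int:
    """Channels needed for a whole-cell conductance: ``round(G_cell/g_u)``."""
    if g_cell_nS <= 0 or g_u_pS <= 0:
        raise ValueError("conductances must be positive")
    return int(round(g_cell_nS * 1e3 / g_u_pS))
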