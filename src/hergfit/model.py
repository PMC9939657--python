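"""Hodgkin–Huxley hERG (IKr) channel model.

The current is ``I_Kr = g_Kr * a * r * (V - E_K)`` where ``a`` is an
activation gate and ``r`` an inactivation gate, each relaxing first-order
towards a voltage-dependent steady state:

    da/dt = (a_inf - a) / tau_a,   a_inf = k1/(k1+k2),  tau_a = 1/(k1+k2)
    dr/dt = (r_inf - r) / tau_r,   r_inf = k4/(k3+k4),  tau_r = 1/(k3+k4)

with Eyring-style rates ``k1 = p1*exp(p2*V)``, ``k2 = p3*exp(-p4*V)``,
``k3 = p5*exp(p6*V)``, ``k4 = p7*exp(-p8*V)``.  Nine free parameters:
theta = (g_Kr, p1..p8).  Internally voltages are volts, conductance pA/V,
current pA, time seconds.

Under a piecewise-constant voltage protocol the gate ODEs are linear with
constant coefficients within each segment, so the default simulation
backend evaluates the exact exponential-relaxation solution at the sample
times; an adaptive ODE backend (``method="ode"``) is provided for
cross-checking and satisfies the same tolerance contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationInfeasibleError
from .protocol import VoltageProtocol

#: Largest rate-law exponent magnitude accepted before the evaluation is
#: declared infeasible (exp(700) is near the float64 overflow edge).
EXP_GUARD = 700.0

PARAM_NAMES = ("g_kr", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")
N_PARAMS = 9


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and ionic concentrations for the Nernst potential."""

    R: float = 8.314472        # J/(K mol)
    T: float = 298.15          # K
    F: float = 96485.3415      # C/mol
    z: int = 1                 # K+ valency
    K_out: float = 4.0         # mM, extracellular [K+]
    K_in: float = 110.0        # mM, intracellular [K+]


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class ChannelParams:
    """The nine-parameter vector theta = (g_Kr, p1..p8).

    g_kr : maximal conductance, pA/V.
    p1, p3, p5, p7 : rate prefactors, 1/s.
    p2, p4, p6, p8 : voltage sensitivities, 1/V.
    All strictly positive.
    """

    g_kr: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ChannelParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {arr.shape}")
        return cls(*arr)

    @property
    def kinetics(self) -> np.ndarray:
        """The eight kinetic parameters p1..p8 (conductance excluded)."""
        return self.as_array()[1:]


@dataclass(frozen=True)
class GateState:
    """Occupancies of the activation (a) and inactivation (r) gates."""

    a: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError(f"gate occupancies must lie in [0,1], got a={self.a}, r={self.r}")

    def state_probabilities(self) -> dict[str, float]:
        """Occupancies of the four channel states CI, I, O, C (sum to 1)."""
        a, r = self.a, self.r
        return {
            "CI": (1 - r) * (1 - a),
            "I": a * (1 - r),
            "O": a * r,
            "C": r * (1 - a),
        }


@dataclass(frozen=True)
class RateSet:
    """Voltage-dependent transition rates, 1/s."""

    k1: float  # activation
    k2: float  # deactivation
    k3: float  # inactivation
    k4: float  # recovery


def nernst_potential(constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Reversal (Nernst) potential E_K = (R T)/(z F) ln([K+]_o/[K+]_i), volts."""
    c = constants
    if c.K_out <= 0 or c.K_in <= 0:
        raise ValueError("ion concentrations must be positive")
    if c.T <= 0:
        raise ValueError("temperature must be positive")
    if c.z == 0:
        raise ValueError("valency must be nonzero")
    return (c.R * c.T) / (c.z * c.F) * np.log(c.K_out / c.K_in)


def transition_rates(params: ChannelParams, V: float) -> RateSet:
    """Rates k1..k4 at membrane voltage ``V`` (volts).

    Raises :class:`SimulationInfeasibleError` if any exponent exceeds the
    overflow guard — the fitter treats that as an infeasible evaluation.
    """
    exponents = np.array([params.p2 * V, -params.p4 * V, params.p6 * V, -params.p8 * V])
    if not np.all(np.isfinite(exponents)) or np.any(np.abs(exponents) > EXP_GUARD):
        raise SimulationInfeasibleError(
            f"rate-law exponent overflow at V={V}: {exponents}"
        )
    pref = np.array([params.p1, params.p3, params.p5, params.p7])
    k = pref * np.exp(exponents)
    if not np.all(np.isfinite(k)):
        raise SimulationInfeasibleError(f"non-finite rate at V={V}")
    return RateSet(*k)


def gate_equilibria(rates: RateSet) -> tuple[float, float, float, float]:
    """Steady states and time constants (a_inf, r_inf, tau_a, tau_r)."""
    for name in ("k1", "k2", "k3", "k4"):
        if getattr(rates, name) <= 0:
            raise ValueError(f"{name} must be positive")
    sa = rates.k1 + rates.k2
    sr = rates.k3 + rates.k4
    return rates.k1 / sa, rates.k4 / sr, 1.0 / sa, 1.0 / sr


def equilibrium_state(params: ChannelParams, V: float) -> GateState:
    """Gate state at voltage-clamp equilibrium for ``V``."""
    a_inf, r_inf, _, _ = gate_equilibria(transition_rates(params, V))
    return GateState(a=a_inf, r=r_inf)


def instantaneous_current(
    params: ChannelParams, state: GateState, V: float, E_K: float
) -> float:
    """I_Kr = g_Kr * a * r * (V - E_K), picoamps."""
    return params.g_kr * state.a * state.r * (V - E_K)


def _segment_kinetics(params: ChannelParams, protocol: VoltageProtocol):
    """Per-segment (a_inf, r_inf, tau_a, tau_r) arrays."""
    out = np.empty((len(protocol.segments), 4))
    for i, (_, V) in enumerate(protocol.segments):
        out[i] = gate_equilibria(transition_rates(params, V))
    return out


def simulate_gates(
    params: ChannelParams,
    protocol: VoltageProtocol,
    times: np.ndarray,
    method: str = "analytic",
    abs_tol: float = 1e-8,
    rel_tol: float = 1e-10,
) -> np.ndarray:
    """Gate trajectories (n, 2) array of (a, r) at ``times``.

    Gates start at equilibrium for the protocol's first segment voltage.
    ``method="analytic"`` evaluates the exact per-segment exponential
    relaxation; ``method="ode"`` integrates with an adaptive stiff solver
    at the given tolerances.
    """
    times = np.asarray(times, dtype=float)
    kin = _segment_kinetics(params, protocol)
    bounds = protocol.boundaries
    seg_idx = np.clip(
        np.searchsorted(bounds, times, side="right") - 1, 0, len(protocol.segments) - 1
    )

    # gate state at the start of each segment
    a0 = np.empty(len(protocol.segments))
    r0 = np.empty(len(protocol.segments))
    a0[0], r0[0] = kin[0, 0], kin[0, 1]

    if method == "analytic":
        for s in range(1, len(protocol.segments)):
            dur = protocol.segments[s - 1][0]
            ainf, rinf, ta, tr = kin[s - 1]
            a0[s] = ainf + (a0[s - 1] - ainf) * np.exp(-dur / ta)
            r0[s] = rinf + (r0[s - 1] - rinf) * np.exp(-dur / tr)
        dt = times - bounds[seg_idx]
        ainf, rinf, ta, tr = kin[seg_idx].T
        a = ainf + (a0[seg_idx] - ainf) * np.exp(-dt / ta)
        r = rinf + (r0[seg_idx] - rinf) * np.exp(-dt / tr)
    elif method == "ode":
        from scipy.integrate import solve_ivp

        a = np.empty_like(times)
        r = np.empty_like(times)
        state = np.array([a0[0], r0[0]])
        for s, (dur, _) in enumerate(protocol.segments):
            ainf, rinf, ta, tr = kin[s]

            def rhs(_t, y, ainf=ainf, rinf=rinf, ta=ta, tr=tr):
                return [(ainf - y[0]) / ta, (rinf - y[1]) / tr]

            mask = seg_idx == s
            t_eval = np.concatenate([times[mask] - bounds[s], [dur]])
            order = np.argsort(t_eval, kind="stable")
            sol = solve_ivp(
                rhs, (0.0, dur), state, method="LSODA",
                t_eval=np.unique(t_eval), atol=abs_tol, rtol=rel_tol,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise SimulationInfeasibleError(f"ODE solver failed in segment {s}: {sol.message}")
            interp_a = np.interp(times[mask] - bounds[s], sol.t, sol.y[0])
            interp_r = np.interp(times[mask] - bounds[s], sol.t, sol.y[1])
            a[mask], r[mask] = interp_a, interp_r
            state = sol.y[:, -1]
            del order
    else:
        raise ValueError(f"unknown method {method!r}")

    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(r))):
        raise SimulationInfeasibleError("non-finite gate state along trajectory")
    return np.column_stack([a, r])


def simulate_current(
    params: ChannelParams,
    protocol: VoltageProtocol,
    sample_rate: float = 5000.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    method: str = "analytic",
    abs_tol: float = 1e-8,
    rel_tol: float = 1e-10,
):
    """Simulate I_Kr under voltage clamp; returns a :class:`~hergfit.dataset.CurrentTrace`.

    The trace is sampled uniformly at ``sample_rate`` over the protocol's
    total duration, with ``n = round(duration * sample_rate)`` samples at
    times ``i / sample_rate``.
    """
    from .dataset import CurrentTrace  # local import to avoid a cycle

    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round(protocol.total_duration * sample_rate))
    times = np.arange(n) / sample_rate
    gates = simulate_gates(params, protocol, times, method=method,
                           abs_tol=abs_tol, rel_tol=rel_tol)
    E_K = nernst_potential(constants)
    V = protocol.voltage_series(times)
    current = params.g_kr * gates[:, 0] * gates[:, 1] * (V - E_K)
    if not np.all(np.isfinite(current)):
        raise SimulationInfeasibleError("non-finite current sample")
    return CurrentTrace(values=current, sample_rate=float(sample_rate))
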