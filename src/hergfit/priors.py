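"""Uniform prior with physiological rate constraints, and the normalized
learning-space transform.

Parameters are drawn componentwise-uniform inside a box:
g_Kr ~ U(100, 5e5) pA/V; prefactors p1,p3,p5,p7 ~ U(1e-4, 1e6) 1/s;
sensitivities p2,p4,p6,p8 ~ U(1e-4, 400) 1/V — and accepted only if the
four maximal-rate constraints hold strictly:

    0.0167 < p1*exp( p2*Vmax) < 1e6
    0.0167 < p3*exp(-p4*Vmin) < 1e6
    0.0167 < p5*exp( p6*Vmax) < 1e6
    0.0167 < p7*exp(-p8*Vmin) < 1e6

with Vmin = -0.12 V, Vmax = 0.06 V.  These bound every transition rate
over the physiological voltage window: 0.0167 1/s is one event per
minute, 1e6 1/s the fastest rate resolvable at patch-clamp bandwidth.

Each constraint couples exactly one (prefactor, sensitivity) pair, so
rejection sampling is performed per pair — distributionally identical to
joint rejection but exponentially cheaper (joint acceptance is ~1e-6).

The learning-space transform applies log10 to the decade-spanning
parameters (g_Kr and the prefactors) and then min–max scales every
component to [0, 1] using bounds derived from the prior box, never from a
data batch, so train/validation/inference share one fixed transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SamplerError
from .model import ChannelParams, N_PARAMS, PARAM_NAMES

#: indices into the theta vector (g, p1..p8)
_PREFACTOR_IDX = (1, 3, 5, 7)   # p1, p3, p5, p7
_SENSITIVITY_IDX = (2, 4, 6, 8)  # p2, p4, p6, p8


@dataclass(frozen=True)
class PriorSpec:
    """Bounds of the uniform prior and of the rate constraints."""

    g_bounds: tuple[float, float] = (100.0, 500_000.0)        # pA/V
    prefactor_bounds: tuple[float, float] = (1e-4, 1e6)       # 1/s
    sensitivity_bounds: tuple[float, float] = (1e-4, 400.0)   # 1/V
    rate_bounds: tuple[float, float] = (0.0167, 1e6)          # 1/s
    v_min: float = -0.12                                       # V
    v_max: float = 0.06                                        # V

    def __post_init__(self):
        for lo, hi in (self.g_bounds, self.prefactor_bounds,
                       self.sensitivity_bounds, self.rate_bounds):
            if not lo < hi:
                raise ValueError(f"bounds must satisfy lo < hi, got ({lo}, {hi})")

    def box(self) -> np.ndarray:
        """(9, 2) array of per-parameter (lo, hi) prior bounds."""
        box = np.empty((N_PARAMS, 2))
        box[0] = self.g_bounds
        for i in _PREFACTOR_IDX:
            box[i] = self.prefactor_bounds
        for i in _SENSITIVITY_IDX:
            box[i] = self.sensitivity_bounds
        return box

    def in_box(self, theta: np.ndarray, rtol: float = 1e-9) -> bool:
        box = self.box()
        theta = np.asarray(theta, dtype=float)
        slack = rtol * (box[:, 1] - box[:, 0])
        return bool(np.all(theta >= box[:, 0] - slack) and np.all(theta <= box[:, 1] + slack))


DEFAULT_PRIOR = PriorSpec()


def constraint_rates(theta: np.ndarray, spec: PriorSpec = DEFAULT_PRIOR) -> np.ndarray:
    """The four extreme-voltage rate magnitudes the constraints bound.

    Returns [p1*e^(p2*Vmax), p3*e^(-p4*Vmin), p5*e^(p6*Vmax), p7*e^(-p8*Vmin)].
    """
    theta = np.asarray(theta, dtype=float)
    pref = theta[list(_PREFACTOR_IDX)]
    sens = theta[list(_SENSITIVITY_IDX)]
    volt = np.array([spec.v_max, -spec.v_min, spec.v_max, -spec.v_min])
    return pref * np.exp(sens * volt)


def check_constraints(params, spec: PriorSpec = DEFAULT_PRIOR) -> bool:
    """True iff all four rate constraints hold strictly."""
    theta = params.as_array() if isinstance(params, ChannelParams) else np.asarray(params)
    lo, hi = spec.rate_bounds
    r = constraint_rates(theta, spec)
    return bool(np.all((r > lo) & (r < hi)))


#: per-accepted-sample rejection budget before the sampler gives up
REJECTION_BUDGET = 1_000_000


def _pair_rng(seed: int, sample_index: int, pair: int, attempt: int) -> np.random.Generator:
    # counter-based substream: output depends only on (seed, i, pair, attempt),
    # never on other samples' rejection histories
    return np.random.Generator(
        np.random.Philox(key=seed, counter=[sample_index, pair, attempt, 0])
    )


def sample_params(
    spec: PriorSpec = DEFAULT_PRIOR, n: int = 1, seed: int = 0
) -> list[ChannelParams]:
    """Draw ``n`` constraint-satisfying parameter sets; deterministic in ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    arr = sample_params_array(spec, n, seed)
    return [ChannelParams.from_array(row) for row in arr]


def sample_params_array(
    spec: PriorSpec = DEFAULT_PRIOR, n: int = 1, seed: int = 0
) -> np.ndarray:
    """Like :func:`sample_params` but returns an (n, 9) array."""
    lo_r, hi_r = spec.rate_bounds
    volt = np.array([spec.v_max, -spec.v_min, spec.v_max, -spec.v_min])
    out = np.empty((n, N_PARAMS))
    for i in range(n):
        g_rng = _pair_rng(seed, i, 4, 0)
        out[i, 0] = g_rng.uniform(*spec.g_bounds)
        for pair in range(4):
            for attempt in range(REJECTION_BUDGET):
                rng = _pair_rng(seed, i, pair, attempt)
                p = rng.uniform(*spec.prefactor_bounds)
                s = rng.uniform(*spec.sensitivity_bounds)
                rate = p * np.exp(s * volt[pair])
                if lo_r < rate < hi_r:
                    out[i, 1 + 2 * pair] = p
                    out[i, 2 + 2 * pair] = s
                    break
            else:
                raise SamplerError(
                    f"rejection budget {REJECTION_BUDGET} exceeded for pair {pair}"
                )
    return out


@dataclass(frozen=True)
class NormalizationSpec:
    """Fixed transform between raw theta and the [0,1]^9 learning space."""

    log_flags: tuple[bool, ...]
    lo: tuple[float, ...]
    hi: tuple[float, ...]

    def __post_init__(self):
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError("normalization bounds must satisfy lo < hi")

    @classmethod
    def from_prior(cls, spec: PriorSpec = DEFAULT_PRIOR,
                   log_conductance: bool = True) -> "NormalizationSpec":
        """Derive the transform from the prior box.

        log10 is applied to the prefactors (they span 10 decades) and, by
        default, to g_Kr (3.7 decades); sensitivities stay linear.
        """
        box = spec.box()
        flags = np.zeros(N_PARAMS, dtype=bool)
        flags[list(_PREFACTOR_IDX)] = True
        flags[0] = log_conductance
        lo = np.where(flags, np.log10(box[:, 0]), box[:, 0])
        hi = np.where(flags, np.log10(box[:, 1]), box[:, 1])
        return cls(tuple(flags.tolist()), tuple(lo), tuple(hi))

    def _arrays(self):
        return (np.asarray(self.log_flags, dtype=bool),
                np.asarray(self.lo), np.asarray(self.hi))


DEFAULT_NORMALIZATION = NormalizationSpec.from_prior()


def to_normalized(params, norm: NormalizationSpec = DEFAULT_NORMALIZATION) -> np.ndarray:
    """Map theta to the unit box: log10 where flagged, then min–max scale."""
    theta = params.as_array() if isinstance(params, ChannelParams) else np.asarray(params, float)
    flags, lo, hi = norm._arrays()
    x = np.where(flags, np.log10(theta), theta)
    return (x - lo) / (hi - lo)


def from_normalized(vec, norm: NormalizationSpec = DEFAULT_NORMALIZATION,
                    eps: float = 1e-9) -> ChannelParams:
    """Inverse of :func:`to_normalized`; rejects vectors outside [-eps, 1+eps]."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,):
        raise ValueError(f"expected shape ({N_PARAMS},), got {vec.shape}")
    if np.any(vec < -eps) or np.any(vec > 1 + eps):
        raise ValueError(f"normalized vector outside [0,1]: {vec}")
    flags, lo, hi = norm._arrays()
    theta = lo + np.clip(vec, 0.0, 1.0) * (hi - lo)
    theta[flags] = 10.0 ** theta[flags]
    return ChannelParams.from_array(theta)
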