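"""Labelled synthetic training data: simulate, add noise, downsample, package.

Each training example pairs a downsampled noisy current trace with the
normalized generating parameter vector.  The emulated recording condition
is a 15.4 s staircase sweep at 5 kHz (77,000 samples) with additive
zero-mean Gaussian noise of SD 10.84 pA (measured at steady-state current
in the experimental recordings this pipeline emulates), decimated by 50 to
1,540 samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DatasetError
from .model import ChannelParams, simulate_current
from .errors import SimulationInfeasibleError
from .priors import (DEFAULT_NORMALIZATION, DEFAULT_PRIOR, NormalizationSpec,
                     PriorSpec, sample_params_array, to_normalized)
from .protocol import VoltageProtocol, build_default_staircase

DEFAULT_SAMPLE_RATE = 5000.0   # Hz
DEFAULT_NOISE_SIGMA = 10.84    # pA
DEFAULT_DOWNSAMPLE = 50

TRACE_CSV_HEADER = ("time_s", "current_pA")


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current time series, picoamps, starting at t=0."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


@dataclass(frozen=True)
class NoiseModel:
    """Additive zero-mean Gaussian measurement noise."""

    sigma: float = DEFAULT_NOISE_SIGMA  # pA

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class TrainingExample:
    trace: CurrentTrace
    target: np.ndarray          # normalized theta in [0,1]^9
    theta_raw: ChannelParams
    provenance: dict = field(default_factory=dict)


def add_noise(trace: CurrentTrace, noise: NoiseModel, seed: int = 0) -> CurrentTrace:
    """Add iid N(0, sigma^2) to every sample; deterministic given seed."""
    if noise.sigma == 0:
        return trace
    rng = np.random.default_rng(seed)
    return CurrentTrace(trace.values + rng.normal(0.0, noise.sigma, trace.values.size),
                        trace.sample_rate)


def downsample(trace: CurrentTrace, factor: int) -> CurrentTrace:
    """Keep-first decimation: every ``factor``-th sample starting at index 0."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return trace
    return CurrentTrace(trace.values[::factor], trace.sample_rate / factor)


@dataclass
class Dataset:
    """In-memory dataset container mirroring the on-disk layout."""

    traces: np.ndarray        # (n, m) downsampled noisy currents, pA
    targets: np.ndarray       # (n, 9) normalized theta
    theta: np.ndarray         # (n, 9) raw theta
    manifest: dict

    def __len__(self):
        return self.traces.shape[0]

    def example(self, i: int) -> TrainingExample:
        rate = self.manifest["sample_rate"] / self.manifest["downsample_factor"]
        return TrainingExample(
            trace=CurrentTrace(self.traces[i], rate),
            target=self.targets[i],
            theta_raw=ChannelParams.from_array(self.theta[i]),
            provenance={"index": i, "seed": self.manifest["seed"]},
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.traces, self.targets, self.theta):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def protocol_hash(protocol: VoltageProtocol) -> str:
    payload = json.dumps(protocol.segments).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def generate_dataset(
    n: int,
    spec: PriorSpec = DEFAULT_PRIOR,
    protocol: VoltageProtocol | None = None,
    noise: NoiseModel = NoiseModel(),
    factor: int = DEFAULT_DOWNSAMPLE,
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    norm: NormalizationSpec = DEFAULT_NORMALIZATION,
    resample_budget: int = 100,
) -> Dataset:
    """Sample -> simulate -> add noise -> downsample, ``n`` times.

    Noise is added to the full-rate trace (the noise model is stated on the
    recorded signal) before decimation.  A theta whose simulation fails is
    resampled under a fresh substream and the event recorded in the
    manifest.  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if protocol is None:
        protocol = build_default_staircase()

    m = int(round(protocol.total_duration * sample_rate))
    m_down = len(range(0, m, factor))
    traces = np.empty((n, m_down))
    thetas = np.empty((n, 9))
    resampled: list[int] = []

    for i in range(n):
        for attempt in range(resample_budget):
            # distinct prior substream per (example, attempt)
            theta = sample_params_array(spec, 1, seed=_mix(seed, i, attempt))[0]
            try:
                clean = simulate_current(ChannelParams.from_array(theta), protocol,
                                         sample_rate=sample_rate)
            except SimulationInfeasibleError:
                resampled.append(i)
                continue
            break
        else:
            raise DatasetError(f"resample budget exceeded for example {i}")
        noisy = add_noise(clean, noise, seed=_mix(seed, i, 7_000_000))
        traces[i] = downsample(noisy, factor).values
        thetas[i] = theta

    targets = np.stack([to_normalized(t, norm) for t in thetas])
    manifest = {
        "n": n,
        "seed": seed,
        "sigma": noise.sigma,
        "downsample_factor": factor,
        "sample_rate": sample_rate,
        "protocol_hash": protocol_hash(protocol),
        "protocol_name": protocol.name,
        "trace_length": m_down,
        "n_resampled": len(resampled),
        "resampled_indices": resampled,
    }
    return Dataset(traces=traces, targets=targets, theta=thetas, manifest=manifest)


def _mix(seed: int, i: int, attempt: int) -> int:
    # stable per-(seed, example, attempt) substream key, kept below 2^31
    h = hashlib.sha256(f"{seed}:{i}:{attempt}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Physiological cell population

#: Room-temperature hERG kinetics from sinusoidal-protocol patch-clamp
#: fitting (Beattie et al. 2018, cell 5), converted to pA/V, 1/s, 1/V.
#: The standard reference point for this model's physiological regime.
LITERATURE_THETA = np.array(
    [152_400.0, 0.226, 69.9, 0.0345, 54.62, 87.3, 8.91, 5.15, 31.58]
)


def literature_params() -> ChannelParams:
    """The literature (physiological) parameter set for this model."""
    return ChannelParams.from_array(LITERATURE_THETA)


def sample_cell_params(
    n: int,
    spread: float = 0.2,
    seed: int = 0,
    spec: PriorSpec = DEFAULT_PRIOR,
    budget: int = 1000,
) -> list[ChannelParams]:
    """Emulate a population of experimental cells.

    Each cell's theta is the literature value jittered componentwise by a
    lognormal factor exp(N(0, spread^2)) — cell-to-cell variability of
    roughly +/-20% per parameter at the default spread — then accepted only
    if it lies in the prior box and satisfies the rate constraints.

    Unlike draws from the full uniform prior (most of which sit in
    kinetically degenerate regimes where several parameters are not
    practically identifiable from a single sweep), these cells occupy the
    physiological regime the fitting benchmark is about.
    """
    from .priors import check_constraints

    box = spec.box()
    cells: list[ChannelParams] = []
    for i in range(n):
        for attempt in range(budget):
            rng = np.random.default_rng(_mix(seed, i, attempt))
            theta = LITERATURE_THETA * np.exp(rng.normal(0.0, spread, 9))
            theta = np.clip(theta, box[:, 0], box[:, 1])
            if check_constraints(theta, spec):
                cells.append(ChannelParams.from_array(theta))
                break
        else:
            raise DatasetError(f"cell resample budget exceeded at cell {i}")
    return cells


def generate_cells(
    n: int,
    spread: float = 0.2,
    seed: int = 0,
    spec: PriorSpec = DEFAULT_PRIOR,
    protocol: VoltageProtocol | None = None,
    noise: NoiseModel = NoiseModel(),
    factor: int = DEFAULT_DOWNSAMPLE,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> list[tuple[CurrentTrace, ChannelParams]]:
    """Noisy downsampled recordings of a synthetic cell population."""
    if protocol is None:
        protocol = build_default_staircase()
    out = []
    for i, theta in enumerate(sample_cell_params(n, spread, seed, spec)):
        clean = simulate_current(theta, protocol, sample_rate=sample_rate)
        noisy = add_noise(clean, noise, seed=_mix(seed, i, 8_000_000))
        out.append((downsample(noisy, factor), theta))
    return out


# ---------------------------------------------------------------------------
# I/O

def save_dataset(ds: Dataset, path) -> None:
    """Write the container to HDF5 with the manifest as a JSON attribute."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=ds.traces)
        f.create_dataset("targets", data=ds.targets)
        f.create_dataset("theta", data=ds.theta)
        f.attrs["manifest"] = json.dumps(ds.manifest)


def load_dataset(path) -> Dataset:
    import h5py

    with h5py.File(path, "r") as f:
        return Dataset(
            traces=f["traces"][...],
            targets=f["targets"][...],
            theta=f["theta"][...],
            manifest=json.loads(f.attrs["manifest"]),
        )


def write_trace_csv(trace: CurrentTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TRACE_CSV_HEADER) + "\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_trace_csv(path) -> CurrentTrace:
    """Read a ``time_s,current_pA`` CSV; infers the rate from the time column."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = np.atleast_1d(data["time_s"])
    v = np.atleast_1d(data["current_pA"])
    if t.size < 2:
        raise DatasetError("trace CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise DatasetError("trace CSV is not uniformly sampled")
    return CurrentTrace(values=v, sample_rate=1.0 / dt[0])
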