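"""Domain containers shared across the pipeline.

The pipeline moves through four representations: a raw multichannel
:class:`EEGRecording`, fixed-length artifact-free :class:`Epoch` segments, a
per-band :class:`ConnectivityMatrix` of phase-lag-index weights, and the
graph-theoretical read-out :class:`NetworkMeasures` (weighted clustering Cw,
weighted path length Lw, and their surrogate-normalized forms gamma and
lambda). The synthetic generator adds :class:`CouplingTopology` (the
ground-truth coupling graph driving simulated signals) and
:class:`TrialSimConfig` (the outcome-level trial generator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Standard 10-20 scalp electrode labels for a 19-channel clinical montage.
MONTAGE_1020 = [
    "Fp2", "Fp1", "F8", "F7", "F4", "F3", "T4", "T3", "C4", "C3",
    "T6", "T5", "P4", "P3", "O2", "O1", "Fz", "Cz", "Pz",
]

#: Sample rates (Hz) seen across clinical EEG equipment.
COMMON_SAMPLE_RATES = (200.0, 250.0, 256.0, 400.0, 500.0, 512.0)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band: half-open interval [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz})"
            )

    def validate_for_rate(self, rate: float) -> None:
        if self.high_hz >= rate / 2:
            raise ValueError(
                f"band {self.name!r} upper corner {self.high_hz} Hz is not "
                f"below the Nyquist frequency {rate / 2} Hz"
            )


#: Conventional clinical EEG bands used throughout.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 25.0),
)


@dataclass(frozen=True)
class FilterSpec:
    """Description of a realized digital filter, kept for provenance."""

    kind: str  # highpass | lowpass | bandpass
    corners_hz: tuple[float, ...]
    zero_phase: bool = True
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if any(c <= 0 for c in self.corners_hz):
            raise ValueError("filter corners must be positive")


@dataclass
class EEGRecording:
    """A channels x samples matrix of scalp potentials in microvolts."""

    data: np.ndarray
    rate: float
    labels: list[str]
    subject_id: str | None = None
    visit: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        if not 200 <= self.rate <= 512:
            warnings.warn(
                f"sample rate {self.rate} Hz outside the expected 200-512 Hz "
                "range of clinical EEG equipment",
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Epoch:
    """A contiguous artifact-free slice of a recording."""

    data: np.ndarray
    rate: float
    offset: int = 0
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be channels x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) per channel."""

    phases: np.ndarray
    rate: float
    band: str | None = None
    edge_trim: int = 0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band, per-epoch PLI adjacency matrix."""

    weights: np.ndarray
    labels: list[str]
    band: str | None = None
    epoch_id: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectivity diagonal must be exactly 0")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("PLI weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class NetworkMeasures:
    """Graph read-out of one network (or epoch-averaged per recording).

    gamma = Cw / <Cw over weight-shuffled surrogates>;
    lambda_ = Lw / <Lw over surrogates>. Values near 1 indicate random
    organization; gamma > 1 with moderate lambda indicates small-world
    structure.
    """

    cw: float
    lw: float
    gamma: float
    lambda_: float
    band: str | None = None
    n_surrogates: int = 50
    seed: int | None = None
    per_epoch: list["NetworkMeasures"] | None = None


@dataclass
class CouplingTopology:
    """Ground-truth coupling graph driving the signal simulator."""

    kappa: np.ndarray
    rewiring_p: float = 0.0
    base_k: int = 4

    def __post_init__(self) -> None:
        k = np.asarray(self.kappa, dtype=float)
        if not np.allclose(k, k.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(k) != 0):
            raise ValueError("coupling diagonal must be 0")
        if k.min() < 0:
            raise ValueError("coupling strengths must be non-negative")
        if not 0 <= self.rewiring_p <= 1:
            raise ValueError("rewiring_p must lie in [0, 1]")
        self.kappa = k

    @property
    def n_nodes(self) -> int:
        return self.kappa.shape[0]


VISITS = ("baseline", "wk12", "wk24")


@dataclass
class TrialSimConfig:
    """Outcome-level trial generator configuration.

    Defaults emulate a 2-arm, 3-visit (0/12/24 weeks), multi-site trial of
    ~180 subjects whose beta-band normalized clustering declines in the
    control arm and stays flat in the active arm, with ~20% missing
    baseline EEGs and ~7% dropout.
    """

    n_control: int = 93
    n_active: int = 86
    n_sites: int = 9
    mean_control: tuple[float, float, float] = (1.026, 1.022, 1.014)
    mean_active: tuple[float, float, float] = (1.028, 1.024, 1.029)
    sd_site: float = 0.006
    sd_subject: float = 0.009
    sd_residual: float = 0.027
    missing_baseline_frac: float = 0.20
    dropout_frac: float = 0.067
    memory_link: str = "none"  # none | linear | quadratic
    memory_noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("missing_baseline_frac", "dropout_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("sd_site", "sd_subject", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.memory_link not in ("none", "linear", "quadratic"):
            raise ValueError(f"unknown memory_link {self.memory_link!r}")


@dataclass
class MMRMResult:
    """Fitted mixed-model-for-repeated-measures summary."""

    params: dict[str, float]
    trajectory_F: float
    trajectory_df: tuple[int, float]
    trajectory_p: float
    endpoint_estimate: float
    endpoint_se: float
    endpoint_t: float
    endpoint_df: float
    endpoint_p: float
    icc: float
    var_site: float
    var_subject: float
    var_residual: float
    converged: bool
    df_method: str
    n_obs: int
    n_subjects: int
    site_dropped: bool = False
    warnings_: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    """Quadratic-vs-linear memory-association probe."""

    statistic: float
    p_value: float
    quadratic_coef: float
    linear_coef: float
    group: str | None
    timepoint: str | None
    model: str  # "per_timepoint" | "mixed"
    n: int
    degenerate_random_effect: bool = False
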