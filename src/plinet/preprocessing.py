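"""Reading, re-referencing, filtering, resampling and epoching of EEG.

Conventions follow multi-site clinical EEG practice: 19-channel 10-20
montage, 200-512 Hz sampling, off-line average reference, and four
4096-sample artifact-free epochs per recording. Band filtering is
zero-phase (forward-backward Butterworth) so that it cannot distort the
instantaneous phases that the connectivity stage depends on.

The transformation steps are exposed as sklearn-style transformers
(:class:`AverageReference`, :class:`BandpassFilter`, :class:`Resampler`,
:class:`EpochSelector`); the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BandDefinition, EEGRecording, Epoch, FilterSpec


class AsciiParseError(ValueError):
    """Raised when a plain-text sample matrix cannot be parsed."""


def read_eeg_ascii(
    path: str | Path,
    rate: float,
    labels: list[str] | None = None,
    subject_id: str | None = None,
    visit: str | None = None,
) -> EEGRecording:
    """Read a plain-text EEG sample matrix.

    The file holds one row per time point and one column per channel,
    whitespace- or comma-delimited, with an optional header row of channel
    labels. Values are taken to be microvolts.

    Parameters
    ----------
    path : path to the ASCII file.
    rate : sample rate in Hz (not stored in the file).
    labels : channel names; if omitted, taken from the header row.
    """
    path = Path(path)
    rows: list[list[float]] = []
    header: list[str] | None = None
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if not rows and header is None:
                # A non-numeric first row is a label header.
                try:
                    float(tokens[0])
                except ValueError:
                    header = tokens
                    continue
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise AsciiParseError(
                    f"{path.name}: non-numeric value on line {lineno}: {exc}"
                ) from None
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise AsciiParseError(
                    f"{path.name}: ragged row on line {lineno} "
                    f"({len(values)} values, expected {n_cols})"
                )
            rows.append(values)
    if not rows:
        raise AsciiParseError(f"{path.name}: no numeric data found")
    data = np.asarray(rows, dtype=float).T  # column-major -> channel rows
    if labels is None:
        if header is None:
            labels = [f"ch{i}" for i in range(data.shape[0])]
        else:
            labels = header
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{path.name}: {len(labels)} labels for {data.shape[0]} columns"
        )
    return EEGRecording(
        data=data, rate=rate, labels=list(labels),
        subject_id=subject_id, visit=visit,
    )


def read_eeg_edf(path: str | Path, **kwargs) -> EEGRecording:
    """Read an EDF file via mne (optional dependency)."""
    import mne  # lazy: only needed for EDF input

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data, rate=float(raw.info["sfreq"]),
        labels=list(raw.ch_names), **kwargs,
    )


class AverageReference(TransformerMixin, BaseEstimator):
    """Re-reference each sample to the instantaneous channel mean.

    After the transform the channel sum is zero at every sample; applying
    it twice equals applying it once.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: EEGRecording) -> EEGRecording:
        if X.n_channels < 2:
            raise ValueError("average reference undefined for <2 channels")
        data = X.data - X.data.mean(axis=0, keepdims=True)
        return EEGRecording(
            data=data, rate=X.rate, labels=list(X.labels),
            subject_id=X.subject_id, visit=X.visit,
        )


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase band-pass filter (forward-backward Butterworth).

    Parameters
    ----------
    low_hz, high_hz : band corners in Hz; must lie inside (0, Nyquist).
    order : Butterworth order per pass (default 4; the forward-backward
        application doubles the effective roll-off and cancels phase).
    """

    def __init__(self, low_hz: float, high_hz: float, order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order

    @property
    def spec(self) -> FilterSpec:
        return FilterSpec(
            kind="bandpass", corners_hz=(self.low_hz, self.high_hz),
            zero_phase=True, order=self.order,
        )

    def fit(self, X, y=None):
        return self

    def transform(self, X: EEGRecording | Epoch):
        nyq = X.rate / 2
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= nyq:
            raise ValueError(
                f"high corner {self.high_hz} Hz >= Nyquist {nyq} Hz"
            )
        sos = signal.butter(
            self.order, [self.low_hz, self.high_hz],
            btype="bandpass", fs=X.rate, output="sos",
        )
        data = signal.sosfiltfilt(sos, X.data, axis=1)
        if isinstance(X, Epoch):
            return Epoch(data=data, rate=X.rate, offset=X.offset, band=X.band)
        return EEGRecording(
            data=data, rate=X.rate, labels=list(X.labels),
            subject_id=X.subject_id, visit=X.visit,
        )


class Resampler(TransformerMixin, BaseEstimator):
    """Anti-aliased polyphase resampling to a target rate.

    Handles both integer decimation and rational ratios (e.g. 500 -> 200
    Hz) through :func:`scipy.signal.resample_poly`, which applies the
    anti-alias low-pass as part of the polyphase filter.
    """

    def __init__(self, target_rate: float):
        self.target_rate = target_rate

    def fit(self, X, y=None):
        return self

    def transform(self, X: EEGRecording) -> EEGRecording:
        if self.target_rate > X.rate:
            raise ValueError(
                f"target rate {self.target_rate} Hz exceeds source rate "
                f"{X.rate} Hz (upsampling not supported)"
            )
        if self.target_rate == X.rate:
            return X
        from fractions import Fraction

        frac = Fraction(self.target_rate / X.rate).limit_denominator(1000)
        data = signal.resample_poly(X.data, frac.numerator,
                                    frac.denominator, axis=1)
        return EEGRecording(
            data=data, rate=self.target_rate, labels=list(X.labels),
            subject_id=X.subject_id, visit=X.visit,
        )


def detect_artifacts(
    rec: EEGRecording,
    amp_thresh_uv: float = 100.0,
    flat_run: int | None = None,
) -> np.ndarray:
    """Heuristic per-sample artifact mask.

    A sample is flagged when any channel exceeds ``amp_thresh_uv``
    microvolts in absolute value, or when any channel is exactly constant
    over a run of at least ``flat_run`` samples (default one second) --
    a stand-in for the visual artifact screening of clinical practice.

    Returns a boolean vector of length ``n_samples``; True marks artifact.
    """
    if amp_thresh_uv <= 0:
        raise ValueError("amp_thresh_uv must be > 0")
    if flat_run is None:
        flat_run = int(round(rec.rate))
    if flat_run <= 0:
        raise ValueError("flat_run must be > 0")
    mask = (np.abs(rec.data) > amp_thresh_uv).any(axis=0)
    # Flat-line runs: consecutive equal samples on a channel.
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        same = np.concatenate(([False], np.diff(x) == 0))
        # run-length encode `same`
        idx = np.flatnonzero(np.diff(same.astype(int)) != 0) + 1
        bounds = np.concatenate(([0], idx, [len(same)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if same[a] and (b - a) + 1 >= flat_run:
                mask[a - 1:b] = True
    return mask


class EpochSelector(TransformerMixin, BaseEstimator):
    """Greedy left-to-right selection of artifact-free epochs.

    Scans the recording from sample 0, taking the first ``n_epochs``
    non-overlapping windows of ``epoch_len`` samples that contain no
    flagged sample; on hitting an artifact the scan restarts just past it.
    Deterministic by construction, unlike the expert visual selection it
    replaces.
    """

    def __init__(self, n_epochs: int = 4, epoch_len: int = 4096,
                 amp_thresh_uv: float = 100.0,
                 flat_run: int | None = None):
        self.n_epochs = n_epochs
        self.epoch_len = epoch_len
        self.amp_thresh_uv = amp_thresh_uv
        self.flat_run = flat_run

    def fit(self, X, y=None):
        return self

    def transform(self, X: EEGRecording,
                  mask: np.ndarray | None = None) -> list[Epoch]:
        if mask is None:
            mask = detect_artifacts(X, self.amp_thresh_uv, self.flat_run)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (X.n_samples,):
            raise ValueError("mask length must equal the number of samples")
        L = self.epoch_len
        epochs: list[Epoch] = []
        i = 0
        n = X.n_samples
        while i + L <= n and len(epochs) < self.n_epochs:
            window = mask[i:i + L]
            if window.any():
                i = i + int(np.flatnonzero(window)[-1]) + 1
            else:
                epochs.append(Epoch(data=X.data[:, i:i + L].copy(),
                                    rate=X.rate, offset=i))
                i += L
        if len(epochs) < self.n_epochs:
            raise ValueError(
                f"{len(epochs)} clean epochs found, {self.n_epochs} requested"
            )
        return epochs


# -- thin functional wrappers ------------------------------------------------

def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample channel mean from every channel."""
    return AverageReference().transform(rec)


def bandpass_filter(rec: EEGRecording | Epoch, band: BandDefinition,
                    order: int = 4):
    """Zero-phase band-pass to ``band`` (forward-backward Butterworth)."""
    return BandpassFilter(band.low_hz, band.high_hz, order=order).transform(rec)


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Resample to ``target_rate`` with anti-alias filtering."""
    return Resampler(target_rate).transform(rec)


def select_epochs(rec: EEGRecording, n_epochs: int = 4,
                  epoch_len: int = 4096,
                  mask: np.ndarray | None = None) -> list[Epoch]:
    """First ``n_epochs`` non-overlapping artifact-free windows."""
    return EpochSelector(n_epochs=n_epochs, epoch_len=epoch_len).transform(
        rec, mask=mask
    )
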