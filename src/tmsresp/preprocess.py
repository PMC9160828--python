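"""Automated resting-state EEG preprocessing: filter, epoch, reject.

Replaces an interactive preprocessing workflow with a deterministic one:
zero-phase IIR band-pass (0.1-60 Hz) plus 50 Hz notch, segmentation into
fixed-length epochs, and amplitude-threshold artifact rejection (default
+/-100 uV) standing in for manual epoch-by-epoch review and ICA blink
correction, which are not reproducible in software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, EmptyResultError

__all__ = [
    "EEGRecording",
    "EpochSet",
    "bandpass_notch",
    "segment",
    "reject_artifacts",
    "read_brainvision",
    "read_edf",
    "save_epochs",
    "load_epochs",
]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    data is channels x samples; channel labels follow the 10-20 convention.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str
    condition: str = "eyes-closed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ParameterError("data must be a channels x samples matrix with >= 1 channel")
        if np.any(np.isnan(self.data)):
            raise ParameterError("recording contains NaN samples")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ParameterError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ParameterError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``kept_mask`` indexes the original segmentation: entry *i* is True iff
    the i-th raw epoch survived rejection, so ``epochs`` holds exactly the
    rows where the mask is True, in order.
    """

    epochs: np.ndarray  # n_epochs x channels x samples_per_epoch
    fs: float
    epoch_length_s: float
    kept_mask: np.ndarray  # bool over the original segmentation
    channel_labels: tuple[str, ...]
    subject_id: str

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be n_epochs x channels x samples")
        if self.epochs.shape[0] < 1:
            raise EmptyResultError("epoch set is empty")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ParameterError(
                f"samples per epoch {self.epochs.shape[2]} != fs x length = {expected}"
            )
        if int(self.kept_mask.sum()) != self.epochs.shape[0]:
            raise ParameterError("kept_mask must select exactly the present epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def concatenate(self) -> np.ndarray:
        """Concatenate kept epochs back into a channels x samples array."""
        return np.concatenate(list(self.epochs.transpose(0, 2, 1)), axis=0).T

    def kept_runs(self) -> list[np.ndarray]:
        """Concatenated channels x samples arrays, one per contiguous run of kept epochs."""
        runs: list[np.ndarray] = []
        idx = 0
        current: list[np.ndarray] = []
        for kept in self.kept_mask:
            if kept:
                current.append(self.epochs[idx])
                idx += 1
            elif current:
                runs.append(np.concatenate([e.T for e in current]).T)
                current = []
        if current:
            runs.append(np.concatenate([e.T for e in current]).T)
        return runs


def bandpass_notch(
    rec: EEGRecording,
    low_hz: float = 0.1,
    high_hz: float = 60.0,
    notch_hz: float | None = 50.0,
) -> EEGRecording:
    """Zero-phase band-pass plus mains notch, per channel.

    Butterworth order 4 band-pass applied forward-backward (sosfiltfilt), then
    a second-order notch (Q = 30) at ``notch_hz`` (None disables it).  The
    high-pass edge removes DC and slow drift.
    """
    nyq = rec.fs / 2
    if not 0 < low_hz < high_hz:
        raise ParameterError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ParameterError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    if notch_hz is not None and not low_hz < notch_hz < high_hz:
        raise ParameterError("notch frequency must lie inside the passband")

    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return EEGRecording(out, rec.fs, rec.channel_labels, rec.subject_id, rec.condition)


def segment(rec: EEGRecording, epoch_length_s: float = 1.0) -> EpochSet:
    """Cut the recording into non-overlapping epochs; the trailing remainder is dropped."""
    spw = int(round(rec.fs * epoch_length_s))
    if spw < 1:
        raise ParameterError("epoch length must cover at least one sample")
    n_epochs = rec.n_samples // spw
    if n_epochs < 1:
        raise ParameterError(
            f"recording of {rec.duration_s:.3f} s is shorter than the required "
            f"minimum of one {epoch_length_s}-s epoch"
        )
    cut = rec.data[:, : n_epochs * spw]
    epochs = cut.reshape(rec.data.shape[0], n_epochs, spw).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        kept_mask=np.ones(n_epochs, dtype=bool),
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
    )


def reject_artifacts(epochs: EpochSet, amp_threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude on any channel exceeds the threshold.

    Idempotent; raises EmptyResultError if nothing survives.
    """
    if amp_threshold_uv <= 0:
        raise ParameterError("amplitude threshold must be positive")
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep_local = peak <= amp_threshold_uv
    if not keep_local.any():
        raise EmptyResultError(
            f"all {epochs.n_epochs} epochs exceed +/-{amp_threshold_uv} uV"
        )
    new_mask = epochs.kept_mask.copy()
    new_mask[np.flatnonzero(epochs.kept_mask)[~keep_local]] = False
    return EpochSet(
        epochs=epochs.epochs[keep_local],
        fs=epochs.fs,
        epoch_length_s=epochs.epoch_length_s,
        kept_mask=new_mask,
        channel_labels=epochs.channel_labels,
        subject_id=epochs.subject_id,
    )


# ---------------------------------------------------------------------------
# I/O.  Readers go through MNE; exclusion of non-scalp channels (reference,
# ground, EOG) happens here by label list so only analysis channels enter
# the feature pipeline.
# ---------------------------------------------------------------------------

def _from_mne_raw(raw, subject_id: str, condition: str, exclude: tuple[str, ...]) -> EEGRecording:
    picks = [ch for ch in raw.ch_names if ch not in exclude]
    data = raw.get_data(picks=picks) * 1e6  # MNE uses volts internally
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(picks),
        subject_id=subject_id,
        condition=condition,
    )


def read_brainvision(
    vhdr_path: str | Path,
    subject_id: str | None = None,
    condition: str = "eyes-closed",
    exclude_channels: tuple[str, ...] = (),
) -> EEGRecording:
    """Read a BrainVision .vhdr/.vmrk/.eeg triplet into an EEGRecording (uV)."""
    import mne

    vhdr_path = Path(vhdr_path)
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    sid = subject_id if subject_id is not None else vhdr_path.stem
    return _from_mne_raw(raw, sid, condition, exclude_channels)


def read_edf(
    edf_path: str | Path,
    subject_id: str | None = None,
    condition: str = "eyes-closed",
    exclude_channels: tuple[str, ...] = (),
) -> EEGRecording:
    """Read an EDF/EDF+ file into an EEGRecording (uV)."""
    import mne

    edf_path = Path(edf_path)
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    sid = subject_id if subject_id is not None else edf_path.stem
    return _from_mne_raw(raw, sid, condition, exclude_channels)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write cleaned epochs as a .npy array plus a JSON sidecar with metadata."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), epochs.epochs)
    sidecar = {
        "fs": epochs.fs,
        "epoch_length_s": epochs.epoch_length_s,
        "kept_mask": epochs.kept_mask.astype(int).tolist(),
        "channel_labels": list(epochs.channel_labels),
        "subject_id": epochs.subject_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        epochs=np.load(path.with_suffix(".npy")),
        fs=meta["fs"],
        epoch_length_s=meta["epoch_length_s"],
        kept_mask=np.asarray(meta["kept_mask"], dtype=bool),
        channel_labels=tuple(meta["channel_labels"]),
        subject_id=meta["subject_id"],
    )
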