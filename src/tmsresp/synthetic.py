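"""Synthetic resting-state EEG cohorts with known class structure.

Emulates the study conditions of a small rTMS trial in Alzheimer's disease:
14 subjects (8 treatment responders, 6 non-responders), ~30 scalp channels at
500 Hz, 4-minute eyes-closed recordings.  Each channel is pink (1/f)
background noise plus unit-variance band-limited Gaussian components, one per
canonical EEG band, scaled by a class-dependent linear amplitude gain; a
shared broadband source mixed into every channel gives the montage a
non-trivial spatial correlation.  Responder status is encoded as a
class-dependent theta-band gain, mirroring the empirical finding that theta
power carries the response signal.

Band-limited components are built by FFT masking of white Gaussian noise
(zero every bin outside the band, inverse transform, rescale to unit
variance), so band confinement is exact and matches the FFT-mask band filter
used downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .preprocess import EEGRecording
from .bandpower import CANONICAL_BANDS, CANONICAL_BAND_NAMES

__all__ = [
    "MMSERule",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_recording",
    "generate_cohort",
    "write_brainvision",
    "write_cohort",
]

TMS_POS = "TMS+"
TMS_NEG = "TMS-"

# Extended 10-20 scalp labels; the first n_channels are used.
_SCALP_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "PO3", "POz", "PO4", "O1", "O2", "PO7", "PO8",
)


@dataclass(frozen=True)
class MMSERule:
    """How MMSE pre/post scores are drawn per class.

    Pre-treatment scores are integers in [pre_low, pre_high], a plausible
    mild-to-moderate dementia range.  Responders gain 1-3 points (a fraction
    of them, ``tie_fraction``, stay constant to exercise the tie-goes-to-
    responder labeling rule); non-responders lose 1-3 points.
    """

    pre_low: int = 10
    pre_high: int = 28
    delta_magnitudes: tuple[int, ...] = (1, 2, 3)
    tie_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.pre_low <= self.pre_high <= 30:
            raise ConfigurationError("MMSE pre range must satisfy 0 <= low <= high <= 30")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise ConfigurationError("tie_fraction must be in [0, 1]")


def _default_gains() -> dict[str, float]:
    return {name: 1.0 for name in CANONICAL_BAND_NAMES}


def _pos_gains() -> dict[str, float]:
    g = _default_gains()
    g["theta"] = 1.5
    return g


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth generating parameters for one synthetic cohort.

    Amplitude units are microvolts: each band component has standard
    deviation ``gain x component_scale_uv``, the pink background has total
    standard deviation ``pink_noise_sd`` uV (chosen so the in-band SNR of the
    theta component is near 1), and the shared broadband source contributes
    ``mixing_scale_uv`` uV through random per-channel mixing weights.
    """

    n_pos: int = 8
    n_neg: int = 6
    n_channels: int = 30
    fs: float = 500.0
    duration_s: float = 240.0
    band_gains_pos: dict[str, float] = field(default_factory=_pos_gains)
    band_gains_neg: dict[str, float] = field(default_factory=_default_gains)
    pink_noise_sd: float = 17.0
    component_scale_uv: float = 5.0
    mixing_scale_uv: float = 5.0
    mmse_rule: MMSERule = field(default_factory=MMSERule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigurationError("need at least one subject per class")
        if self.n_channels < 1 or self.n_channels > len(_SCALP_1020):
            raise ConfigurationError(
                f"n_channels must be in [1, {len(_SCALP_1020)}]"
            )
        highest_edge = max(b.f_high for b in CANONICAL_BANDS)
        if self.fs <= 2 * highest_edge:
            raise ConfigurationError(
                f"fs = {self.fs} Hz must exceed twice the highest band edge "
                f"({highest_edge} Hz)"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        for side, gains in (("pos", self.band_gains_pos), ("neg", self.band_gains_neg)):
            unknown = set(gains) - set(CANONICAL_BAND_NAMES)
            if unknown:
                raise ConfigurationError(
                    f"band_gains_{side} names unknown bands {sorted(unknown)}"
                )
            if any(g < 0 for g in gains.values()):
                raise ConfigurationError("band gains must be non-negative")
        if self.pink_noise_sd < 0 or self.component_scale_uv < 0 or self.mixing_scale_uv < 0:
            raise ConfigurationError("amplitude scales must be non-negative")

    def gains_for(self, label: str) -> dict[str, float]:
        if label == TMS_POS:
            return dict(self.band_gains_pos)
        if label == TMS_NEG:
            return dict(self.band_gains_neg)
        raise ConfigurationError(f"unknown class label {label!r}")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return _SCALP_1020[: self.n_channels]


@dataclass
class SyntheticCohort:
    """Recordings plus subject metadata, with the generating config attached."""

    recordings: list[EEGRecording]
    subjects: list  # list[SubjectRecord]; typed loosely to avoid a cycle
    truth: SyntheticConfig


def _band_limited_noise(n: int, fs: float, f_low: float, f_high: float, rng,
                        n_rows: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [f_low, f_high] by FFT masking.

    Returns an (n_rows, n) matrix of independent rows, each rescaled to unit
    variance (exact band confinement, matching the downstream FFT band filter).
    """
    white = rng.standard_normal((n_rows, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[:, (freqs < f_low) | (freqs > f_high)] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return np.where(sd > 0, x / np.where(sd > 0, sd, 1.0), x)


def _pink_noise(n: int, fs: float, sd: float, rng, n_rows: int = 1) -> np.ndarray:
    """1/f-shaped Gaussian noise, each row rescaled to standard deviation ``sd``."""
    if sd == 0:
        rng.standard_normal((n_rows, n))  # keep the stream position stable
        return np.zeros((n_rows, n))
    white = rng.standard_normal((n_rows, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    cur = x.std(axis=1, keepdims=True)
    return x * (sd / np.where(cur > 0, cur, 1.0))


def generate_recording(
    config: SyntheticConfig, label: str, subject_seed: int | np.random.SeedSequence
) -> EEGRecording:
    """One subject's multichannel recording for the given class label.

    Each channel is an independent draw of pink background plus per-band
    components at the class gains, plus a weighted copy of a broadband source
    shared across channels (random weights per channel) so channels are
    spatially correlated.
    """
    gains = config.gains_for(label)  # validates label
    if isinstance(subject_seed, np.random.SeedSequence):
        ss = subject_seed
    else:
        ss = np.random.SeedSequence(int(subject_seed))
    rng = np.random.default_rng(ss)
    n = int(round(config.fs * config.duration_s))
    n_ch = config.n_channels

    if config.mixing_scale_uv > 0:
        common = _pink_noise(n, config.fs, 1.0, rng)[0]
    else:
        common = np.zeros(n)
    weights = rng.uniform(0.2, 0.8, size=n_ch)

    data = _pink_noise(n, config.fs, config.pink_noise_sd, rng, n_rows=n_ch)
    for band in CANONICAL_BANDS:
        g = gains.get(band.name, 0.0)
        if g > 0:
            data += g * config.component_scale_uv * _band_limited_noise(
                n, config.fs, band.f_low, band.f_high, rng, n_rows=n_ch
            )
    data += config.mixing_scale_uv * weights[:, None] * common[None, :]

    return EEGRecording(
        data=data,
        fs=config.fs,
        channel_labels=config.channel_labels,
        subject_id="",  # filled in by generate_cohort; standalone use keeps it blank
        condition="eyes-closed",
    )


def _draw_mmse(rule: MMSERule, label: str, tie: bool, rng) -> tuple[int, int]:
    pre = int(rng.integers(rule.pre_low, rule.pre_high + 1))
    if label == TMS_POS:
        delta = 0 if tie else int(rng.choice(rule.delta_magnitudes))
        post = min(30, pre + delta)
    else:
        delta = int(rng.choice(rule.delta_magnitudes))
        post = max(0, pre - delta)
        if post >= pre:  # pre == 0 corner: force a strict decrease impossible; bump pre
            pre = min(30, pre + delta)
            post = pre - delta
    return pre, post


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the full cohort: recordings plus an MMSE-labeled subject table.

    Per-subject seeds are spawned deterministically from the master seed
    (counter-offset spawn keys), so regeneration with the same config is
    bit-identical and any single subject can be regenerated in isolation.
    """
    from .validate import SubjectRecord, label_subjects  # local import: avoid cycle

    labels = [TMS_POS] * config.n_pos + [TMS_NEG] * config.n_neg
    n_tie = int(round(config.mmse_rule.tie_fraction * config.n_pos))
    recordings: list[EEGRecording] = []
    rows: list[dict] = []
    for i, label in enumerate(labels):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        rec = generate_recording(config, label, ss)
        sid = f"S{i + 1:02d}"
        rec.subject_id = sid
        recordings.append(rec)
        meta_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i, 1))
        )
        tie = label == TMS_POS and i < n_tie
        pre, post = _draw_mmse(config.mmse_rule, label, tie, meta_rng)
        rows.append({"subject_id": sid, "mmse_pre": pre, "mmse_post": post})

    subjects = label_subjects(rows)
    got = [s.label for s in subjects]
    if got != labels:  # sanity: the MMSE rule must reproduce the intended classes
        raise ConfigurationError("MMSE draw did not reproduce the intended labels")
    return SyntheticCohort(recordings=recordings, subjects=subjects, truth=config)


# ---------------------------------------------------------------------------
# On-disk export: BrainVision triplets plus a CSV subject table.
# ---------------------------------------------------------------------------

def write_brainvision(rec: EEGRecording, outdir: str | Path, basename: str | None = None) -> Path:
    """Write one recording as a BrainVision .vhdr/.vmrk/.eeg triplet.

    IEEE float32, multiplexed orientation, amplitudes in uV.  Readable by
    any BrainVision-aware tool (including the package's own reader).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = basename or rec.subject_id or "recording"
    vhdr, vmrk, eeg = (outdir / f"{base}{ext}" for ext in (".vhdr", ".vmrk", ".eeg"))

    sampling_interval_us = 1e6 / rec.fs
    ch_lines = "\n".join(
        f"Ch{i + 1}={label},,1,µV" for i, label in enumerate(rec.channel_labels)
    )
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "; Synthetic recording\n\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={eeg.name}\n"
        f"MarkerFile={vmrk.name}\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={len(rec.channel_labels)}\n"
        f"SamplingInterval={sampling_interval_us:.6f}\n\n"
        "[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n\n"
        "[Channel Infos]\n"
        f"{ch_lines}\n",
        encoding="utf-8",
    )
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    return vhdr


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort: BrainVision triplets, subjects.csv, config.json."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_brainvision(rec, outdir)
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.subjects],
            "mmse_pre": [s.mmse_pre for s in cohort.subjects],
            "mmse_post": [s.mmse_post for s in cohort.subjects],
            "condition": [rec.condition for rec in cohort.recordings],
        }
    )
    table.to_csv(outdir / "subjects.csv", index=False)
    cfg = asdict(cohort.truth)
    cfg["mmse_rule"] = asdict(cohort.truth.mmse_rule)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1))
    return outdir
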