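"""End-to-end orchestration: config, preprocessing chain, experiment runner.

Binds the stages together: read (or simulate) recordings -> band-pass +
notch -> 1-s epochs -> amplitude rejection -> windowed band-power features
-> per-fold selection + classification under the balanced Monte-Carlo
leave-one-out engine (or direct classification).  Also provides the two
comparison tables of the analysis: accuracy per feature-extraction window
size, and accuracy per feature-selection method.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .preprocess import (
    EEGRecording,
    bandpass_notch,
    segment,
    reject_artifacts,
    read_brainvision,
    read_edf,
)
from .bandpower import CANONICAL_BANDS, extract_features, stack_features
from .synthetic import SyntheticConfig, SyntheticCohort, generate_cohort, write_cohort
from .validate import (
    ValidationReport,
    label_subjects,
    run_loo,
    direct_classification,
)
from .hyperopt import SearchSpace

__all__ = [
    "FeatureConfig",
    "RunConfig",
    "cohort_features",
    "run_experiment",
    "simulate",
    "compare_selectors",
    "window_size_sweep",
]

logger = logging.getLogger("tmsresp")


@dataclass(frozen=True)
class FeatureConfig:
    """Preprocessing and feature-extraction parameters."""

    low_hz: float = 0.1
    high_hz: float = 60.0
    notch_hz: float | None = 50.0
    epoch_length_s: float = 1.0
    amp_threshold_uv: float = 100.0
    window_length_s: float = 2.0
    band_subset: tuple[str, ...] | None = None
    strict_windows: bool = False


@dataclass
class RunConfig:
    """One experiment: data source, feature, selector, classifier, validation."""

    recordings_dir: str | None = None
    subject_table: str | None = None
    output_dir: str = "runs"
    condition: str = "eyes-closed"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selector: dict = field(default_factory=lambda: {"method": "none"})
    classifier: dict = field(default_factory=lambda: {"type": "svm"})
    use_hyperopt: bool = False
    validation_mode: str = "loo"  # loo | direct
    train_fraction: float = 9 / 14
    trial_cap: int = 50
    val_per_class: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        feats = raw.pop("features", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "features"})
        if feats:
            if "band_subset" in feats and feats["band_subset"] is not None:
                feats["band_subset"] = tuple(feats["band_subset"])
            cfg.features = FeatureConfig(**feats)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def clean_recording(rec: EEGRecording, fc: FeatureConfig):
    """Filter, epoch and reject one recording."""
    filtered = bandpass_notch(rec, fc.low_hz, fc.high_hz, fc.notch_hz)
    epochs = segment(filtered, fc.epoch_length_s)
    return reject_artifacts(epochs, fc.amp_threshold_uv)


def cohort_features(cohort: SyntheticCohort, fc: FeatureConfig = FeatureConfig()):
    """Preprocess every recording and stack the windowed band-power features.

    Returns (X, provenance, subject_ids); rows follow the cohort's recording
    order.
    """
    series = []
    for rec in cohort.recordings:
        clean = clean_recording(rec, fc)
        series.append(
            extract_features(
                clean,
                bands=CANONICAL_BANDS,
                window_length_s=fc.window_length_s,
                band_subset=list(fc.band_subset) if fc.band_subset else None,
                strict_windows=fc.strict_windows,
            )
        )
    return stack_features(series)


def load_cohort(recordings_dir: str | Path, subject_table: str | Path,
                condition: str = "eyes-closed") -> SyntheticCohort:
    """Read a cohort from disk: BrainVision/EDF recordings plus a subjects CSV."""
    recordings_dir = Path(recordings_dir)
    table = pd.read_csv(subject_table)
    subjects = label_subjects(table)
    recordings = []
    for s in subjects:
        vhdr = recordings_dir / f"{s.subject_id}.vhdr"
        edf = recordings_dir / f"{s.subject_id}.edf"
        if vhdr.exists():
            recordings.append(read_brainvision(vhdr, s.subject_id, condition))
        elif edf.exists():
            recordings.append(read_edf(edf, s.subject_id, condition))
        else:
            raise ConfigurationError(
                f"no recording found for subject {s.subject_id} in {recordings_dir}"
            )
    return SyntheticCohort(recordings=recordings, subjects=subjects, truth=None)


def simulate(config: SyntheticConfig, outdir: str | Path | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort; optionally write it to disk."""
    cohort = generate_cohort(config)
    if outdir is not None:
        write_cohort(cohort, outdir)
        logger.info("wrote synthetic cohort to %s", outdir)
    return cohort


def run_experiment(config: RunConfig, cohort: SyntheticCohort | None = None) -> ValidationReport:
    """Execute the configured experiment end to end and persist artifacts.

    ``cohort`` may be passed directly (e.g. fresh from simulate); otherwise
    it is loaded from the configured paths.  Writes the validation report
    (JSON, embedding seed and config hash) and a text summary to output_dir.
    """
    if cohort is None:
        if not config.recordings_dir or not config.subject_table:
            raise ConfigurationError("recordings_dir and subject_table (or a cohort) required")
        cohort = load_cohort(config.recordings_dir, config.subject_table, config.condition)

    X, provenance, subject_ids = cohort_features(cohort, config.features)
    order = {s.subject_id: s for s in cohort.subjects}
    subjects = [order[sid] for sid in subject_ids]

    space = SearchSpace() if config.use_hyperopt else None
    if config.validation_mode == "loo":
        report = run_loo(
            X, subjects, provenance=provenance,
            selector_config=config.selector, classifier_config=config.classifier,
            seed=config.seed, trial_cap=config.trial_cap,
            val_per_class=config.val_per_class, hyperopt_space=space,
        )
    elif config.validation_mode == "direct":
        report = direct_classification(
            X, subjects, provenance=provenance,
            train_fraction=config.train_fraction, n_random_trials=config.trial_cap,
            selector_config=config.selector, classifier_config=config.classifier,
            seed=config.seed,
        )
    else:
        raise ConfigurationError(f"unknown validation_mode {config.validation_mode!r}")

    report.config["config_hash"] = config.config_hash
    report.config["run_config"] = config.to_dict()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_json(outdir / f"report_{config.config_hash}.json")
    (outdir / f"report_{config.config_hash}.txt").write_text(report.summary() + "\n")
    logger.info("experiment done: mean accuracy %.1f%%", report.overall_mean)
    return report


def compare_selectors(
    cohort: SyntheticCohort,
    methods: dict[str, dict] | None = None,
    fc: FeatureConfig = FeatureConfig(),
    classifier: dict | None = None,
    seed: int = 0,
    trial_cap: int = 50,
) -> pd.DataFrame:
    """Leave-one-out accuracy per feature-selection route (one comparison row).

    Default methods: none, pca, wavelet, swlda, theta-band restriction.
    """
    if methods is None:
        methods = {
            "none": {"method": "none"},
            "pca": {"method": "pca", "k": 20},
            "wavelet": {"method": "wavelet", "keep_fraction": 0.10},
            "swlda": {"method": "swlda"},
            "theta": {"method": "band_restrict", "band": "theta"},
        }
    X, provenance, subject_ids = cohort_features(cohort, fc)
    order = {s.subject_id: s for s in cohort.subjects}
    subjects = [order[sid] for sid in subject_ids]
    rows = {}
    for name, sel in methods.items():
        rep = run_loo(
            X, subjects, provenance=provenance, selector_config=sel,
            classifier_config=classifier, seed=seed, trial_cap=trial_cap,
            keep_audit=False,
        )
        rows[name] = rep.overall_mean
    return pd.DataFrame([rows])


def window_size_sweep(
    cohort: SyntheticCohort,
    window_lengths_s: tuple[float, ...] = (1.0, 2.0, 4.0),
    base_fc: FeatureConfig = FeatureConfig(),
    selector: dict | None = None,
    classifier: dict | None = None,
    seed: int = 0,
    trial_cap: int = 50,
) -> pd.DataFrame:
    """Leave-one-out accuracy per feature-extraction window length."""
    rows = {}
    for w in window_lengths_s:
        fc = FeatureConfig(
            low_hz=base_fc.low_hz, high_hz=base_fc.high_hz, notch_hz=base_fc.notch_hz,
            epoch_length_s=base_fc.epoch_length_s,
            amp_threshold_uv=base_fc.amp_threshold_uv,
            window_length_s=w, band_subset=base_fc.band_subset,
            strict_windows=base_fc.strict_windows,
        )
        X, provenance, subject_ids = cohort_features(cohort, fc)
        order = {s.subject_id: s for s in cohort.subjects}
        subjects = [order[sid] for sid in subject_ids]
        rep = run_loo(
            X, subjects, provenance=provenance, selector_config=selector,
            classifier_config=classifier, seed=seed, trial_cap=trial_cap,
            keep_audit=False,
        )
        rows[f"window {w:g} s"] = rep.overall_mean
    return pd.DataFrame([rows])
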