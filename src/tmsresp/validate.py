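"""Labeling, balanced Monte-Carlo leave-one-out validation, direct classification.

With 14 subjects split 8/6 into responders (TMS+) and non-responders (TMS-),
a single train/test split is meaningless; the engine therefore holds out one
subject at a time and, within each fold, repeatedly draws class-balanced
train and validation subsets from the remaining subjects, averaging the
held-out subject's classification outcome over the draws.  The number of
draws follows from combinatorics — the count of distinct maximal balanced
subsets times the count of balanced train/validation partitions, capped at
50 — so the Monte-Carlo average covers the sampling space.

Everything that learns from data (standardization statistics, feature
selectors, hyperparameters, the classifier) is fit on the training rows of
each trial only; the held-out subject never leaks into any fitted quantity.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ConfigurationError, TmsrespError
from .featsel import Standardizer, make_selector
from .classify import SVMParams, train_svm, predict, train_swlda_classifier, accuracy
from .hyperopt import SearchSpace, evolutionary_search

__all__ = [
    "TMS_POS",
    "TMS_NEG",
    "SubjectRecord",
    "SplitPlan",
    "ValidationReport",
    "label_subjects",
    "max_balanced_subset",
    "n_trials_required",
    "mc_leave_one_out",
    "run_loo",
    "direct_classification",
    "size_sweep",
    "permutation_null_band",
]

TMS_POS = "TMS+"
TMS_NEG = "TMS-"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: MMSE before/after treatment and the derived response label.

    The labeling rule: MMSE increased or constant after treatment -> TMS+
    (responder; ties count as benefit), decreased -> TMS- (non-responder).
    """

    subject_id: str
    mmse_pre: int
    mmse_post: int
    label: str

    def __post_init__(self) -> None:
        for name, score in (("mmse_pre", self.mmse_pre), ("mmse_post", self.mmse_post)):
            if not 0 <= score <= 30:
                raise ParameterError(
                    f"subject {self.subject_id}: {name} = {score} outside [0, 30]"
                )
        expected = TMS_POS if self.mmse_post >= self.mmse_pre else TMS_NEG
        if self.label != expected:
            raise ParameterError(
                f"subject {self.subject_id}: label {self.label!r} inconsistent with "
                f"MMSE change {self.mmse_pre} -> {self.mmse_post} (expected {expected!r})"
            )


@dataclass(frozen=True)
class SplitPlan:
    """One Monte-Carlo trial of one leave-one-out fold."""

    test_id: str
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    trial_seed: int

    def validate(self, labels: dict[str, str]) -> None:
        """Assert pairwise disjointness and class balance; violations abort the run."""
        test, train, val = {self.test_id}, set(self.train_ids), set(self.val_ids)
        if (test & train) or (test & val) or (train & val):
            raise TmsrespError(f"split sets overlap: {self}")
        for name, ids in (("train", self.train_ids), ("val", self.val_ids)):
            pos = sum(labels[i] == TMS_POS for i in ids)
            neg = len(ids) - pos
            if pos != neg:
                raise TmsrespError(
                    f"{name} set unbalanced ({pos} TMS+ vs {neg} TMS-): {self}"
                )


@dataclass
class ValidationReport:
    """Aggregated outcome of a validation run."""

    per_subject: dict[str, float]
    overall_mean: float
    trial_sd: float
    n_trials: dict[str, int]
    config: dict
    audit: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["config_hash"] = hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        text = json.dumps(payload, indent=1, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [
            f"overall mean accuracy: {self.overall_mean:.1f}%",
            f"across-trial SD:       {self.trial_sd:.1f}%",
            "per-subject accuracy:",
        ]
        for sid, acc in self.per_subject.items():
            lines.append(f"  {sid}: {acc:6.1f}%  ({self.n_trials[sid]} trials)")
        if self.skipped:
            lines.append(f"skipped folds: {len(self.skipped)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Labeling and balanced sampling
# ---------------------------------------------------------------------------

def label_subjects(table) -> list[SubjectRecord]:
    """Derive TMS+/TMS- labels from an MMSE table.

    Accepts a pandas DataFrame or a sequence of mappings with columns
    subject_id, mmse_pre, mmse_post.  A missing or non-finite score raises an
    error naming the subject.
    """
    if isinstance(table, pd.DataFrame):
        rows = table.to_dict("records")
    else:
        rows = list(table)
    records: list[SubjectRecord] = []
    for row in rows:
        sid = str(row.get("subject_id", "<unnamed>"))
        for col in ("mmse_pre", "mmse_post"):
            value = row.get(col)
            if value is None or (isinstance(value, float) and not math.isfinite(value)):
                raise ParameterError(f"subject {sid}: missing {col}")
        pre, post = int(row["mmse_pre"]), int(row["mmse_post"])
        label = TMS_POS if post >= pre else TMS_NEG
        records.append(SubjectRecord(sid, pre, post, label))
    return records


def max_balanced_subset(
    ids_by_class: dict[str, Sequence[str]], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Sample a maximal balanced subset: min-class-count subjects from each class.

    Sampling is without replacement, uniform over subjects; every maximal
    balanced subset is equally likely (the practical equivalent of drawing
    many random selections and keeping a maximal balanced one).
    """
    if any(len(ids) == 0 for ids in ids_by_class.values()) or len(ids_by_class) < 2:
        raise ParameterError("both classes must be nonempty")
    k = min(len(ids) for ids in ids_by_class.values())
    return {
        label: sorted(rng.choice(np.asarray(ids, dtype=object), size=k, replace=False).tolist())
        for label, ids in ids_by_class.items()
    }


def n_trials_required(n_pos: int, n_neg: int, cap: int = 50, val_per_class: int = 1) -> int:
    """Monte-Carlo trial count from combinatorics, capped.

    Distinct maximal balanced subsets = C(max, max - min) (the ways to drop
    the surplus majority-class subjects); each subset splits into balanced
    train/validation sets in C(min, v)^2 ways.  The product, capped at
    ``cap`` (default 50), is the number of random trials per fold.
    """
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("class counts must be >= 1")
    hi, lo = max(n_pos, n_neg), min(n_pos, n_neg)
    n_subsets = math.comb(hi, hi - lo)
    n_partitions = math.comb(lo, val_per_class) ** 2 if 0 < val_per_class < lo else 1
    return min(n_subsets * n_partitions, cap)


def permutation_null_band(n_outcomes: int, level: float = 0.95) -> tuple[float, float]:
    """Exact chance band for mean accuracy over ``n_outcomes`` held-out outcomes.

    Under label exchange each fold outcome is at worst an independent fair
    coin flip, so the mean accuracy (in %) follows Binomial(n, 1/2)/n; the
    returned band holds the central ``level`` mass.  Averaging each fold over
    many correlated trials only shrinks the variance, so the band is
    conservative for the Monte-Carlo engine.
    """
    alpha = (1 - level) / 2
    lo = stats.binom.ppf(alpha, n_outcomes, 0.5) / n_outcomes * 100
    hi = stats.binom.ppf(1 - alpha, n_outcomes, 0.5) / n_outcomes * 100
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# The Monte-Carlo leave-one-out engine
# ---------------------------------------------------------------------------

def _build_selector(selector_config: dict | None, n_train: int):
    cfg = dict(selector_config or {"method": "none"})
    method = cfg.pop("method", "none")
    if method == "pca":
        # the projection rank cannot exceed n_train - 1
        cfg["k"] = min(int(cfg.get("k", 20)), n_train - 1)
    if method == "swlda":
        cfg.setdefault("max_features", n_train)
    return make_selector(method, **cfg)


def _fit_predict_trial(
    X: np.ndarray,
    y: np.ndarray,
    provenance,
    idx_train: np.ndarray,
    idx_val: np.ndarray,
    idx_test: np.ndarray,
    selector_config: dict | None,
    classifier_config: dict | None,
    hyperopt_space: SearchSpace | None,
):
    """Fit standardizer + selector + classifier on train rows; predict test rows.

    Returns (predicted labels, decision values, chosen hyperparameters).
    """
    ccfg = dict(classifier_config or {"type": "svm"})
    ctype = ccfg.pop("type", "svm")

    std = Standardizer().fit(X[idx_train])
    Xs = std.transform(X)
    selector = _build_selector(selector_config, len(idx_train))
    selector.fit(Xs[idx_train], y[idx_train], provenance=provenance)
    Xt = selector.transform(Xs)

    chosen: dict = {}
    if Xt.shape[1] == 0:
        # the selector kept nothing (possible with SWLDA): majority fallback
        vals, counts = np.unique(y[idx_train], return_counts=True)
        majority = vals[int(np.argmax(counts))]
        pred = np.full(len(idx_test), majority)
        return pred, np.zeros(len(idx_test)), {"fallback": "majority"}
    if ctype == "swlda":
        model = train_swlda_classifier(Xt[idx_train], y[idx_train],
                                       max_features=len(idx_train))
        pred = model.predict(Xt[idx_test])
        dec = model.decision_scores(Xt[idx_test])
        return pred, dec, chosen

    if ctype != "svm":
        raise ConfigurationError(f"unknown classifier type {ctype!r}")

    if hyperopt_space is not None:
        if len(idx_val) == 0:
            raise ConfigurationError("hyperparameter search needs a validation set")

        def objective(C: float, sigma: float) -> float:
            m = train_svm(Xt[idx_train], y[idx_train],
                          SVMParams(C=C, sigma=sigma, kernel=ccfg.get("kernel", "rbf")))
            lab, _ = predict(m, Xt[idx_val])
            return accuracy(y[idx_val], lab)

        chosen, _trace = evolutionary_search(objective, hyperopt_space)
        params = SVMParams(C=chosen["C"], sigma=chosen["sigma"],
                           kernel=ccfg.get("kernel", "rbf"))
    else:
        params = SVMParams(
            C=float(ccfg.get("C", 1.0)),
            sigma=ccfg.get("sigma"),
            kernel=ccfg.get("kernel", "rbf"),
        )
    model = train_svm(Xt[idx_train], y[idx_train], params)
    pred, dec = predict(model, Xt[idx_test])
    return pred, dec, chosen


def run_loo(
    X: np.ndarray,
    subjects: Sequence[SubjectRecord],
    provenance=None,
    selector_config: dict | None = None,
    classifier_config: dict | None = None,
    seed: int = 0,
    trial_cap: int = 50,
    val_per_class: int = 1,
    train_per_class: int | None = None,
    hyperopt_space: SearchSpace | None = None,
    keep_audit: bool = True,
) -> ValidationReport:
    """Balanced Monte-Carlo leave-one-out on a precomputed feature matrix.

    Every subject serves as the test sample exactly once.  Per fold,
    ``n_trials_required`` balanced subsets of the remaining subjects are
    drawn and split into balanced train and validation sets
    (``val_per_class`` subjects per class in validation; the rest train,
    optionally subsampled to ``train_per_class``).  All fitting happens on
    the training rows of each trial.
    """
    X = np.asarray(X, dtype=float)
    subjects = list(subjects)
    if X.shape[0] != len(subjects):
        raise ParameterError("one feature row per subject required")
    labels = {s.subject_id: s.label for s in subjects}
    y = np.asarray([s.label for s in subjects])
    index_of = {s.subject_id: i for i, s in enumerate(subjects)}
    for cls in (TMS_POS, TMS_NEG):
        if np.sum(y == cls) < 2:
            raise ParameterError(f"need >= 2 subjects per class, {cls} has {np.sum(y == cls)}")

    per_subject: dict[str, float] = {}
    n_trials_map: dict[str, int] = {}
    all_outcomes: list[float] = []
    audit: list[dict] = []
    skipped: list[dict] = []

    for fold_idx, test_subject in enumerate(subjects):
        rest = [s for s in subjects if s.subject_id != test_subject.subject_id]
        ids_by_class = {
            TMS_POS: [s.subject_id for s in rest if s.label == TMS_POS],
            TMS_NEG: [s.subject_id for s in rest if s.label == TMS_NEG],
        }
        k = min(len(v) for v in ids_by_class.values())
        tpc = train_per_class if train_per_class is not None else k - val_per_class
        if min(len(v) for v in ids_by_class.values()) < val_per_class + 1 or tpc < 1 \
                or tpc + val_per_class > k:
            skipped.append({
                "subject_id": test_subject.subject_id,
                "reason": f"infeasible balance: {len(ids_by_class[TMS_POS])} TMS+ / "
                          f"{len(ids_by_class[TMS_NEG])} TMS- remaining, "
                          f"val_per_class={val_per_class}, train_per_class={tpc}",
            })
            continue

        n_trials = n_trials_required(
            len(ids_by_class[TMS_POS]), len(ids_by_class[TMS_NEG]),
            cap=trial_cap, val_per_class=val_per_class,
        )
        outcomes = []
        for t in range(n_trials):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold_idx, t))
            trial_seed = int(ss.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(ss)
            subset = max_balanced_subset(ids_by_class, rng)
            val_ids: list[str] = []
            train_ids: list[str] = []
            for cls, ids in subset.items():
                ids = list(ids)
                rng.shuffle(ids)
                val_ids.extend(ids[:val_per_class])
                train_ids.extend(ids[val_per_class:val_per_class + tpc])
            plan = SplitPlan(
                test_id=test_subject.subject_id,
                train_ids=tuple(sorted(train_ids)),
                val_ids=tuple(sorted(val_ids)),
                trial_seed=trial_seed,
            )
            plan.validate(labels)

            idx_train = np.asarray([index_of[i] for i in plan.train_ids])
            idx_val = np.asarray([index_of[i] for i in plan.val_ids])
            idx_test = np.asarray([index_of[plan.test_id]])
            pred, dec, chosen = _fit_predict_trial(
                X, y, provenance, idx_train, idx_val, idx_test,
                selector_config, classifier_config, hyperopt_space,
            )
            correct = float(pred[0] == test_subject.label) * 100.0
            outcomes.append(correct)
            if keep_audit:
                audit.append({
                    "test_id": plan.test_id,
                    "train_ids": list(plan.train_ids),
                    "val_ids": list(plan.val_ids),
                    "trial_seed": plan.trial_seed,
                    "chosen_params": chosen,
                    "decision_value": float(dec[0]),
                    "correct": bool(correct == 100.0),
                })
        per_subject[test_subject.subject_id] = float(np.mean(outcomes))
        n_trials_map[test_subject.subject_id] = n_trials
        all_outcomes.extend(outcomes)

    if not per_subject:
        raise TmsrespError("every fold was infeasible; nothing to report")

    return ValidationReport(
        per_subject=per_subject,
        overall_mean=float(np.mean(all_outcomes)),
        trial_sd=float(np.std(all_outcomes)),
        n_trials=n_trials_map,
        config={
            "mode": "mc_leave_one_out",
            "selector": selector_config or {"method": "none"},
            "classifier": classifier_config or {"type": "svm"},
            "seed": seed,
            "trial_cap": trial_cap,
            "val_per_class": val_per_class,
            "train_per_class": train_per_class,
            "hyperopt": hyperopt_space is not None,
        },
        audit=audit,
        skipped=skipped,
    )


def mc_leave_one_out(
    cohort,
    feature_config=None,
    selector_config: dict | None = None,
    classifier_config: dict | None = None,
    seed: int = 0,
    **engine_kwargs,
) -> ValidationReport:
    """End-to-end engine entry: preprocess + extract features, then run_loo.

    ``cohort`` carries recordings and subject records; ``feature_config`` is a
    pipeline.FeatureConfig (defaults used when None).
    """
    from .pipeline import FeatureConfig, cohort_features

    fc = feature_config or FeatureConfig()
    X, provenance, subject_ids = cohort_features(cohort, fc)
    order = {s.subject_id: s for s in cohort.subjects}
    subjects = [order[sid] for sid in subject_ids]
    return run_loo(
        X, subjects, provenance=provenance,
        selector_config=selector_config, classifier_config=classifier_config,
        seed=seed, **engine_kwargs,
    )


# ---------------------------------------------------------------------------
# Direct classification and dataset-size sweeps
# ---------------------------------------------------------------------------

def direct_classification(
    X: np.ndarray,
    subjects: Sequence[SubjectRecord],
    provenance=None,
    train_fraction: float = 9 / 14,
    n_random_trials: int = 50,
    selector_config: dict | None = None,
    classifier_config: dict | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Random stratified train/test splits without a validation set.

    Per trial the cohort is split class-stratified at ``train_fraction``
    (default 9 of 14 subjects in training — the empirically optimal ratio);
    mean and SD of test accuracy over ``n_random_trials`` trials are reported.
    """
    X = np.asarray(X, dtype=float)
    subjects = list(subjects)
    y = np.asarray([s.label for s in subjects])
    ids = [s.subject_id for s in subjects]
    n = len(subjects)

    by_class = {cls: np.flatnonzero(y == cls) for cls in (TMS_POS, TMS_NEG)}
    n_train_by_class = {}
    for cls, idx in by_class.items():
        n_tr = int(round(train_fraction * idx.size))
        if n_tr < 1 or n_tr > idx.size - 1:
            raise ParameterError(
                f"train_fraction {train_fraction:.3f} leaves class {cls} without "
                "at least one subject in both train and test"
            )
        n_train_by_class[cls] = n_tr

    trial_accs: list[float] = []
    subj_hits: dict[str, list[float]] = {sid: [] for sid in ids}
    audit: list[dict] = []
    for t in range(n_random_trials):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(t,)))
        idx_train_parts = []
        for cls, idx in by_class.items():
            perm = rng.permutation(idx)
            idx_train_parts.append(perm[: n_train_by_class[cls]])
        idx_train = np.sort(np.concatenate(idx_train_parts))
        idx_test = np.setdiff1d(np.arange(n), idx_train)

        pred, dec, _ = _fit_predict_trial(
            X, y, provenance, idx_train, np.asarray([], dtype=int), idx_test,
            selector_config, classifier_config, hyperopt_space=None,
        )
        acc = accuracy(y[idx_test], pred)
        trial_accs.append(acc)
        for j, pi in zip(idx_test, pred):
            subj_hits[ids[j]].append(float(pi == y[j]) * 100.0)
        audit.append({
            "train_ids": [ids[i] for i in idx_train],
            "test_ids": [ids[i] for i in idx_test],
            "accuracy": acc,
        })

    per_subject = {sid: float(np.mean(h)) if h else float("nan") for sid, h in subj_hits.items()}
    return ValidationReport(
        per_subject=per_subject,
        overall_mean=float(np.mean(trial_accs)),
        trial_sd=float(np.std(trial_accs)),
        n_trials={sid: len(h) for sid, h in subj_hits.items()},
        config={
            "mode": "direct_classification",
            "train_fraction": train_fraction,
            "n_random_trials": n_random_trials,
            "selector": selector_config or {"method": "none"},
            "classifier": classifier_config or {"type": "svm"},
            "seed": seed,
        },
        audit=audit,
    )


def size_sweep(
    X: np.ndarray,
    subjects: Sequence[SubjectRecord],
    mode: str = "train-size",
    provenance=None,
    selector_config: dict | None = None,
    classifier_config: dict | None = None,
    seed: int = 0,
    trial_cap: int = 50,
    fixed_val_per_class: int = 1,
    fixed_train_per_class: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out accuracy across the feasible grid of dataset sizes.

    ``train-size``: validation fixed at ``fixed_val_per_class`` per class,
    training size swept over every feasible per-class count.  ``val-size``:
    training size fixed, validation size swept.  Returns a table of
    (size, mean_accuracy, sd) with size in subjects (both classes).
    """
    subjects = list(subjects)
    y = np.asarray([s.label for s in subjects])
    n_pos, n_neg = int(np.sum(y == TMS_POS)), int(np.sum(y == TMS_NEG))
    # worst-case per-class pool after removing one subject of the minority class
    k_min = min(n_pos, n_neg) - 1

    rows = []
    if mode == "train-size":
        grid = range(1, k_min - fixed_val_per_class + 1)
        for tpc in grid:
            rep = run_loo(
                X, subjects, provenance=provenance,
                selector_config=selector_config, classifier_config=classifier_config,
                seed=seed, trial_cap=trial_cap,
                val_per_class=fixed_val_per_class, train_per_class=tpc,
                keep_audit=False,
            )
            rows.append({"size": 2 * tpc, "mean_accuracy": rep.overall_mean,
                         "sd": rep.trial_sd})
    elif mode == "val-size":
        for vpc in range(1, k_min):
            tpc = fixed_train_per_class if fixed_train_per_class is not None else k_min - vpc
            if tpc < 1 or tpc + vpc > k_min:
                continue
            rep = run_loo(
                X, subjects, provenance=provenance,
                selector_config=selector_config, classifier_config=classifier_config,
                seed=seed, trial_cap=trial_cap,
                val_per_class=vpc, train_per_class=tpc,
                keep_audit=False,
            )
            rows.append({"size": 2 * vpc, "mean_accuracy": rep.overall_mean,
                         "sd": rep.trial_sd})
    else:
        raise ParameterError("mode must be 'train-size' or 'val-size'")
    return pd.DataFrame(rows)
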