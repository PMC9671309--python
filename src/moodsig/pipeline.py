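"""MRLSF extraction, participant-level cross-validated classification and reports.

Every ten-week window path (four normalised score channels plus the cumulative
missing-count channel) is mapped to its level-3 log-signature on the Lyndon
basis — the missing-response-incorporated log-signature features (MRLSF).  A
random forest is trained and evaluated under participant-level k-fold
cross-validation: all windows of a participant live in exactly one fold, so
train and hold-out sets never share a participant.  Window-level class
probabilities are aggregated to participant diagnoses by hard (majority) and
soft (summed-probability) voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoding import CLASSES, INSTRUMENTS, MoodStream
from .logsig import LyndonBasis, logsig, lyndon_words, witt_dimension
from .preprocess import PreparedWindow

logger = logging.getLogger(__name__)

#: Channel display names for feature reports; index 4 is the miss-count channel.
CHANNEL_NAMES = ("ASRM", "QIDS", "EQ-5D", "GAD-7", "the missing signal")


@dataclass
class WindowSet:
    """Per-window MRLSF matrix with the window -> participant mapping."""

    features: np.ndarray
    window_participant: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    basis: LyndonBasis

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


@dataclass
class FoldAssignment:
    """Participant -> fold map for leakage-free grouped cross-validation."""

    fold_of_participant: dict[str, int]
    k: int
    seed: int

    def test_participants(self, fold: int) -> set[str]:
        return {p for p, f in self.fold_of_participant.items() if f == fold}


@dataclass
class ParticipantPrediction:
    """Window-level probabilities and the two participant-level votes."""

    participant_id: str
    window_probs: np.ndarray
    hard_label: str = field(init=False)
    soft_label: str = field(init=False)
    soft_prob: np.ndarray = field(init=False)

    def __post_init__(self):
        self.soft_label, self.soft_prob = vote_soft(self.window_probs)
        self.hard_label = vote_hard(self.window_probs)


@dataclass
class RFConfig:
    """Random-forest hyperparameters (exposed; sensible fixed defaults)."""

    n_estimators: int = 500
    max_depth: Optional[int] = None
    max_features: str = "sqrt"
    random_state: int = 0

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=1,
        )


@dataclass
class EvalReport:
    """Participant-level evaluation: accuracy, f1, confusion, AUC, importances."""

    accuracy_hard: float
    accuracy_soft: float
    f1_hard: dict[str, float]
    f1_soft: dict[str, float]
    confusion_hard: np.ndarray
    confusion_soft: np.ndarray
    auc: dict[str, float]
    auc_ci: dict[str, tuple[float, float]]
    importance: list[tuple[str, float]]

    def to_dict(self) -> dict:
        return {
            "accuracy_hard": self.accuracy_hard,
            "accuracy_soft": self.accuracy_soft,
            "f1_hard": self.f1_hard,
            "f1_soft": self.f1_soft,
            "confusion_hard": self.confusion_hard.tolist(),
            "confusion_soft": self.confusion_soft.tolist(),
            "auc": self.auc,
            "auc_ci": {k: list(v) for k, v in self.auc_ci.items()},
            "importance": [[n, v] for n, v in self.importance],
        }


def feature_name(word: tuple[int, ...], channel_names: Sequence[str] = CHANNEL_NAMES) -> str:
    """Human-readable name of a Lyndon-word feature, in the reporting idiom."""
    names = [channel_names[i - 1] for i in word]
    if len(word) == 1:
        return f"Incremental effects of {names[0]}"
    if len(word) == 2:
        return f"Interaction between {names[0]} and {names[1]}"
    return "Interaction among " + ", ".join(names[:-1]) + f" and {names[-1]}"


def extract_mrlsf(windows: Sequence[PreparedWindow], p: int = 3) -> WindowSet:
    """Level-``p`` log-signature features for every prepared window."""
    if not windows:
        raise ValueError("no windows to extract features from")
    d = windows[0].path.shape[1]
    if any(w.path.shape[1] != d for w in windows):
        raise ValueError("windows must share the channel count")
    basis = lyndon_words(d, p)
    F = witt_dimension(d, p)
    features = np.empty((len(windows), F))
    for i, w in enumerate(windows):
        features[i] = logsig(w.path, p).coords
    names = [feature_name(word) for word in basis.words]
    return WindowSet(
        features=features,
        window_participant=np.array([w.participant_id for w in windows]),
        labels=np.array([w.diagnosis for w in windows]),
        feature_names=names,
        basis=basis,
    )


def make_folds(
    participants: Sequence[str],
    labels: Sequence[str],
    k: int = 3,
    seed: int = 0,
) -> FoldAssignment:
    """Stratified participant-level fold assignment (deterministic per seed)."""
    participants = np.asarray(participants)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} participants")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(participants, labels)):
        for i in test_idx:
            fold_of[str(participants[i])] = fold
    return FoldAssignment(fold_of_participant=fold_of, k=k, seed=seed)


def vote_hard(window_probs: np.ndarray, classes: Sequence[str] = CLASSES) -> str:
    """Majority vote over window argmax labels; ties fall back to soft voting."""
    probs = np.atleast_2d(window_probs)
    votes = np.bincount(np.argmax(probs, axis=1), minlength=len(classes))
    winners = np.flatnonzero(votes == votes.max())
    if len(winners) == 1:
        return classes[winners[0]]
    soft_label, _ = vote_soft(probs, classes)
    return soft_label


def vote_soft(
    window_probs: np.ndarray, classes: Sequence[str] = CLASSES
) -> tuple[str, np.ndarray]:
    """Label by argmax of summed window probabilities; exact ties go to the
    lowest class index in the fixed (BD, HC, BPD) order."""
    probs = np.atleast_2d(window_probs)
    sums = probs.sum(axis=0)
    soft_prob = sums / probs.shape[0]
    return classes[int(np.argmax(sums))], soft_prob


def fit_predict_cv(
    windowset: WindowSet,
    folds: FoldAssignment,
    rf_config: RFConfig = RFConfig(),
) -> tuple[dict[str, ParticipantPrediction], list[RandomForestClassifier]]:
    """Train per fold on all train-participant windows; predict hold-out windows.

    Every participant is held out exactly once and receives one prediction.
    Returns the per-participant predictions and the fitted fold models (for
    feature-importance reporting).
    """
    predictions: dict[str, ParticipantPrediction] = {}
    models: list[RandomForestClassifier] = []
    for fold in range(folds.k):
        test_parts = folds.test_participants(fold)
        test_mask = np.isin(windowset.window_participant, list(test_parts))
        train_mask = ~test_mask
        # leakage check is asserted, not assumed
        assert not (
            set(windowset.window_participant[train_mask])
            & set(windowset.window_participant[test_mask])
        )
        y_train = windowset.labels[train_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {fold} is degenerate (single class)")
        clf = rf_config.build()
        clf.fit(windowset.features[train_mask], y_train)
        models.append(clf)
        order = [list(clf.classes_).index(c) for c in CLASSES]
        probs = clf.predict_proba(windowset.features[test_mask])[:, order]
        test_pids = windowset.window_participant[test_mask]
        for pid in sorted(set(test_pids)):
            predictions[pid] = ParticipantPrediction(
                participant_id=pid, window_probs=probs[test_pids == pid]
            )
    return predictions, models


def _one_vs_rest_auc(
    y_true: np.ndarray, soft_probs: np.ndarray, cls_idx: int
) -> float:
    y_bin = (y_true == CLASSES[cls_idx]).astype(int)
    return float(roc_auc_score(y_bin, soft_probs[:, cls_idx]))


def evaluate(
    predictions: dict[str, ParticipantPrediction],
    true_labels: dict[str, str],
    models: Iterable[RandomForestClassifier] = (),
    feature_names: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Participant-level metrics under both voting schemes.

    AUC is one-vs-rest on the soft-vote probability vectors, with a percentile
    bootstrap (over participants) 95% confidence interval.
    """
    missing = set(true_labels) - set(predictions)
    if missing:
        raise ValueError(f"no prediction for participants: {sorted(missing)[:5]}")
    pids = sorted(true_labels)
    y_true = np.array([true_labels[p] for p in pids])
    y_hard = np.array([predictions[p].hard_label for p in pids])
    y_soft = np.array([predictions[p].soft_label for p in pids])
    soft_probs = np.array([predictions[p].soft_prob for p in pids])

    def per_class_f1(y_pred):
        vals = f1_score(y_true, y_pred, labels=list(CLASSES), average=None,
                        zero_division=0)
        return {c: float(v) for c, v in zip(CLASSES, vals)}

    auc, auc_ci = {}, {}
    rng = np.random.default_rng(seed)
    for ci, cls in enumerate(CLASSES):
        auc[cls] = _one_vs_rest_auc(y_true, soft_probs, ci)
        boots = []
        n = len(pids)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y_true[idx]
            if len(np.unique(yb == cls)) < 2:
                continue
            boots.append(_one_vs_rest_auc(yb, soft_probs[idx], ci))
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
        auc_ci[cls] = (float(lo), float(hi))

    importance = importance_report(list(models), list(feature_names)) if models else []

    return EvalReport(
        accuracy_hard=float(np.mean(y_hard == y_true)),
        accuracy_soft=float(np.mean(y_soft == y_true)),
        f1_hard=per_class_f1(y_hard),
        f1_soft=per_class_f1(y_soft),
        confusion_hard=confusion_matrix(y_true, y_hard, labels=list(CLASSES)),
        confusion_soft=confusion_matrix(y_true, y_soft, labels=list(CLASSES)),
        auc=auc,
        auc_ci=auc_ci,
        importance=importance,
    )


def importance_report(
    models: Sequence[RandomForestClassifier],
    feature_names: Sequence[str],
    top_n: Optional[int] = None,
) -> list[tuple[str, float]]:
    """Fold-averaged, normalised feature importances, ranked descending."""
    if not models:
        raise ValueError("no fitted models supplied")
    imp = np.mean([m.feature_importances_ for m in models], axis=0)
    imp = imp / imp.sum()
    order = np.argsort(imp)[::-1]
    ranked = [(feature_names[i], float(imp[i])) for i in order]
    return ranked[:top_n] if top_n else ranked


def roc_points(
    predictions: dict[str, ParticipantPrediction],
    true_labels: dict[str, str],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One-vs-rest ROC curves (fpr, tpr) per class from soft-vote probabilities."""
    pids = sorted(true_labels)
    y_true = np.array([true_labels[p] for p in pids])
    soft_probs = np.array([predictions[p].soft_prob for p in pids])
    curves = {}
    for ci, cls in enumerate(CLASSES):
        fpr, tpr, _ = roc_curve((y_true == cls).astype(int), soft_probs[:, ci])
        curves[cls] = (fpr, tpr)
    return curves


# ---------------------------------------------------------------------------
# Cohort summaries

#: Clinical cutoffs: ASRM > 5 manic episode, QIDS > 10 moderate-severe
#: depression, GAD-7 > 10 moderate-severe anxiety.
CUTOFFS = {"asrm": 5.0, "qids": 10.0, "gad7": 10.0}


def cohort_summary(streams: Sequence[MoodStream]) -> dict:
    """Per-group missingness and mean-score correlation summaries.

    For each diagnostic group: the median and interquartile range of
    per-participant missing proportions, the Pearson correlation matrix of
    per-participant mean scores (absent when the group has < 2 participants),
    and per-instrument proportions of weeks missing / below cutoff / above
    cutoff.
    """
    out: dict = {}
    for group in CLASSES:
        members = [s for s in streams if s.diagnosis == group]
        if not members:
            continue
        props = np.array([s.missing_mask.mean() for s in members])
        entry: dict = {
            "n": len(members),
            "missing_median": float(np.median(props)),
            "missing_iqr": [float(q) for q in np.percentile(props, [25, 75])],
        }
        means = np.array([
            [s.scores[:, c][s.scores[:, c] != s.sentinel].mean()
             if np.any(s.scores[:, c] != s.sentinel) else np.nan
             for c in range(s.scores.shape[1])]
            for s in members
        ])
        if len(members) >= 2:
            entry["mean_score_correlation"] = np.corrcoef(means.T).tolist()
        else:
            entry["mean_score_correlation"] = None
            logger.warning("group %s has < 2 participants; correlations absent", group)
        per_instrument = {}
        for c, name in enumerate(INSTRUMENTS):
            cols = np.concatenate([s.scores[:, c] for s in members])
            missing = cols == -1.0
            frac_missing = float(missing.mean())
            valid = cols[~missing]
            cutoff = CUTOFFS.get(name)
            if cutoff is not None and valid.size:
                above = float(np.mean(valid > cutoff)) * (1 - frac_missing)
                below = (1 - frac_missing) - above
            else:
                above, below = np.nan, np.nan
            per_instrument[name] = {
                "missing": frac_missing, "below_cutoff": below, "above_cutoff": above
            }
        entry["per_instrument"] = per_instrument
        out[group] = entry
    return out
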