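"""Comparison models: naive window means, and KNN / probabilistic-PCA imputation
feeding flattened ten-week windows, all under the same CV/voting harness.

The naive model scores each ten-week window by the per-instrument mean of the
valid (non-missing) responses — the clinic-style summary.  The imputation
models fill the missing weekly responses first (KNN on missing-aware Euclidean
distances; PPCA by expectation-maximisation) and then classify the flattened
10x4 window vectors.  Imputers are fit on the training fold's weekly rows and
applied to the hold-out rows, so no information leaks across the participant
split; a transductive switch reproduces the cohort-wide variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.impute import KNNImputer

from .encoding import CLASSES, MoodStream
from .pipeline import (
    EvalReport,
    FoldAssignment,
    ParticipantPrediction,
    RFConfig,
    evaluate,
    make_folds,
)
from .preprocess import WindowSpec

logger = logging.getLogger(__name__)

__all__ = [
    "naive_features",
    "knn_impute",
    "PPCA",
    "ppca_impute",
    "flatten_features",
    "run_baseline",
]


def naive_features(
    window: np.ndarray, full_stream: Optional[np.ndarray] = None, sentinel: float = -1.0
) -> np.ndarray:
    """Per-channel mean of valid scores in a raw window (clinic-style metric).

    A channel with no valid in-window value falls back to the participant's
    full-stream mean for that channel; if none exists anywhere, raises.
    """
    window = np.asarray(window, dtype=float)
    out = np.empty(window.shape[1])
    for c in range(window.shape[1]):
        col = window[:, c]
        valid = col[col != sentinel]
        if valid.size:
            out[c] = valid.mean()
            continue
        if full_stream is not None:
            fallback = full_stream[:, c][full_stream[:, c] != sentinel]
            if fallback.size:
                logger.debug("channel %d all-missing in window; full-stream mean used", c)
                out[c] = fallback.mean()
                continue
        raise ValueError(f"channel {c} has no valid value anywhere")
    return out


def _to_nan(X: np.ndarray, sentinel: float) -> np.ndarray:
    X = np.asarray(X, dtype=float).copy()
    X[X == sentinel] = np.nan
    return X


def knn_impute(
    X: np.ndarray,
    K: int = 5,
    train: Optional[np.ndarray] = None,
    sentinel: float = -1.0,
) -> np.ndarray:
    """Impute missing weekly observations from their K nearest neighbours.

    Distances between weekly rows are missing-aware Euclidean (computed on
    mutually observed channels and rescaled by the observed fraction); each
    missing entry is the mean of the variable over the K nearest rows where it
    is observed.  When ``train`` is given, neighbours are drawn from the
    training rows only.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Xn = _to_nan(X, sentinel)
    fit_rows = _to_nan(train, sentinel) if train is not None else Xn
    imputer = KNNImputer(n_neighbors=K, weights="uniform")
    imputer.fit(fit_rows)
    filled = imputer.transform(Xn)
    observed = ~np.isnan(Xn)
    filled[observed] = Xn[observed]
    return filled


class PPCA:
    """Probabilistic PCA with missing data, fit by expectation-maximisation.

    Model: ``x = W z + mu + eps`` with ``z ~ N(0, I_q)`` and isotropic noise
    ``eps ~ N(0, sigma2 I)``.  Missing coordinates are treated as latent along
    with ``z``; the E-step computes their posterior expectations given the
    observed coordinates, and the conditional M-steps update ``mu``, ``W`` and
    ``sigma2`` in turn, so the observed-data log-likelihood never decreases.
    Observed entries are never altered by :meth:`transform`.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6,
                 max_iter: int = 500, seed: int = 0):
        self.q = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.converged_: bool = False
        self.loglik_path_: list[float] = []

    # -- internals ---------------------------------------------------------

    def _e_step_row(self, x: np.ndarray, obs: np.ndarray):
        """Posterior moments of (z, x_missing) for one row."""
        Wo = self.W_[obs]
        M = Wo.T @ Wo + self.sigma2_ * np.eye(self.q)
        Minv = np.linalg.inv(M)
        Ez = Minv @ Wo.T @ (x[obs] - self.mu_[obs])
        Czz = self.sigma2_ * Minv
        return Ez, Czz

    def _observed_loglik(self, X: np.ndarray, observed: np.ndarray) -> float:
        total = 0.0
        for i in range(X.shape[0]):
            obs = observed[i]
            if not obs.any():
                continue
            Wo = self.W_[obs]
            C = Wo @ Wo.T + self.sigma2_ * np.eye(int(obs.sum()))
            dev = X[i, obs] - self.mu_[obs]
            sign, logdet = np.linalg.slogdet(C)
            total += -0.5 * (
                obs.sum() * np.log(2 * np.pi) + logdet + dev @ np.linalg.solve(C, dev)
            )
        return float(total)

    def fit(self, X: np.ndarray) -> "PPCA":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if self.q >= d:
            raise ValueError("n_components must be smaller than the variable count")
        observed = ~np.isnan(X)
        if not observed.any(axis=0).all():
            raise ValueError("every variable must be observed somewhere")
        rng = np.random.default_rng(self.seed)
        col_mean = np.nanmean(X, axis=0)
        self.mu_ = col_mean.copy()
        self.W_ = rng.normal(scale=0.1, size=(d, self.q))
        self.sigma2_ = float(np.nanvar(X)) or 1.0
        self.converged_ = False
        self.loglik_path_ = [self._observed_loglik(X, observed)]

        prev_fill = None
        for _ in range(self.max_iter):
            # E-step: per-row posterior moments.
            Ez = np.empty((n, self.q))
            Czz = np.empty((n, self.q, self.q))
            Ex = X.copy()
            for i in range(n):
                obs = observed[i]
                ez, czz = self._e_step_row(X[i], obs)
                Ez[i], Czz[i] = ez, czz
                mis = ~obs
                if mis.any():
                    Ex[i, mis] = self.W_[mis] @ ez + self.mu_[mis]
            # CM-step 1: mu from expected complete data.
            self.mu_ = (Ex - Ez @ self.W_.T).mean(axis=0)
            Xc = Ex - self.mu_
            # CM-step 2: W from expected sufficient statistics.
            W_old = self.W_
            Szz = Czz.sum(axis=0) + Ez.T @ Ez
            Sxz = Xc.T @ Ez
            for i in range(n):  # add Cov(x_m, z) = W_m Czz for missing coords
                mis = ~observed[i]
                if mis.any():
                    Sxz[mis] += W_old[mis] @ Czz[i]
            self.W_ = np.linalg.solve(Szz.T, Sxz.T).T
            # CM-step 3: sigma2 = (1/nd) Σ_i E[||x_i − mu − W z_i||²] under the
            # fixed E-step posterior; missing coordinates contribute their
            # posterior variance and the z cross-covariance terms.
            total = 0.0
            for i in range(n):
                mis = ~observed[i]
                resid = Xc[i] - self.W_ @ Ez[i]
                total += resid @ resid
                total += np.trace(self.W_ @ Czz[i] @ self.W_.T)
                if mis.any():
                    total += mis.sum() * self.sigma2_
                    total += np.trace(W_old[mis] @ Czz[i] @ W_old[mis].T)
                    total -= 2.0 * np.trace(
                        self.W_[mis] @ Czz[i] @ W_old[mis].T
                    )
            self.sigma2_ = max(float(total) / (n * d), 1e-12)

            self.loglik_path_.append(self._observed_loglik(X, observed))
            fill = Ex[~observed] if (~observed).any() else Xc.ravel()
            if prev_fill is not None:
                denom = np.abs(prev_fill).max() or 1.0
                if np.abs(fill - prev_fill).max() / denom < self.tol:
                    self.converged_ = True
                    break
            prev_fill = fill.copy()
        else:
            self.converged_ = abs(
                self.loglik_path_[-1] - self.loglik_path_[-2]
            ) < self.tol * max(1.0, abs(self.loglik_path_[-1]))
            if not self.converged_:
                logger.warning("PPCA EM did not converge in %d iterations", self.max_iter)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Fill missing entries with their posterior means; observed untouched."""
        X = np.asarray(X, dtype=float)
        out = X.copy()
        for i in range(X.shape[0]):
            obs = ~np.isnan(X[i])
            mis = ~obs
            if not mis.any():
                continue
            if not obs.any():
                out[i, mis] = self.mu_[mis]
                continue
            Ez, _ = self._e_step_row(np.nan_to_num(X[i]), obs)
            out[i, mis] = self.W_[mis] @ Ez + self.mu_[mis]
        return out


def ppca_impute(
    X: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    train: Optional[np.ndarray] = None,
    sentinel: float = -1.0,
) -> tuple[np.ndarray, bool]:
    """PPCA-EM imputation of a weekly observation matrix.

    Returns ``(filled, converged)``.  With ``train`` given, the model is fit on
    the training rows only and applied to ``X``.
    """
    Xn = _to_nan(X, sentinel)
    fit_rows = _to_nan(train, sentinel) if train is not None else Xn
    if not np.isnan(fit_rows).any() and not np.isnan(Xn).any():
        return Xn, True  # nothing to impute
    model = PPCA(n_components=n_components, tol=tol, max_iter=max_iter).fit(fit_rows)
    return model.transform(Xn), model.converged_


def flatten_features(window: np.ndarray) -> np.ndarray:
    """Row-major flattening of an imputed (width, C) window: entry ``C*t + c``
    is week ``t``, channel ``c``."""
    return np.asarray(window, dtype=float).ravel(order="C")


# ---------------------------------------------------------------------------
# Harness


def _window_starts(W: int, spec: WindowSpec) -> range:
    return range(0, W - spec.width + 1, spec.stride)


def _baseline_feature_rows(
    streams: Sequence[MoodStream],
    spec: WindowSpec,
    method: str,
    knn_k: int,
    ppca_components: int,
    train_pids: Optional[set] = None,
    imputed_scores: Optional[dict[str, np.ndarray]] = None,
):
    """Window feature matrix + bookkeeping for one baseline method."""
    feats, pids, labels = [], [], []
    if method in ("knn", "ppca") and imputed_scores is None:
        all_rows = np.vstack([s.scores for s in streams])
        train_rows = (
            np.vstack([s.scores for s in streams if s.participant_id in train_pids])
            if train_pids is not None else None
        )
        if method == "knn":
            filled_all = knn_impute(all_rows, K=knn_k, train=train_rows)
        else:
            filled_all, _ = ppca_impute(
                all_rows, n_components=ppca_components, train=train_rows
            )
        imputed_scores = {}
        offset = 0
        for s in streams:
            imputed_scores[s.participant_id] = filled_all[offset:offset + s.n_weeks]
            offset += s.n_weeks
    for s in streams:
        starts = _window_starts(s.n_weeks, spec)
        for start in starts:
            if method == "naive":
                row = naive_features(
                    s.scores[start:start + spec.width], full_stream=s.scores
                )
            elif method in ("knn", "ppca", "external"):
                row = flatten_features(
                    imputed_scores[s.participant_id][start:start + spec.width]
                )
            else:
                raise ValueError(f"unknown baseline method {method!r}")
            feats.append(row)
            pids.append(s.participant_id)
            labels.append(s.diagnosis)
    return np.array(feats), np.array(pids), np.array(labels)


def run_baseline(
    streams: Sequence[MoodStream],
    method: str,
    folds: Optional[FoldAssignment] = None,
    spec: WindowSpec = WindowSpec(),
    rf_config: RFConfig = RFConfig(),
    knn_k: int = 5,
    ppca_components: int = 2,
    transductive: bool = False,
    imputed_streams: Optional[Sequence[MoodStream]] = None,
    seed: int = 0,
    n_boot: int = 1000,
) -> tuple[EvalReport, dict[str, ParticipantPrediction]]:
    """Run a comparison model under the same folds/classifier/voting harness.

    ``method`` is one of ``naive``, ``knn``, ``ppca`` or ``external`` (the last
    consumes a pre-imputed, sentinel-free cohort via ``imputed_streams``, which
    is how external multiple-imputation pipelines plug in).  With
    ``transductive=True`` the imputer sees the whole cohort at once; the
    default refits it within each training fold.
    """
    if method not in ("naive", "knn", "ppca", "external"):
        raise ValueError(f"unknown baseline method {method!r}")
    streams = [s for s in streams if s.n_weeks >= spec.width]
    participants = [s.participant_id for s in streams]
    labels = {s.participant_id: s.diagnosis for s in streams}
    if folds is None:
        folds = make_folds(participants, [labels[p] for p in participants], seed=seed)

    external_scores = None
    if method == "external":
        if imputed_streams is None:
            raise ValueError("external method requires imputed_streams")
        external_scores = {s.participant_id: s.scores for s in imputed_streams}
        if any((v == -1.0).any() for v in external_scores.values()):
            raise ValueError("externally imputed cohort still contains sentinels")

    predictions: dict[str, ParticipantPrediction] = {}
    models = []
    from .pipeline import CLASSES as _CLASSES  # fixed class order

    for fold in range(folds.k):
        test_parts = folds.test_participants(fold)
        train_parts = set(participants) - test_parts
        train_pids = None if (transductive or method in ("naive", "external")) \
            else train_parts
        X, pids, y = _baseline_feature_rows(
            streams, spec, method, knn_k, ppca_components,
            train_pids=train_pids, imputed_scores=external_scores,
        )
        test_mask = np.isin(pids, list(test_parts))
        clf = rf_config.build()
        clf.fit(X[~test_mask], y[~test_mask])
        models.append(clf)
        order = [list(clf.classes_).index(c) for c in _CLASSES]
        probs = clf.predict_proba(X[test_mask])[:, order]
        test_pids = pids[test_mask]
        for pid in sorted(set(test_pids)):
            predictions[pid] = ParticipantPrediction(
                participant_id=pid, window_probs=probs[test_pids == pid]
            )
    report = evaluate(predictions, labels, models=models,
                      feature_names=[f"x{i}" for i in range(X.shape[1])],
                      seed=seed, n_boot=n_boot)
    return report, predictions
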