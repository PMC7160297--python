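"""Leave-pair-out cross-validation, subject scoring, metrics and IPW.

Subjects are classified by averaging their held-out frame probabilities and
thresholding at 50% (ties go to the negative class, HC).  ADHD is the
positive class everywhere, which fixes the orientation of the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats

from .ersp import FrameSet
from .nets import TrainConfig, build_model, predict_frames, standardize, train
from .synth import ParameterError, SubjectRecord

__all__ = [
    "FoldPlan", "FoldResult", "PerformanceSummary", "IpwWeights",
    "lpocv_folds", "score_subject", "auc_wmw", "fit_propensity",
    "run_lpocv", "compare_models", "POSITIVE_CLASS",
]

POSITIVE_CLASS = "ADHD"
PROPENSITY_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    held_out: tuple[str, str]  # (ADHD subject, HC subject)
    train_ids: tuple[str, ...]


@dataclass
class FoldResult:
    fold_id: int
    held_out: tuple[str, str]
    frame_probs: dict[str, np.ndarray]  # subject -> per-frame P(ADHD)
    subject_scores: dict[str, float]
    subject_preds: dict[str, str]
    accuracy: float  # fraction of the held-out pair classified correctly
    pair_auc: float  # WMW AUC over the held-out pair, in {0, 0.5, 1}


@dataclass
class PerformanceSummary:
    architecture: str
    n_folds: int
    accuracy_pct: float
    accuracy_sd_pct: float
    auc_pct: float
    auc_sd_pct: float
    pooled_auc_pct: float
    channels: tuple[str, ...] | None = None
    ipw: bool = False

    def as_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "n_folds": self.n_folds,
            "accuracy_pct": self.accuracy_pct,
            "accuracy_sd_pct": self.accuracy_sd_pct,
            "auc_pct": self.auc_pct,
            "auc_sd_pct": self.auc_sd_pct,
            "pooled_auc_pct": self.pooled_auc_pct,
            "channels": list(self.channels) if self.channels else None,
            "ipw": self.ipw,
        }


@dataclass
class IpwWeights:
    subject_ids: tuple[str, ...]
    propensity: np.ndarray  # P(ADHD | age), clipped
    weights: np.ndarray  # 1/p for ADHD, 1/(1-p) for HC

    def weight_of(self, subject_id: str) -> float:
        return float(self.weights[self.subject_ids.index(subject_id)])


def lpocv_folds(subjects: Sequence[SubjectRecord]) -> list[FoldPlan]:
    """All (ADHD, HC) pairs as held-out test sets, deterministically ordered."""
    adhd = sorted(s.subject_id for s in subjects if s.group == POSITIVE_CLASS)
    hc = sorted(s.subject_id for s in subjects if s.group == "HC")
    if not adhd or not hc:
        raise ParameterError("both classes must be present for LPOCV")
    all_ids = set(adhd) | set(hc)
    plans = []
    for k, (a, h) in enumerate(product(adhd, hc)):
        train_ids = tuple(sorted(all_ids - {a, h}))
        plans.append(FoldPlan(fold_id=k, held_out=(a, h), train_ids=train_ids))
    return plans


def score_subject(frame_probs: Sequence[float]) -> tuple[float, str]:
    """Mean frame probability; ADHD iff score > 0.5 (ties -> HC)."""
    probs = np.asarray(frame_probs, dtype=float)
    if probs.size == 0:
        raise ParameterError("no frame probabilities to score")
    score = float(probs.mean())
    return score, (POSITIVE_CLASS if score > 0.5 else "HC")


def auc_wmw(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC via the Wilcoxon-Mann-Whitney statistic (rank formulation).

    Equals (#concordant pairs + 0.5 #ties) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fit_propensity(ages: Sequence[float], labels: Sequence[str]) -> IpwWeights:
    """Single-covariate logistic propensity P(ADHD | age) and IPW weights.

    Propensities are clipped to [0.05, 0.95] before inversion so that
    near-separation cannot produce unbounded weights.
    """
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels)
    y = (labels == POSITIVE_CLASS).astype(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ParameterError("propensity fit requires both classes")
    design = sm.add_constant(ages)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        p = np.asarray(fit.predict(design))
    except Exception:  # perfect separation and friends
        warnings.warn("propensity fit failed to converge cleanly; "
                      "falling back to a ridge-regularized fit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit_regularized(alpha=1e-4, disp=0)
            p = np.asarray(fit.predict(design))
    lo, hi = PROPENSITY_CLIP
    clipped = np.clip(p, lo, hi)
    if np.any(p != clipped):
        warnings.warn("propensity scores clipped to avoid extreme weights")
    weights = np.where(y == 1, 1.0 / clipped, 1.0 / (1.0 - clipped))
    sid = tuple(f"s{i}" for i in range(len(ages)))
    return IpwWeights(subject_ids=sid, propensity=clipped, weights=weights)


def _frame_weights(frames: FrameSet, subjects: Sequence[SubjectRecord]
                   ) -> np.ndarray:
    """Per-frame IPW weights: subject weight replicated over the subject's
    frames, then normalized to mean 1 within the training set."""
    subjects = list(subjects)
    ipw = fit_propensity([s.age for s in subjects], [s.group for s in subjects])
    by_id = {s.subject_id: float(w)
             for s, w in zip(subjects, ipw.weights)}
    w = np.array([by_id[sid] for sid in frames.subject_ids], dtype=float)
    return w / w.mean()


def _fold_seed(base_seed: int, fold_id: int) -> int:
    return int(np.random.SeedSequence((base_seed, fold_id)).generate_state(1)[0])


def run_lpocv(frames: FrameSet, subjects: Sequence[SubjectRecord],
              architecture: str = "cnn",
              train_config: TrainConfig = TrainConfig(),
              ipw: bool = False,
              channel_subset: Sequence[str] | None = None,
              keep_models: bool = False,
              ) -> tuple[PerformanceSummary, list[FoldResult]]:
    """Train/evaluate one model per leave-pair-out fold.

    Per fold a fresh network is trained on every frame of the non-held-out
    subjects (z-scored with training statistics only, IPW loss weights when
    requested) and the held-out pair is scored by frame-probability
    averaging.  ACC is the percentage of held-out subjects classified
    correctly; the pair AUC is averaged across folds, and a pooled AUC over
    all held-out subject scores is reported alongside.
    """
    subjects = list(subjects)
    by_id = {s.subject_id: s for s in subjects}
    if channel_subset is not None:
        unknown = set(channel_subset) - set(frames.channel_names)
        if unknown:
            raise ParameterError(f"unknown channels {sorted(unknown)}")
        frames = frames.select_channels(list(channel_subset))
    have = set(np.unique(frames.subject_ids))
    missing = {s.subject_id for s in subjects} - have
    if missing:
        raise ParameterError(f"no frames for subjects {sorted(missing)}")

    plans = lpocv_folds(subjects)
    results: list[FoldResult] = []
    models = []
    pooled_scores: list[float] = []
    pooled_labels: list[str] = []
    y_all = (frames.labels == POSITIVE_CLASS).astype(np.int64)

    for plan in plans:
        train_mask = np.isin(frames.subject_ids, plan.train_ids)
        x_train = frames.frames[train_mask]
        y_train = y_all[train_mask]
        weights = None
        if ipw:
            sub_frames = frames.subset_subjects(plan.train_ids)
            weights = _frame_weights(
                sub_frames, [by_id[i] for i in plan.train_ids])
            # subset_subjects preserves frame order of the mask selection
        fold_seed = _fold_seed(train_config.seed, plan.fold_id)
        model = build_model(architecture, n_channels=frames.frames.shape[-1],
                            seed=fold_seed)
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            beta1=train_config.beta1, beta2=train_config.beta2,
            eps=train_config.eps, batch_size=train_config.batch_size,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience,
            min_delta=train_config.min_delta, seed=fold_seed)

        x_test = frames.frames[~train_mask]
        x_train_std, x_test_std, _ = standardize(x_train, x_test)
        train(model, x_train_std, y_train, weights, cfg)

        test_ids = frames.subject_ids[~train_mask]
        probs = predict_frames(model, x_test_std)[:, 1]
        frame_probs, scores, preds = {}, {}, {}
        n_correct = 0
        for sid in plan.held_out:
            p = probs[test_ids == sid]
            frame_probs[sid] = p
            scores[sid], preds[sid] = score_subject(p)
            if preds[sid] == by_id[sid].group:
                n_correct += 1
        pair_auc = auc_wmw([scores[s] for s in plan.held_out],
                           [by_id[s].group for s in plan.held_out])
        results.append(FoldResult(
            fold_id=plan.fold_id, held_out=plan.held_out,
            frame_probs=frame_probs, subject_scores=scores,
            subject_preds=preds, accuracy=n_correct / 2.0, pair_auc=pair_auc))
        pooled_scores.extend(scores[s] for s in plan.held_out)
        pooled_labels.extend(by_id[s].group for s in plan.held_out)
        if keep_models:
            models.append(model)

    acc = np.array([r.accuracy for r in results])
    aucs = np.array([r.pair_auc for r in results])
    summary = PerformanceSummary(
        architecture=architecture,
        n_folds=len(results),
        accuracy_pct=float(acc.mean() * 100.0),
        accuracy_sd_pct=float(acc.std(ddof=1) * 100.0) if len(acc) > 1 else 0.0,
        auc_pct=float(aucs.mean() * 100.0),
        auc_sd_pct=float(aucs.std(ddof=1) * 100.0) if len(aucs) > 1 else 0.0,
        pooled_auc_pct=float(auc_wmw(pooled_scores, pooled_labels) * 100.0),
        channels=tuple(channel_subset) if channel_subset is not None else None,
        ipw=ipw,
    )
    if keep_models:
        summary.models = models  # type: ignore[attr-defined]
    return summary, results


def compare_models(acc_folds_a: Sequence[float],
                   acc_folds_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample t-test on per-fold performance vectors.

    Degenerate zero-variance cases are resolved explicitly: identical
    constant vectors give (0, 1); a constant shift gives (+/-inf, 0).
    """
    a = np.asarray(acc_folds_a, dtype=float)
    b = np.asarray(acc_folds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least two folds per model")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
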