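"""Group-level searchlight decoding with permuted baselines and the
5x2 cross-validation F-test.

Samples are the ideation-window volumes of every subject's trials of the two
conditions, concatenated at the group level; folds and label permutations
operate on whole trials (a story's volumes never straddle the train/test
boundary or change label independently).  Classification uses an RBF-kernel
SVM (C = 1); regression uses ordinary least squares.  Performance is the
mean cross-validated score minus the mean score under permuted labels (or a
permuted target).

Two p-values are reported per unit: ``p_f`` from the 5x2 cv F-test against
the permuted baseline, referred to F(10, 5), and ``p`` — an exact
permutation p of the mean cross-validated score against the per-permutation
scores, which is the calibrated quantity (the F(10, 5) reference does not
account for the dataset-conditional chance decodability shared by all
folds) and is the one FDR is applied to.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVC

from .dataset import RoiTimeSeriesDataset, ValidationError
from .stats_report import fdr_bh

logger = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "PerfMap", "assemble_samples",
           "group_searchlight_classify", "group_searchlight_regress",
           "five_by_two_cv_ftest"]


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    n_label_permutations: int = 100
    n_repeats: int = 5
    n_folds: int = 2
    seed: int = 0
    baseline_scheme: str = "pooled"   # or "per_permutation"
    min_features: int = 1

    def __post_init__(self) -> None:
        if self.n_folds != 2 or self.n_repeats < 1:
            raise ValidationError("the 5x2 scheme requires exactly 2 folds")
        if self.baseline_scheme not in ("pooled", "per_permutation"):
            raise ValidationError(f"unknown baseline scheme {self.baseline_scheme!r}")


@dataclass
class PerfMap:
    """Per-unit decoding performance with 5x2 F-test inference."""

    table: pd.DataFrame   # unit, score, baseline, performance, F, p_f, p, q01, q05
    kind: str             # "classification" | "regression"
    skipped_units: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def mean_score(self) -> float:
        return float(self.table["score"].mean())


def five_by_two_cv_ftest(real_scores: np.ndarray, baseline_scores: np.ndarray
                         ) -> tuple[float, float]:
    """5x2 cv F-test between paired fold scores of two procedures.

    With per-fold differences p_i^(j) and per-repetition variances
    s_i^2 = (p_i^(1) - pbar_i)^2 + (p_i^(2) - pbar_i)^2, the statistic is
    F = (sum_ij p_i^(j)^2) / (2 sum_i s_i^2), referred to F(10, 5).
    Zero-variance differences are degenerate: returns (nan, 1.0) with a
    warning.
    """
    real = np.asarray(real_scores, float)
    base = np.asarray(baseline_scores, float)
    if real.shape != (5, 2) or base.shape != (5, 2):
        raise ValidationError("expected 5x2 fold-score arrays")
    diff = real - base
    pbar = diff.mean(axis=1, keepdims=True)
    s2 = ((diff - pbar) ** 2).sum(axis=1)
    denom = 2 * s2.sum()
    if denom == 0:
        warnings.warn("degenerate 5x2 F-test: zero variance of fold "
                      "differences; p reported as 1", stacklevel=2)
        return float("nan"), 1.0
    F = float((diff ** 2).sum() / denom)
    p = float(stats.f.sf(F, 10, 5))
    return F, p


# ---------------------------------------------------------------------------
# Sample assembly and trial-level folding
# ---------------------------------------------------------------------------

def assemble_samples(dataset: RoiTimeSeriesDataset, conditions: list[int]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack ideation volumes of the given conditions across subjects.

    Returns (X, labels, trial_ids): X is (n_samples, n_rois); labels index
    into ``conditions``; trial_ids identify the (subject, condition, trial)
    a volume belongs to.
    """
    d = dataset.design
    xs, ys, gs = [], [], []
    gid = 0
    for s in range(d.n_subjects):
        for yi, c in enumerate(conditions):
            for t in range(d.trials_per_condition):
                block = dataset.values[s, c, t]
                xs.append(block)
                ys.append(np.full(block.shape[0], yi))
                gs.append(np.full(block.shape[0], gid))
                gid += 1
    return np.vstack(xs), np.concatenate(ys), np.concatenate(gs)


def _trial_folds(trial_labels: np.ndarray, n_repeats: int,
                 rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified 50% trial splits: one (fold0_trials, fold1_trials) per repeat."""
    trials = np.arange(len(trial_labels))
    folds = []
    for _ in range(n_repeats):
        fold0, fold1 = [], []
        for lab in np.unique(trial_labels):
            members = trials[trial_labels == lab]
            perm = rng.permutation(members)
            half = len(perm) // 2
            fold0.extend(perm[:half])
            fold1.extend(perm[half:])
        folds.append((np.array(sorted(fold0)), np.array(sorted(fold1))))
    return folds


def _zscore_train(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _cv_scores(X: np.ndarray, trial_targets_per_rep: np.ndarray,
               groups: np.ndarray, folds, model_factory, scorer) -> np.ndarray:
    """(n_repeats, 2) cross-validated scores splitting by trial.

    ``trial_targets_per_rep`` is (n_repeats, n_trials): the per-trial target
    used in each repetition (identical rows for the real analysis, within-
    fold permuted rows for the baseline).
    """
    scores = np.empty((len(folds), 2))
    for r, (f0, f1) in enumerate(folds):
        sample_targets = trial_targets_per_rep[r][groups]
        for j, (train_trials, test_trials) in enumerate([(f0, f1), (f1, f0)]):
            tr = np.isin(groups, train_trials)
            te = np.isin(groups, test_trials)
            Xtr, Xte = _zscore_train(X[tr], X[te])
            model = model_factory()
            model.fit(Xtr, sample_targets[tr])
            scores[r, j] = scorer(model, Xte, sample_targets[te])
    return scores


def _default_units(dataset: RoiTimeSeriesDataset) -> dict[str, list[int]]:
    return {lab: [i] for i, lab in enumerate(dataset.roi_labels)}


def _run_searchlight(dataset, X, groups, trial_targets, units, config,
                     model_factory, scorer, kind) -> PerfMap:
    rng = np.random.default_rng(config.seed)
    trial_targets = np.asarray(trial_targets)
    n_trials = len(trial_targets)

    def _strata(targets):
        if kind == "classification":
            return targets
        # median split by rank: balances the target spread across folds
        ranks = np.argsort(np.argsort(targets))
        return (2 * ranks >= n_trials).astype(int)

    folds = _trial_folds(_strata(trial_targets), config.n_repeats, rng)
    real_targets = np.tile(trial_targets, (config.n_repeats, 1))
    # Each baseline draw permutes whole-trial labels globally and re-derives
    # its own stratified folds from the permuted labels — a full rerun of
    # the procedure on an exchangeable relabelling, shared across units for
    # comparability.
    baselines = []
    for _ in range(config.n_label_permutations):
        permuted = trial_targets[rng.permutation(n_trials)]
        b_folds = _trial_folds(_strata(permuted), config.n_repeats, rng)
        baselines.append((np.tile(permuted, (config.n_repeats, 1)), b_folds))

    units = units or _default_units(dataset)
    rows, skipped = [], []
    for name, cols in units.items():
        cols = list(cols)
        if len(cols) < config.min_features:
            logger.info("unit %s skipped: %d feature(s)", name, len(cols))
            skipped.append(name)
            continue
        Xu = X[:, cols]
        real = _cv_scores(Xu, real_targets, groups, folds, model_factory, scorer)
        n_perm = config.n_label_permutations
        if n_perm:
            base_stack = np.empty((n_perm, config.n_repeats, 2))
            for b, (b_targets, b_folds) in enumerate(baselines):
                base_stack[b] = _cv_scores(Xu, b_targets, groups, b_folds,
                                           model_factory, scorer)
            base_mean = base_stack.mean(axis=0)
            if config.baseline_scheme == "pooled":
                F, p_f = five_by_two_cv_ftest(real, base_mean)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fps = [five_by_two_cv_ftest(real, base_stack[b])
                           for b in range(n_perm)]
                F = float(np.nanmean([f for f, _ in fps]))
                p_f = float(np.mean([pv for _, pv in fps]))
            baseline = float(base_mean.mean())
            # exact permutation p on the mean CV score: real labels and the
            # within-fold permuted labels are exchangeable under the null
            perm_scores = base_stack.mean(axis=(1, 2))
            p_perm = float((1 + (perm_scores >= real.mean()).sum()) / (1 + n_perm))
        else:
            baseline, F, p_f, p_perm = np.nan, np.nan, np.nan, np.nan
        rows.append({"unit": name, "score": float(real.mean()),
                     "baseline": baseline,
                     "performance": float(real.mean()) - (baseline if n_perm else 0.0),
                     "F": F, "p_f": p_f, "p": p_perm})
    if not rows:
        raise ValidationError("no unit had enough features to analyse")
    table = pd.DataFrame(rows)
    if config.n_label_permutations and table["p"].notna().all():
        table["q01"] = fdr_bh(table["p"].to_numpy(), alpha=0.01)[0]
        table["q05"] = fdr_bh(table["p"].to_numpy(), alpha=0.05)[0]
    return PerfMap(table=table, kind=kind, skipped_units=skipped)


def group_searchlight_classify(dataset: RoiTimeSeriesDataset,
                               cond_a: int | str, cond_b: int | str,
                               units: dict[str, list[int]] | None = None,
                               config: ClassifierConfig | None = None) -> PerfMap:
    """Binary RBF-SVM searchlight between two conditions at the group level.

    Per unit: mean accuracy over the 5x2 folds, the permuted-label baseline
    accuracy, their difference (performance), and the 5x2 cv F-test p,
    FDR-corrected across units at alpha 0.01 and 0.05.
    """
    config = config or ClassifierConfig()
    labels = dataset.design.condition_labels
    ca = labels.index(cond_a) if isinstance(cond_a, str) else cond_a
    cb = labels.index(cond_b) if isinstance(cond_b, str) else cond_b
    X, y, groups = assemble_samples(dataset, [ca, cb])
    trial_labels = np.array([y[groups == g][0] for g in np.unique(groups)])

    factory = lambda: SVC(kernel=config.kernel, C=config.C)
    scorer = lambda model, Xte, yte: float((model.predict(Xte) == yte).mean())
    return _run_searchlight(dataset, X, groups, trial_labels, units, config,
                            factory, scorer, "classification")


def group_searchlight_regress(dataset: RoiTimeSeriesDataset,
                              condition: int | str,
                              target_feature: np.ndarray,
                              units: dict[str, list[int]] | None = None,
                              config: ClassifierConfig | None = None) -> PerfMap:
    """OLS searchlight regression of a per-trial behavioural feature.

    ``target_feature`` holds one scalar per (subject, trial) of the
    condition, ordered subject-major, and is broadcast to the trial's
    volumes.  Performance is cross-validated R^2 minus R^2 with the target
    permuted across trials; FDR across units at alpha 0.05.
    """
    config = config or ClassifierConfig()
    labels = dataset.design.condition_labels
    c = labels.index(condition) if isinstance(condition, str) else condition
    X, _, groups = assemble_samples(dataset, [c])
    target_feature = np.asarray(target_feature, float)
    n_trials = len(np.unique(groups))
    if target_feature.shape != (n_trials,):
        raise ValidationError(
            f"need one target value per trial ({n_trials}), got "
            f"{target_feature.shape}")
    if not np.all(np.isfinite(target_feature)):
        raise ValidationError("target feature must be finite")
    if np.ptp(target_feature) == 0:
        raise ValidationError("constant target: R^2 undefined")

    factory = LinearRegression

    def scorer(model, Xte, yte):
        pred = model.predict(Xte)
        ss_res = ((yte - pred) ** 2).sum()
        ss_tot = ((yte - yte.mean()) ** 2).sum()
        return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

    return _run_searchlight(dataset, X, groups, target_feature, units, config,
                            factory, scorer, "regression")
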