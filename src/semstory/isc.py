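"""Triplet-matched inter-subject correlation with circular-shift nulls.

For each ROI and target-word triplet, the Pearson correlation of the
ideation-window time course is computed between every pair of subjects who
were cued by that triplet in the given condition; the ROI's ISC is the mean
of the strictly-lower-triangle entries, averaged across triplets.  The null
distribution circularly shifts each subject's series by a random nonzero
offset and recomputes ISC (5000 iterations by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RoiTimeSeriesDataset, ValidationError
from .stats_report import fdr_bh

logger = logging.getLogger(__name__)

__all__ = ["IscResult", "compute_isc", "isc_permutation_null", "isc_contrast"]


@dataclass
class IscResult:
    condition: str
    isc: np.ndarray                      # (n_rois,) mean ISC
    per_triplet: dict[int, dict]         # triplet -> {subjects, corr (S,S,R), isc (R,)}
    roi_labels: list[str]
    p_values: np.ndarray | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_excluded_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"roi": self.roi_labels, "condition": self.condition,
                           "isc": self.isc})
        if self.p_values is not None:
            df["p"] = self.p_values
            df["q"] = fdr_bh(self.p_values)[0]
        return df


def _zscore(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score along the time axis; returns (z, zero-variance mask)."""
    mean = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    bad = sd[:, 0, :] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (series - mean) / sd, bad


def _pairwise_corr(z: np.ndarray) -> np.ndarray:
    """(S, T, R) z-scored series -> (S, S, R) Pearson correlation."""
    T = z.shape[1]
    return np.einsum("itr,jtr->ijr", z, z) / T


def _triplet_series(dataset: RoiTimeSeriesDataset, condition: int
                    ) -> dict[int, tuple[list[int], np.ndarray]]:
    """Map triplet id -> (subjects, (S, T, R) ideation series) for a condition."""
    d = dataset.design
    out = {}
    for trip in range(d.n_triplets):
        subjects = d.subjects_with_triplet(condition, trip)
        if len(subjects) < 2:
            continue
        trial = trip % d.trials_per_condition
        series = np.stack([dataset.values[s, condition, trial] for s in subjects])
        out[trip] = (subjects, series)
    return out


def _condition_index(dataset: RoiTimeSeriesDataset, condition: int | str) -> int:
    if isinstance(condition, str):
        return dataset.design.condition_labels.index(condition)
    return condition


def compute_isc(dataset: RoiTimeSeriesDataset, condition: int | str) -> IscResult:
    """Per-ROI triplet-matched ISC for one condition.

    The dataset's volume axis must already be the ideation window.  Pairs
    with a zero-variance series are excluded (logged); if every pair of a
    triplet is excluded for every ROI an error is raised.
    """
    c = _condition_index(dataset, condition)
    groups = _triplet_series(dataset, c)
    if not groups:
        raise ValidationError("no triplet is shared by >= 2 subjects")
    R = dataset.n_rois
    per_triplet: dict[int, dict] = {}
    sums = np.zeros(R)
    counts = np.zeros(R)
    n_excluded = 0
    for trip, (subjects, series) in sorted(groups.items()):
        z, bad = _zscore(series)            # bad: (S, R)
        corr = _pairwise_corr(z)
        S = len(subjects)
        iu = np.tril_indices(S, k=-1)
        valid = ~(bad[iu[0]] | bad[iu[1]])  # (n_pairs, R)
        n_excluded += int((~valid).sum())
        pair_vals = corr[iu[0], iu[1], :]
        trip_sum = np.where(valid, pair_vals, 0.0).sum(axis=0)
        trip_cnt = valid.sum(axis=0)
        trip_isc = np.divide(trip_sum, trip_cnt, out=np.full(R, np.nan),
                             where=trip_cnt > 0)
        per_triplet[trip] = {"subjects": subjects, "corr": corr, "isc": trip_isc}
        sums += np.where(trip_cnt > 0, trip_isc, 0.0)
        counts += (trip_cnt > 0)
    if n_excluded:
        logger.warning("excluded %d zero-variance subject pairs", n_excluded)
    if np.any(counts == 0):
        raise ValidationError("all subject pairs excluded for at least one ROI")
    label = dataset.design.condition_labels[c]
    return IscResult(condition=label, isc=sums / counts, per_triplet=per_triplet,
                     roi_labels=list(dataset.roi_labels),
                     n_excluded_pairs=n_excluded)


def isc_permutation_null(dataset: RoiTimeSeriesDataset, condition: int | str,
                         n_iter: int = 5000, seed: int = 0) -> IscResult:
    """Observed ISC plus circular-shift permutation p-values per ROI.

    Each iteration independently shifts every subject's ideation series by a
    random offset in [1, T-1] and recomputes the triplet-matched ISC;
    p = (1 + #{null >= observed}) / (1 + n_iter).  The shifted-pair
    correlations are read off the circular cross-correlation computed once
    by FFT, so large iteration counts are cheap.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    c = _condition_index(dataset, condition)
    T = dataset.n_volumes
    if T < 3:
        raise ValidationError("need at least 3 volumes for circular shifts")
    observed = compute_isc(dataset, c)
    rng = np.random.default_rng(seed)
    groups = _triplet_series(dataset, c)

    null_acc = np.zeros((n_iter, dataset.n_rois))
    n_groups = 0
    for trip, (subjects, series) in sorted(groups.items()):
        z, _ = _zscore(series)
        S = len(subjects)
        # c_ij(delta) = (1/T) sum_t z_i[t] z_j[t+delta], all deltas at once
        F = np.fft.rfft(z, axis=1)
        iu = np.tril_indices(S, k=-1)
        cross = np.fft.irfft(np.conj(F[iu[0]]) * F[iu[1]], n=T, axis=1) / T
        # cross[p, delta, r] = corr of pair p when (shift_i - shift_j) = delta
        shifts = rng.integers(1, T, size=(n_iter, S))
        delta = (shifts[:, iu[0]] - shifts[:, iu[1]]) % T   # (n_iter, n_pairs)
        pair_idx = np.arange(len(iu[0]))
        null_acc += cross[pair_idx[None, :], delta, :].mean(axis=1)
        n_groups += 1
    null = null_acc / n_groups
    p = (1 + (null >= observed.isc[None, :]).sum(axis=0)) / (1 + n_iter)
    return IscResult(condition=observed.condition, isc=observed.isc,
                     per_triplet=observed.per_triplet,
                     roi_labels=observed.roi_labels, p_values=p,
                     null_mean=null.mean(axis=0), null_sd=null.std(axis=0),
                     n_excluded_pairs=observed.n_excluded_pairs)


@dataclass
class IscContrast:
    condition_a: str
    condition_b: str
    difference: np.ndarray     # (n_rois,) ISC_A - ISC_B
    p_values: np.ndarray
    q_values: np.ndarray
    roi_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi_labels,
                             "contrast": f"{self.condition_a}-{self.condition_b}",
                             "difference": self.difference,
                             "p": self.p_values, "q": self.q_values})


def isc_contrast(result_a: IscResult, result_b: IscResult,
                 n_iter: int = 5000, seed: int = 0) -> IscContrast:
    """Per-ROI ISC difference (A - B) with a sign-flipping permutation null.

    The exchangeable unit is the triplet: the per-triplet ISC difference is
    sign-flipped across triplets; the two-sided p compares |mean difference|
    against the flipped null.  BH-FDR q-values are attached.
    """
    if result_a.roi_labels != result_b.roi_labels:
        raise ValidationError("mismatched ROI sets between conditions")
    triplets = sorted(set(result_a.per_triplet) & set(result_b.per_triplet))
    if not triplets:
        raise ValidationError("no common triplets between conditions")
    diffs = np.stack([result_a.per_triplet[t]["isc"] - result_b.per_triplet[t]["isc"]
                      for t in triplets])              # (n_triplets, R)
    observed = diffs.mean(axis=0)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_iter, len(triplets)))
    null = flips @ diffs / len(triplets)               # (n_iter, R)
    p = (1 + (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)) / (1 + n_iter)
    q, _ = fdr_bh(p)
    return IscContrast(condition_a=result_a.condition,
                       condition_b=result_b.condition,
                       difference=observed, p_values=p, q_values=q,
                       roi_labels=list(result_a.roi_labels))
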