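"""Network functional connectivity and temporal irreversibility.

Functional connectivity is the Fisher z (arctanh) of the Pearson correlation
between ROI time courses, computed per story and averaged within
participant; summaries average within- or between-network ROI pairs for the
default-mode (DMN), salience (SAN) and frontoparietal-control (FCN)
networks.

Temporal irreversibility compares forward and time-reversed lagged
correlations: for zero-meaned series x_i, x_j,

    C_f(tau) = corr(x_i(t), x_j(t + tau))
    C_r(tau) = the same on the time-flipped series
    R(tau)   = (C_f(tau) - C_r(tau))^2   elementwise,

with tau ranging over 1..15 volumes by default, averaged over stories within
a participant; lag clusters are short (1-7) and long (8-15).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RoiTimeSeriesDataset, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["FcMatrix", "IrreversibilityTensor", "functional_connectivity",
           "story_fc", "irreversibility", "pairwise_irreversibility",
           "lag_cluster_summary", "SHORT_LAGS", "LONG_LAGS"]

FISHER_CLIP = 1 - 1e-7
SHORT_LAGS = range(1, 8)
LONG_LAGS = range(8, 16)


def story_fc(series: np.ndarray) -> np.ndarray:
    """arctanh-Pearson ROI x ROI matrix for one story (volumes x ROIs).

    |r| = 1 is clipped at 1 - 1e-7 before arctanh; zero-variance ROIs give
    NaN rows/columns (excluded from summaries).
    """
    series = np.asarray(series, float)
    if series.shape[0] < 3:
        raise ValidationError("need >= 3 volumes per story")
    sd = series.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(series, rowvar=False)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    if not ok.all():
        logger.warning("%d zero-variance ROIs excluded from FC", (~ok).sum())
    clipped = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, np.nan)   # diagonal excluded from all summaries
    return z


@dataclass
class FcMatrix:
    """Participant-level arctanh-Pearson FC (story-averaged), per condition."""

    values: np.ndarray            # (n_subjects, R, R)
    condition: str
    roi_labels: list[str]
    network_assignment: dict[str, str]

    def _net_idx(self, network: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.roi_labels)
                         if self.network_assignment.get(lab) == network], int)

    def within(self, network: str) -> np.ndarray:
        """Per-participant mean FC over i<j pairs inside a network."""
        idx = self._net_idx(network)
        if idx.size < 2:
            raise ValidationError(f"network {network!r} has < 2 ROIs")
        iu = np.triu_indices(idx.size, k=1)
        sub = self.values[:, idx[:, None], idx[None, :]]
        return np.nanmean(sub[:, iu[0], iu[1]], axis=1)

    def between(self, net_a: str, net_b: str) -> np.ndarray:
        """Per-participant mean FC over all cross-network ROI pairs."""
        ia, ib = self._net_idx(net_a), self._net_idx(net_b)
        if ia.size == 0 or ib.size == 0:
            raise ValidationError("empty network")
        sub = self.values[:, ia[:, None], ib[None, :]]
        return np.nanmean(sub.reshape(self.values.shape[0], -1), axis=1)

    def network_summary(self, networks: tuple[str, ...] = ("DMN", "SAN", "FCN")
                        ) -> pd.DataFrame:
        rows = []
        for i, na in enumerate(networks):
            if self._net_idx(na).size >= 2:
                for s, v in enumerate(self.within(na)):
                    rows.append({"participant": s, "condition": self.condition,
                                 "measure": f"within-{na}", "value": v})
            for nb in networks[i + 1:]:
                if self._net_idx(na).size and self._net_idx(nb).size:
                    for s, v in enumerate(self.between(na, nb)):
                        rows.append({"participant": s,
                                     "condition": self.condition,
                                     "measure": f"between-{na}-{nb}",
                                     "value": v})
        return pd.DataFrame(rows)

    def top_edges(self, fraction: float = 0.05,
                  network: str | None = None) -> pd.DataFrame:
        """Strongest edges by group-mean FC (e.g. top 5% within DMN)."""
        mean = np.nanmean(self.values, axis=0)
        idx = (self._net_idx(network) if network
               else np.arange(len(self.roi_labels)))
        iu = np.triu_indices(idx.size, k=1)
        weights = mean[idx[iu[0]], idx[iu[1]]]
        order = np.argsort(weights)[::-1]
        k = max(1, int(round(fraction * len(weights))))
        rows = [{"roi_a": self.roi_labels[idx[iu[0][o]]],
                 "roi_b": self.roi_labels[idx[iu[1][o]]],
                 "weight": weights[o]} for o in order[:k]]
        return pd.DataFrame(rows)


def functional_connectivity(dataset: RoiTimeSeriesDataset,
                            condition: int | str) -> FcMatrix:
    """Participant FC matrices for one condition (mean over that
    participant's stories)."""
    d = dataset.design
    labels = d.condition_labels
    c = labels.index(condition) if isinstance(condition, str) else condition
    out = np.empty((d.n_subjects, dataset.n_rois, dataset.n_rois))
    for s in range(d.n_subjects):
        mats = [story_fc(dataset.values[s, c, t])
                for t in range(d.trials_per_condition)]
        with warnings.catch_warnings():
            # the excluded diagonal is all-NaN by construction
            warnings.simplefilter("ignore", RuntimeWarning)
            out[s] = np.nanmean(mats, axis=0)
    return FcMatrix(values=out, condition=labels[c],
                    roi_labels=list(dataset.roi_labels),
                    network_assignment=dict(dataset.network_assignment))


# ---------------------------------------------------------------------------
# Temporal irreversibility
# ---------------------------------------------------------------------------

def _lagged_corr(series: np.ndarray, tau: int) -> np.ndarray:
    """(R, R) Pearson correlation between x_i(t) and x_j(t+tau) on the
    overlapping T - tau samples, each segment re-centred."""
    T = series.shape[0]
    a = series[: T - tau]
    b = series[tau:]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (a.T @ b) / (T - tau) / np.outer(sa, sb)
    return c


def pairwise_irreversibility(series: np.ndarray,
                             lags=range(1, 16)) -> np.ndarray:
    """R(tau) = (C_f - C_r)^2 for one story: (R, R, n_lags) tensor.

    Ordered pairs: entry (i, j) uses C_f = corr(x_i(t), x_j(t+tau)); the
    (j, i) entry is computed independently.  Constant series give NaN
    entries (flagged, excluded from averages).
    """
    series = np.asarray(series, float)
    lags = list(lags)
    T = series.shape[0]
    if T < max(lags) + 2:
        raise ValidationError(
            f"need T >= max lag + 2 (T={T}, max lag={max(lags)})")
    series = series - series.mean(axis=0)   # zero-meaned, per the definition
    reversed_series = series[::-1]
    out = np.empty((series.shape[1], series.shape[1], len(lags)))
    for li, tau in enumerate(lags):
        cf = _lagged_corr(series, tau)
        cr = _lagged_corr(reversed_series, tau)
        out[:, :, li] = (cf - cr) ** 2
    return out


@dataclass
class IrreversibilityTensor:
    """Participant-level story-averaged R(tau): (n_subjects, R, R, n_lags)."""

    values: np.ndarray
    lags: list[int]
    condition: str
    roi_labels: list[str]

    def curve(self) -> pd.DataFrame:
        """Group-mean R over all ordered off-diagonal pairs, per lag."""
        R = self.values.shape[1]
        off = ~np.eye(R, dtype=bool)
        rows = [{"condition": self.condition, "lag": tau,
                 "irreversibility": float(np.nanmean(self.values[:, off, li]))}
                for li, tau in enumerate(self.lags)]
        return pd.DataFrame(rows)


def irreversibility(dataset: RoiTimeSeriesDataset, condition: int | str,
                    lags=range(1, 16)) -> IrreversibilityTensor:
    """Story-averaged irreversibility tensor per participant for a condition."""
    d = dataset.design
    labels = d.condition_labels
    c = labels.index(condition) if isinstance(condition, str) else condition
    lags = list(lags)
    per_subject = []
    for s in range(d.n_subjects):
        mats = [pairwise_irreversibility(dataset.values[s, c, t], lags)
                for t in range(d.trials_per_condition)]
        per_subject.append(np.nanmean(mats, axis=0))
    return IrreversibilityTensor(values=np.stack(per_subject), lags=lags,
                                 condition=labels[c],
                                 roi_labels=list(dataset.roi_labels))


def lag_cluster_summary(tensor: IrreversibilityTensor,
                        short=SHORT_LAGS, long=LONG_LAGS) -> pd.DataFrame:
    """Per-participant mean R over pairs within the short/long lag clusters."""
    available = set(tensor.lags)
    short = [l for l in short if l in available]
    long = [l for l in long if l in available]
    missing = [l for l in list(SHORT_LAGS) + list(LONG_LAGS)
               if l <= max(tensor.lags) and l not in available]
    if missing:
        raise ValidationError(f"missing lags {missing} in tensor")
    R = tensor.values.shape[1]
    off = ~np.eye(R, dtype=bool)
    rows = []
    for name, cluster in (("short", short), ("long", long)):
        if not cluster:
            continue
        idx = [tensor.lags.index(l) for l in cluster]
        vals = np.nanmean(tensor.values[:, :, :, idx][:, off, :], axis=(1, 2))
        for s, v in enumerate(vals):
            rows.append({"participant": s, "condition": tensor.condition,
                         "measure": f"irrev-{name}", "value": float(v)})
    return pd.DataFrame(rows)


def edge_contrast(tensor_a: IrreversibilityTensor,
                  tensor_b: IrreversibilityTensor,
                  lags: list[int] | None = None,
                  p_threshold: float = 1e-4) -> pd.DataFrame:
    """Directed-edge contrast (paired t across participants, uncorrected).

    Averages R over the requested lags per edge, runs a two-sided paired t
    per ordered pair, and returns edges with p below the (uncorrected)
    threshold.
    """
    if tensor_a.roi_labels != tensor_b.roi_labels:
        raise ValidationError("mismatched ROI sets")
    lags = lags or [l for l in LONG_LAGS if l in tensor_a.lags]
    ia = [tensor_a.lags.index(l) for l in lags]
    ib = [tensor_b.lags.index(l) for l in lags]
    a = tensor_a.values[:, :, :, ia].mean(axis=3)
    b = tensor_b.values[:, :, :, ib].mean(axis=3)
    from scipy import stats as sstats
    rows = []
    R = a.shape[1]
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            diff = a[:, i, j] - b[:, i, j]
            if np.all(np.isfinite(diff)) and diff.std(ddof=1) > 0:
                res = sstats.ttest_rel(a[:, i, j], b[:, i, j])
                if res.pvalue < p_threshold:
                    rows.append({"roi_a": tensor_a.roi_labels[i],
                                 "roi_b": tensor_a.roi_labels[j],
                                 "t": float(res.statistic),
                                 "p": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "t", "p"])
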