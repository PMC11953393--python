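"""Signal cleaning, ideation-window extraction and the trial-wise variance check.

Cleaning applies, in this fixed order: linear detrend, low-pass Butterworth
(0.09 Hz), high-pass Butterworth (0.008 Hz), then OLS confound regression.
Filters are order-5 zero-phase (forward-backward); confounds are passed
through the identical detrend + filters before regression so the residuals
stay orthogonal to them in the analysed band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dataset import RoiTimeSeriesDataset, ValidationError

__all__ = ["CleaningConfig", "clean_signal", "clean_dataset",
           "extract_ideation", "trialwise_variance_profile"]


@dataclass(frozen=True)
class CleaningConfig:
    detrend: bool = True
    low_pass_hz: float | None = 0.09
    high_pass_hz: float | None = 0.008
    filter_order: int = 5
    confound_names: tuple[str, ...] = ()

    def validate(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if self.low_pass_hz is not None and not (0 < self.low_pass_hz < nyquist):
            raise ValidationError(
                f"low_pass_hz must lie in (0, Nyquist={nyquist:g})")
        if self.high_pass_hz is not None and self.low_pass_hz is not None:
            if not self.high_pass_hz < self.low_pass_hz:
                raise ValidationError("high_pass_hz must be below low_pass_hz")


def _butter_sos(cutoff_hz: float, btype: str, order: int, tr: float) -> np.ndarray:
    return sps.butter(order, cutoff_hz, btype=btype, fs=1.0 / tr, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_pad, x.shape[0] - 1)
    return sps.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def _apply_filters(x: np.ndarray, config: CleaningConfig, tr: float) -> np.ndarray:
    if config.detrend:
        x = sps.detrend(x, axis=0, type="linear")
    if config.low_pass_hz is not None:
        x = _filtfilt(_butter_sos(config.low_pass_hz, "lowpass",
                                  config.filter_order, tr), x)
    if config.high_pass_hz is not None:
        x = _filtfilt(_butter_sos(config.high_pass_hz, "highpass",
                                  config.filter_order, tr), x)
    return x


def clean_signal(raw: np.ndarray, confounds: np.ndarray | None,
                 config: CleaningConfig, tr: float) -> np.ndarray:
    """Detrend -> low-pass -> high-pass -> OLS confound regression.

    ``raw`` is volumes x units; ``confounds`` volumes x k (or None).  The
    residuals are orthogonal to the identically filtered confounds.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("raw must be 2-D (volumes x units)")
    config.validate(tr)
    x = _apply_filters(raw, config, tr)
    if confounds is None or confounds.size == 0:
        return x
    confounds = np.asarray(confounds, dtype=float)
    if confounds.shape[0] != raw.shape[0]:
        raise ValidationError("raw and confounds must share the volume axis")
    cf = _apply_filters(confounds, config, tr)
    design = np.column_stack([np.ones(cf.shape[0]), cf])
    rank = np.linalg.matrix_rank(design, tol=1e-8)
    if rank < design.shape[1]:
        raise ValidationError(
            "confound matrix is rank deficient (collinear confounds)")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def clean_dataset(dataset: RoiTimeSeriesDataset,
                  confounds: np.ndarray | None = None,
                  config: CleaningConfig | None = None) -> RoiTimeSeriesDataset:
    """Clean every subject/condition/trial table of a dataset (per run)."""
    config = config or CleaningConfig()
    d = dataset.design
    out = np.empty_like(dataset.values)
    for s in range(d.n_subjects):
        for c in range(d.n_conditions):
            for t in range(d.trials_per_condition):
                out[s, c, t] = clean_signal(dataset.values[s, c, t],
                                            confounds, config, d.tr_seconds)
    return dataset.with_values(out)


def extract_ideation(dataset: RoiTimeSeriesDataset,
                     stage_durations: dict[str, float] | None = None
                     ) -> RoiTimeSeriesDataset:
    """Slice out the ideation window of every trial.

    Returns exactly ``floor(ideation_seconds / TR)`` volumes per trial
    starting at the first volume after the word-cue offset (0-based,
    half-open window).  ``stage_durations`` may override the design's
    ``baseline``/``words``/``ideation`` seconds.
    """
    d = dataset.design
    durations = {"baseline": d.baseline_seconds, "words": d.words_seconds,
                 "ideation": d.ideation_volumes * d.tr_seconds}
    if stage_durations:
        durations.update(stage_durations)
    if durations["ideation"] <= 0:
        raise ValidationError("ideation duration must be positive")
    start = int(round((durations["baseline"] + durations["words"]) / d.tr_seconds))
    n_vol = int(durations["ideation"] / d.tr_seconds)
    stop = start + n_vol
    if dataset.n_volumes == n_vol:
        # trials already reduced to the ideation window
        return dataset
    if dataset.n_volumes < stop:
        raise ValidationError(
            f"trials truncated: need volumes [{start}, {stop}) but trials "
            f"have {dataset.n_volumes} volumes")
    return dataset.with_values(dataset.values[:, :, :, start:stop, :])


def trialwise_variance_profile(dataset: RoiTimeSeriesDataset,
                               per_network: bool = True) -> pd.DataFrame:
    """Across-trial signal variance along each volume of the window.

    For each subject, condition and volume index: sample variance (ddof=1)
    across trials per ROI, averaged over ROIs, then averaged across
    subjects.  Returns a tidy frame with a whole-brain row set
    (``network == 'all'``) and, optionally, per-network rows.
    """
    d = dataset.design
    if d.trials_per_condition < 2:
        raise ValidationError("variance across trials needs >= 2 trials")
    var = dataset.values.var(axis=2, ddof=1)  # (subj, cond, volume, roi)
    groups = {"all": np.arange(dataset.n_rois)}
    if per_network:
        for net in sorted(set(dataset.network_assignment.values())):
            idx = dataset.network_indices(net)
            if idx.size:
                groups[net] = idx
    rows = []
    for net, idx in groups.items():
        prof = var[:, :, :, idx].mean(axis=3).mean(axis=0)  # (cond, volume)
        for c, lab in enumerate(d.condition_labels):
            for v in range(prof.shape[1]):
                rows.append({"network": net, "condition": lab,
                             "volume": v, "variance": prof[c, v]})
    return pd.DataFrame(rows)


def read_nifti_parcellated(bold_path, atlas_path):  # pragma: no cover - optional adapter
    """Mean time series per atlas label from volumetric NIfTI inputs.

    Thin adapter for volumetric data; requires nibabel (optional extra).
    Returns (volumes x labels array, sorted label list).
    """
    import nibabel as nib

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj)
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj)
    labels = sorted(int(l) for l in np.unique(atlas) if l != 0)
    out = np.column_stack([bold[atlas == lab].mean(axis=0) for lab in labels])
    return out, labels
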