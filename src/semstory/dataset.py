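"""Shared experiment-design and ROI time-series containers.

The experimental unit throughout the package is one *trial* (one story): a
subject sees a triplet of target words, silently ideates a story for a fixed
window, then reports it.  Trials are organised as ``n_conditions`` blocks of
``trials_per_condition`` trials each.  Triplet sets are counterbalanced across
subjects: subject ``s`` performs condition ``c`` with triplet set
``(c + s) % n_conditions``, so every triplet is seen exactly once per subject
and, across subjects, every triplet set appears in every condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CONDITION_LABELS = ("OR", "CR", "RA")
NETWORKS = ("DMN", "SAN", "FCN", "other")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial layout of a story-generation experiment.

    Times are in seconds; volumes are counted at the repetition time
    ``tr_seconds``.  A trial is baseline -> word cue -> ideation -> report;
    only the ideation window carries task structure downstream.
    """

    n_subjects: int = 6
    n_conditions: int = 3
    trials_per_condition: int = 8
    ideation_volumes: int = 30
    tr_seconds: float = 1.0
    n_rois: int = 400
    baseline_seconds: float = 25.0
    words_seconds: float = 5.0
    report_seconds: float = 30.0
    counterbalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_conditions", "trials_per_condition",
                     "ideation_volumes", "n_rois"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.n_conditions > len(CONDITION_LABELS):
            raise ValidationError(
                f"at most {len(CONDITION_LABELS)} conditions supported")

    # -- bookkeeping ---------------------------------------------------

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return CONDITION_LABELS[: self.n_conditions]

    @property
    def stories_per_subject(self) -> int:
        return self.n_conditions * self.trials_per_condition

    @property
    def n_triplets(self) -> int:
        return self.n_conditions * self.trials_per_condition

    @property
    def baseline_volumes(self) -> int:
        return int(round(self.baseline_seconds / self.tr_seconds))

    @property
    def words_volumes(self) -> int:
        return int(round(self.words_seconds / self.tr_seconds))

    @property
    def report_volumes(self) -> int:
        return int(round(self.report_seconds / self.tr_seconds))

    @property
    def ideation_start(self) -> int:
        """0-based index of the first ideation volume in a full trial."""
        return self.baseline_volumes + self.words_volumes

    @property
    def trial_volumes(self) -> int:
        return (self.baseline_volumes + self.words_volumes
                + self.ideation_volumes + self.report_volumes)

    def triplet_id(self, subject: int, condition: int, trial: int) -> int:
        """Triplet cueing ``trial`` of ``condition`` for ``subject``."""
        if self.counterbalance:
            triplet_set = (condition + subject) % self.n_conditions
        else:
            triplet_set = condition
        return triplet_set * self.trials_per_condition + trial

    def triplet_assignment(self, subject: int) -> dict[tuple[int, int], int]:
        """Map (condition, trial) -> triplet id for one subject."""
        return {(c, t): self.triplet_id(subject, c, t)
                for c in range(self.n_conditions)
                for t in range(self.trials_per_condition)}

    def subjects_with_triplet(self, condition: int, triplet: int) -> list[int]:
        """Subjects cued by ``triplet`` within ``condition`` (and its trial)."""
        return [s for s in range(self.n_subjects)
                if any(self.triplet_id(s, condition, t) == triplet
                       for t in range(self.trials_per_condition))]

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        return cls(**json.loads(text))


def block_network_assignment(roi_labels: list[str]) -> dict[str, str]:
    """Assign ROIs to DMN/SAN/FCN/other in four contiguous blocks.

    A stand-in for an atlas network lookup on synthetic parcellations.
    """
    n = len(roi_labels)
    edges = [0, n // 4, n // 2, 3 * n // 4, n]
    out: dict[str, str] = {}
    for net, lo, hi in zip(NETWORKS, edges[:-1], edges[1:]):
        for label in roi_labels[lo:hi]:
            out[label] = net
    return out


@dataclass
class RoiTimeSeriesDataset:
    """Subject x condition x trial x volume x ROI tensor with design metadata."""

    values: np.ndarray
    design: ExperimentDesign
    roi_labels: list[str] = field(default_factory=list)
    network_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 5:
            raise ValidationError(
                "values must be a 5-D (subject, condition, trial, volume, roi) tensor")
        d = self.design
        expect = (d.n_subjects, d.n_conditions, d.trials_per_condition)
        if v.shape[:3] != expect:
            raise ValidationError(
                f"tensor leading shape {v.shape[:3]} != design {expect}")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:03d}" for i in range(v.shape[4])]
        if len(self.roi_labels) != v.shape[4]:
            raise ValidationError("roi_labels length must match ROI axis")
        if not self.network_assignment:
            self.network_assignment = block_network_assignment(self.roi_labels)
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite values in time-series tensor")
        self.values = v

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]

    @property
    def n_rois(self) -> int:
        return self.values.shape[4]

    def network_indices(self, network: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.roi_labels)
                         if self.network_assignment.get(lab) == network], dtype=int)

    # -- disk round trip: one delimited table per subject/condition/trial --

    def write_tables(self, out_dir: str | Path, sep: str = "\t") -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "design.json").write_text(self.design.to_json())
        (out / "networks.json").write_text(json.dumps(self.network_assignment, indent=0))
        d = self.design
        for s in range(d.n_subjects):
            for c, lab in enumerate(d.condition_labels):
                for t in range(d.trials_per_condition):
                    df = pd.DataFrame(self.values[s, c, t], columns=self.roi_labels)
                    df.to_csv(out / f"sub-{s:02d}_cond-{lab}_trial-{t:02d}.tsv",
                              sep=sep, index=False)
        return out

    @classmethod
    def read_tables(cls, in_dir: str | Path, sep: str = "\t") -> "RoiTimeSeriesDataset":
        src = Path(in_dir)
        design = ExperimentDesign.from_json((src / "design.json").read_text())
        networks = json.loads((src / "networks.json").read_text())
        first = pd.read_csv(
            src / f"sub-00_cond-{design.condition_labels[0]}_trial-00.tsv", sep=sep)
        roi_labels = list(first.columns)
        n_vol = len(first)
        values = np.empty((design.n_subjects, design.n_conditions,
                           design.trials_per_condition, n_vol, len(roi_labels)))
        for s in range(design.n_subjects):
            for c, lab in enumerate(design.condition_labels):
                for t in range(design.trials_per_condition):
                    df = pd.read_csv(
                        src / f"sub-{s:02d}_cond-{lab}_trial-{t:02d}.tsv", sep=sep)
                    values[s, c, t] = df.to_numpy()
        return cls(values=values, design=design, roi_labels=roi_labels,
                   network_assignment=networks)

    def with_values(self, values: np.ndarray) -> "RoiTimeSeriesDataset":
        return RoiTimeSeriesDataset(values=values, design=self.design,
                                    roi_labels=list(self.roi_labels),
                                    network_assignment=dict(self.network_assignment))
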