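"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analyses are
designed to detect:

* a smooth time course locked to each target-word triplet and shared across
  subjects (what inter-subject correlation measures),
* an additive condition-specific multivariate ROI pattern (what the searchlight
  classifier decodes),
* noise drawn with a network-structured covariance (what functional
  connectivity summarises), and
* lagged directed couplings between ROIs (what temporal irreversibility
  detects).

Baseline, word-cue and report volumes are unstructured noise; only the
ideation window carries effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset import (ExperimentDesign, RoiTimeSeriesDataset, ValidationError,
                      block_network_assignment)

__all__ = [
    "ExperimentDesign", "PlantedEffects", "make_bold_experiment",
    "make_toy_lexicon", "make_lm_table", "make_toy_connectome",
    "make_network_covariance",
]


@dataclass
class PlantedEffects:
    """Ground-truth effect amplitudes for :func:`make_bold_experiment`.

    shared_component_amplitude : (n_triplets, n_rois) or (n_rois,) array-like
        Gain of the triplet-locked shared time course per ROI.
    shared_condition_gain : (n_conditions,) array-like or None
        Optional per-condition multiplier on the shared component (plants
        condition differences in inter-subject synchrony); None means 1.
    condition_pattern_strength : (n_rois,) array-like or scalar
        Per-ROI separation of condition mean patterns in multivariate space.
    network_covariance : (n_rois, n_rois) PSD matrix or None
        Covariance of the ideation-window noise; None means
        ``noise_sd**2 * I``.
    directed_couplings : list of (source_roi, target_roi, lag, gain)
        Lagged linear autoregressive couplings applied inside the ideation
        window: ``x[t, target] += gain * x[t - lag, source]``.
    noise_sd : float
        SD of the unstructured noise (and of ideation noise when no
        covariance is given).
    heavy_tail_df : float or None
        If set, baseline/report noise is Student-t with this many df instead
        of Gaussian (robustness checks).
    """

    shared_component_amplitude: np.ndarray | float = 0.0
    shared_condition_gain: np.ndarray | None = None
    condition_pattern_strength: np.ndarray | float = 0.0
    network_covariance: np.ndarray | None = None
    directed_couplings: list[tuple[int, int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    heavy_tail_df: float | None = None

    def validate(self, design: ExperimentDesign) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        amp = np.broadcast_to(np.asarray(self.shared_component_amplitude, float),
                              (design.n_triplets, design.n_rois))
        if not np.all(np.isfinite(amp)):
            raise ValidationError("shared_component_amplitude must be finite")
        if self.shared_condition_gain is not None:
            gain = np.asarray(self.shared_condition_gain, float)
            if gain.shape != (design.n_conditions,):
                raise ValidationError(
                    "shared_condition_gain must have one entry per condition")
        if self.network_covariance is not None:
            cov = np.asarray(self.network_covariance, float)
            if cov.shape != (design.n_rois, design.n_rois):
                raise ValidationError("network_covariance must be n_rois x n_rois")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValidationError("network_covariance must be symmetric")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
                raise ValidationError("network_covariance must be positive semidefinite")
        for src, tgt, lag, gain in self.directed_couplings:
            if not (0 <= src < design.n_rois and 0 <= tgt < design.n_rois):
                raise ValidationError("coupling ROI index out of range")
            if not (1 <= lag < design.ideation_volumes):
                raise ValidationError(
                    f"coupling lag {lag} must be in [1, ideation_volumes)")
            if not np.isfinite(gain):
                raise ValidationError("coupling gain must be finite")


def _shared_courses(design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Smooth (low-pass filtered Gaussian) unit-variance time courses,
    one per (triplet, ROI), fixed across subjects."""
    raw = rng.standard_normal(
        (design.n_triplets, design.ideation_volumes, design.n_rois))
    smooth = gaussian_filter1d(raw, sigma=2.0, axis=1, mode="wrap")
    smooth -= smooth.mean(axis=1, keepdims=True)
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return smooth / sd


def make_bold_experiment(design: ExperimentDesign,
                         effects: PlantedEffects | None = None,
                         ideation_only: bool = False) -> RoiTimeSeriesDataset:
    """Generate a full synthetic BOLD experiment.

    Returns a dataset of full trials (baseline + words + ideation + report
    volumes); pass ``ideation_only=True`` to keep just the ideation window.
    Identical (design, effects) including ``design.seed`` give bit-identical
    output.
    """
    effects = effects or PlantedEffects()
    effects.validate(design)
    rng = np.random.default_rng(design.seed)
    d = design
    T = d.ideation_volumes

    shared = _shared_courses(d, rng)
    amp = np.broadcast_to(np.asarray(effects.shared_component_amplitude, float),
                          (d.n_triplets, d.n_rois))
    cond_gain = (np.ones(d.n_conditions) if effects.shared_condition_gain is None
                 else np.asarray(effects.shared_condition_gain, float))

    # deterministic condition mean patterns: adjacent condition indices are
    # separated by condition_pattern_strength[r] at ROI r, with alternating
    # sign across ROIs so the patterns are not a global offset
    strength = np.broadcast_to(
        np.asarray(effects.condition_pattern_strength, float), (d.n_rois,))
    offsets = np.arange(d.n_conditions) - (d.n_conditions - 1) / 2
    roi_sign = np.where(np.arange(d.n_rois) % 2 == 0, 1.0, -1.0)
    patt = offsets[:, None] * (strength * roi_sign)[None, :]

    chol = None
    if effects.network_covariance is not None:
        cov = np.asarray(effects.network_covariance, float)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(d.n_rois))

    # the full trial is always generated so the random stream (hence the
    # ideation window) is identical whether or not ideation_only is set
    n_vol = d.trial_volumes
    start = d.ideation_start
    values = np.empty((d.n_subjects, d.n_conditions, d.trials_per_condition,
                       n_vol, d.n_rois))

    def _outside_noise(shape):
        if effects.heavy_tail_df is not None:
            return effects.noise_sd * rng.standard_t(effects.heavy_tail_df, shape)
        return effects.noise_sd * rng.standard_normal(shape)

    for s in range(d.n_subjects):
        for c in range(d.n_conditions):
            for t in range(d.trials_per_condition):
                trial = _outside_noise((n_vol, d.n_rois))
                z = rng.standard_normal((T, d.n_rois))
                ideation = (z @ chol.T) if chol is not None else effects.noise_sd * z
                trip = d.triplet_id(s, c, t)
                ideation = ideation + cond_gain[c] * amp[trip] * shared[trip]
                ideation = ideation + patt[c]
                for src, tgt, lag, gain in effects.directed_couplings:
                    for tt in range(lag, T):
                        ideation[tt, tgt] += gain * ideation[tt - lag, src]
                trial[start:start + T] = ideation
                values[s, c, t] = trial

    if ideation_only:
        values = values[:, :, :, start:start + T, :]
    roi_labels = [f"ROI{i:03d}" for i in range(d.n_rois)]
    return RoiTimeSeriesDataset(values=values, design=d, roi_labels=roi_labels,
                                network_assignment=block_network_assignment(roi_labels))


def make_network_covariance(roi_labels: list[str],
                            within: dict[str, float] | None = None,
                            base_variance: float = 1.0) -> np.ndarray:
    """Block covariance with a common within-network correlation per network.

    ``within`` maps network name -> correlation (e.g. ``{"DMN": 0.6}``);
    unlisted networks get independent ROIs.  The result is PSD by
    construction (equicorrelation blocks with r in [0, 1]).
    """
    within = within or {}
    assignment = block_network_assignment(roi_labels)
    n = len(roi_labels)
    cov = np.eye(n) * base_variance
    for net, r in within.items():
        if not 0 <= r <= 1:
            raise ValidationError("within-network correlation must be in [0, 1]")
        idx = [i for i, lab in enumerate(roi_labels) if assignment[lab] == net]
        for i in idx:
            for j in idx:
                if i != j:
                    cov[i, j] = r * base_variance
    return cov


# ---------------------------------------------------------------------------
# Toy lexicons and masked-LM tables
# ---------------------------------------------------------------------------

def make_toy_lexicon(vocab: list[str], dimension: int,
                     cluster_spec: dict[str, int] | None = None,
                     seed: int = 0, spread: float = 0.15):
    """Unit-norm embedding lexicon with optional cluster structure.

    Words sharing a cluster id are drawn near a common random direction
    (pairwise cosine similarity above between-cluster pairs); unclustered
    words get independent random directions.
    """
    from .text_metrics import EmbeddingLexicon

    if dimension < 2:
        raise ValidationError("dimension must be >= 2")
    if len(set(vocab)) != len(vocab):
        raise ValidationError("duplicate words in vocab")
    rng = np.random.default_rng(seed)
    cluster_spec = cluster_spec or {}
    centers: dict[int, np.ndarray] = {}
    for cid in sorted(set(cluster_spec.values())):
        v = rng.standard_normal(dimension)
        centers[cid] = v / np.linalg.norm(v)
    vectors: dict[str, np.ndarray] = {}
    for word in vocab:
        if word in cluster_spec:
            v = centers[cluster_spec[word]] + spread * rng.standard_normal(dimension)
        else:
            v = rng.standard_normal(dimension)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingLexicon(vectors=vectors, dimension=dimension,
                            model_id=f"toy-seed{seed}")


def make_lm_table(vocab: list[str], contexts: list[tuple[str, int]],
                  concentration: float = 1.0,
                  target_boost: dict[tuple[str, int], str] | None = None,
                  boost_logit: float = 3.0, seed: int = 0):
    """Masked-LM probability table over ``vocab`` for the given masked positions.

    ``contexts`` lists (story_id, mask_index) keys.  Probabilities are a
    softmax of ``concentration``-scaled random logits; as concentration -> 0
    every distribution tends to uniform.  ``target_boost`` forces the named
    word to carry the modal probability at that position.
    """
    from .text_metrics import MaskedLMTable

    if not vocab:
        raise ValidationError("vocab must be non-empty")
    if len(set(vocab)) != len(vocab):
        raise ValidationError("duplicate words in vocab")
    target_boost = target_boost or {}
    for key, word in target_boost.items():
        if word not in vocab:
            raise ValidationError(f"boosted word {word!r} not in vocab")
    if concentration < 0:
        raise ValidationError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    word_index = {w: i for i, w in enumerate(vocab)}
    table: dict[tuple[str, int], dict[str, float]] = {}
    for key in contexts:
        logits = concentration * rng.standard_normal(len(vocab))
        if key in target_boost:
            logits[word_index[target_boost[key]]] = logits.max() + boost_logit
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        table[key] = {w: float(p) for w, p in zip(vocab, probs)}
    return MaskedLMTable(distributions=table, model_id=f"toy-lm-seed{seed}")


# ---------------------------------------------------------------------------
# Toy connectomes with known spectra
# ---------------------------------------------------------------------------

def make_toy_connectome(kind: str, n_vertices: int, **params):
    """Small structural connectomes for harmonic-decomposition fixtures.

    kind = "ring"       : cycle graph (2-regular, closed-form spectrum).
    kind = "lattice"    : square grid linked within ``radius_mm`` at
                          ``spacing_mm`` vertex spacing.
    kind = "two_region" : two vertex blocks wired according to a 2x2
                          ``region_matrix`` plus dense within-block links.
    """
    from .chd import StructuralConnectome

    if n_vertices < 3:
        raise ValidationError("n_vertices must be >= 3")
    if kind == "ring":
        A = np.zeros((n_vertices, n_vertices), dtype=np.uint8)
        idx = np.arange(n_vertices)
        A[idx, (idx + 1) % n_vertices] = 1
        A[(idx + 1) % n_vertices, idx] = 1
        theta = 2 * np.pi * idx / n_vertices
        coords = np.column_stack([np.cos(theta), np.sin(theta),
                                  np.zeros(n_vertices)]) * 50.0
        labels = np.zeros(n_vertices, dtype=int)
    elif kind == "lattice":
        spacing = float(params.get("spacing_mm", 5.0))
        radius = float(params.get("radius_mm", 10.0))
        side = int(np.ceil(np.sqrt(n_vertices)))
        xy = np.array([(i % side, i // side) for i in range(n_vertices)], float)
        coords = np.column_stack([xy * spacing, np.zeros(n_vertices)])
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        A = ((dist > 0) & (dist < radius)).astype(np.uint8)
        labels = np.zeros(n_vertices, dtype=int)
    elif kind == "two_region":
        region_matrix = np.asarray(params.get("region_matrix",
                                              [[0.0, 1.0], [1.0, 0.0]]), float)
        half = n_vertices // 2
        labels = np.array([0] * half + [1] * (n_vertices - half))
        A = np.zeros((n_vertices, n_vertices), dtype=np.uint8)
        thr = region_matrix.mean()
        sym = (region_matrix + region_matrix.T) / 2
        for i in range(n_vertices):
            for j in range(n_vertices):
                if i == j:
                    continue
                if labels[i] == labels[j] or sym[labels[i], labels[j]] > thr:
                    A[i, j] = 1
        coords = np.column_stack([labels * 100.0,
                                  np.arange(n_vertices, dtype=float),
                                  np.zeros(n_vertices)])
    else:
        raise ValidationError(f"unknown connectome kind {kind!r}")
    return StructuralConnectome(adjacency=A, coords=coords,
                                region_labels=labels)


# ---------------------------------------------------------------------------
# Toy stories (plumbing for the text-metrics stage of the pipeline)
# ---------------------------------------------------------------------------

def make_toy_stories(design: ExperimentDesign, vocab: list[str],
                     targets_per_story: int = 3, story_length: int = 12,
                     seed: int | None = None) -> list:
    """Random whitespace-token stories with 3 marked targets per story."""
    from .text_metrics import StoryTranscript

    rng = np.random.default_rng(design.seed if seed is None else seed)
    stories = []
    for s in range(design.n_subjects):
        for c, lab in enumerate(design.condition_labels):
            for t in range(design.trials_per_condition):
                targets = list(rng.choice(vocab, size=targets_per_story,
                                          replace=False))
                others = [w for w in vocab if w not in targets]
                body = list(rng.choice(others, size=story_length, replace=True))
                tokens = targets + body
                stories.append(StoryTranscript(
                    tokens=tokens, target_words=targets,
                    condition_label=lab, subject_id=s, trial_id=t))
    return stories
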