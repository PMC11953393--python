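"""Shared inferential machinery and pipeline orchestration.

Paired one-tailed t-tests with Cohen's d (and its noncentral-t confidence
interval), Benjamini-Hochberg FDR, and the ``run_pipeline`` driver that ties
the synthetic-data, text-metrics, cleaning, ISC, MVPA, harmonic, and
dynamics stages into one reproducible run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .dataset import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PairedComparison", "paired_test", "cohens_d_ci", "fdr_bh",
           "permutation_p", "run_pipeline", "DEFAULT_CONFIG"]


@dataclass
class PairedComparison:
    n: int
    t: float
    p: float
    d: float
    d_ci: tuple[float, float]
    mean_diff: float
    alternative: str
    q: float | None = None


def cohens_d_ci(d: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """CI for a paired-design Cohen's d via noncentral-t inversion.

    The observed t = d * sqrt(n) is referred to noncentral t with n-1 df;
    the CI bounds are the noncentrality parameters bracketing it, rescaled
    back to the d scale.
    """
    if n < 2:
        raise ValidationError("need n >= 2 for a confidence interval")
    t_obs = d * np.sqrt(n)
    df = n - 1
    alpha = 1 - confidence

    def _bound(prob: float) -> float:
        # nc such that P(T_{df, nc} <= t_obs) == prob; cdf decreases in nc
        f = lambda nc: stats.nct.cdf(t_obs, df, nc) - prob
        lo, hi = t_obs - 2, t_obs + 2
        while f(lo) < 0:
            lo -= 5
        while f(hi) > 0:
            hi += 5
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    return (_bound(1 - alpha / 2) / np.sqrt(n), _bound(alpha / 2) / np.sqrt(n))


def paired_test(a: np.ndarray, b: np.ndarray, alternative: str = "greater",
                d_convention: str = "diff-sd") -> PairedComparison:
    """One-tailed paired t-test of a vs b with Cohen's d and its 95% CI.

    ``d_convention``: "diff-sd" divides the mean difference by the SD of the
    differences; "average-sd" by the mean of the two condition SDs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("a and b must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            # identical inputs: no evidence either way
            return PairedComparison(n=len(a), t=0.0,
                                    p=0.5 if alternative != "two-sided" else 1.0,
                                    d=0.0, d_ci=(0.0, 0.0), mean_diff=0.0,
                                    alternative=alternative)
        raise ValidationError("zero-variance differences (degenerate paired test)")
    res = stats.ttest_rel(a, b, alternative=alternative)
    if d_convention == "diff-sd":
        d = diff.mean() / sd
    elif d_convention == "average-sd":
        d = diff.mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
    else:
        raise ValidationError(f"unknown d convention {d_convention!r}")
    ci = cohens_d_ci(diff.mean() / sd, len(a))
    if d_convention == "average-sd":
        scale = d / (diff.mean() / sd) if diff.mean() != 0 else 1.0
        ci = (ci[0] * scale, ci[1] * scale)
    return PairedComparison(n=len(a), t=float(res.statistic), p=float(res.pvalue),
                            d=float(d), d_ci=(float(ci[0]), float(ci[1])),
                            mean_diff=float(diff.mean()), alternative=alternative)


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction: (q-values, rejection mask)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1] with no NaN")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def permutation_p(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """Permutation p with the +1 correction: (1 + #extreme) / (1 + n)."""
    null = np.asarray(null, float)
    if tail == "greater":
        extreme = (null >= observed).sum()
    elif tail == "two-sided":
        extreme = (np.abs(null) >= abs(observed)).sum()
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return float((1 + extreme) / (1 + len(null)))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {"n_subjects": 6, "n_conditions": 3, "trials_per_condition": 4,
               "ideation_volumes": 30, "n_rois": 20},
    "effects": {"shared_component_amplitude": 0.0,
                "condition_pattern_strength": 0.0, "noise_sd": 1.0},
    "stages": ["simulate", "text_metrics", "prep", "isc", "mvpa",
               "chd", "dynamics", "stats"],
    "isc": {"n_iter": 500},
    "mvpa": {"n_label_permutations": 5},
    "chd": {"connectome": "ring", "n_vertices": 32},
    "fdr_alpha": {"isc": 0.01, "mvpa_classify": 0.01, "mvpa_regress": 0.05,
                  "fc": 0.05},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run",
                 stages: list[str] | None = None) -> Path:
    """Execute the synthetic end-to-end pipeline and write one run directory.

    Stage outputs are TSV tables plus a JSON manifest carrying the config
    hash and seed; a rerun with the same config is bit-identical for the
    deterministic stages.  ``stages`` restricts execution (upstream outputs
    must then already exist in ``out_dir``).
    """
    from . import chd as chd_mod
    from . import dynamics as dyn_mod
    from . import isc as isc_mod
    from . import mvpa as mvpa_mod
    from . import neural_prep, synthetic_data, text_metrics

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    stages = stages or cfg["stages"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config_hash": _config_hash(cfg), "seed": seed,
                "stages": [], "timings": {}}

    design = synthetic_data.ExperimentDesign(seed=seed, **cfg["design"])
    effects = synthetic_data.PlantedEffects(**cfg["effects"])

    def _stage(name):
        def deco(fn):
            if name in stages:
                t0 = time.perf_counter()
                logger.info("stage %s: start (seed=%d)", name, seed)
                fn()
                manifest["stages"].append(name)
                manifest["timings"][name] = round(time.perf_counter() - t0, 3)
            return fn
        return deco

    data_dir = out / "data"

    @_stage("simulate")
    def _simulate():
        ds = synthetic_data.make_bold_experiment(design, effects)
        ds.write_tables(data_dir)

    def _load():
        if not (data_dir / "design.json").exists():
            raise FileNotFoundError(
                "missing simulated data; run the 'simulate' stage first")
        from .dataset import RoiTimeSeriesDataset
        return RoiTimeSeriesDataset.read_tables(data_dir)

    @_stage("text_metrics")
    def _text():
        vocab = [f"word{i:02d}" for i in range(40)]
        stories = synthetic_data.make_toy_stories(design, vocab)
        lex = synthetic_data.make_toy_lexicon(vocab, dimension=16, seed=seed)
        keys = [(s.story_id, i) for s in stories for i in range(3)]
        lm = synthetic_data.make_lm_table(vocab, keys, concentration=1.0,
                                          seed=seed)
        scored = text_metrics.score_stories(stories, [lex], [lm])
        mean_scores = text_metrics.aggregate_across_models(scored)
        mean_scores.write_tsv(out / "text_scores.tsv")

    @_stage("prep")
    def _prep():
        ds = neural_prep.extract_ideation(neural_prep.clean_dataset(_load()))
        ds.write_tables(out / "ideation")
        neural_prep.trialwise_variance_profile(ds).to_csv(
            out / "variance_profile.tsv", sep="\t", index=False)

    def _load_ideation():
        from .dataset import RoiTimeSeriesDataset
        path = out / "ideation"
        if not (path / "design.json").exists():
            raise FileNotFoundError(
                "missing ideation windows; run the 'prep' stage first")
        return RoiTimeSeriesDataset.read_tables(path)

    @_stage("isc")
    def _isc():
        ds = _load_ideation()
        frames = [isc_mod.isc_permutation_null(
            ds, c, n_iter=int(cfg["isc"]["n_iter"]), seed=seed + c).to_frame()
            for c in range(design.n_conditions)]
        import pandas as pd
        pd.concat(frames).to_csv(out / "isc.tsv", sep="\t", index=False)

    @_stage("mvpa")
    def _mvpa():
        ds = _load_ideation()
        config = mvpa_mod.ClassifierConfig(
            n_label_permutations=int(cfg["mvpa"]["n_label_permutations"]),
            seed=seed)
        perf = mvpa_mod.group_searchlight_classify(ds, 0, 1, config=config)
        perf.to_frame().to_csv(out / "mvpa_classify.tsv", sep="\t", index=False)

    @_stage("chd")
    def _chd():
        conn = synthetic_data.make_toy_connectome(
            cfg["chd"]["connectome"], int(cfg["chd"]["n_vertices"]))
        basis = chd_mod.compute_harmonics(conn)
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((design.ideation_volumes, conn.n))
        weights = chd_mod.project_signal(F, basis)
        spectrum = chd_mod.harmonic_windows(weights, window_frac=0.25,
                                            step_frac=0.125)
        np.savetxt(out / "harmonic_energy.tsv", spectrum.energies,
                   delimiter="\t")

    @_stage("dynamics")
    def _dynamics():
        ds = _load_ideation()
        import pandas as pd
        fc_frames, irr_frames = [], []
        for c in range(design.n_conditions):
            fc = dyn_mod.functional_connectivity(ds, c)
            fc_frames.append(fc.network_summary())
            tensor = dyn_mod.irreversibility(ds, c,
                                             lags=range(1, min(16, ds.n_volumes - 2)))
            irr_frames.append(dyn_mod.lag_cluster_summary(tensor))
        pd.concat(fc_frames).to_csv(out / "fc_networks.tsv", sep="\t", index=False)
        pd.concat(irr_frames).to_csv(out / "irreversibility.tsv", sep="\t",
                                     index=False)

    @_stage("stats")
    def _stats():
        import pandas as pd
        fc_path = out / "fc_networks.tsv"
        rows = []
        if fc_path.exists():
            fc = pd.read_csv(fc_path, sep="\t")
            for measure, grp in fc.groupby("measure"):
                wide = grp.pivot(index="participant", columns="condition",
                                 values="value")
                labels = list(wide.columns)
                for i in range(len(labels)):
                    for j in range(i + 1, len(labels)):
                        try:
                            cmp = paired_test(wide[labels[i]].to_numpy(),
                                              wide[labels[j]].to_numpy())
                        except ValidationError:
                            continue
                        rows.append({"measure": measure,
                                     "contrast": f"{labels[i]}-{labels[j]}",
                                     **asdict(cmp)})
        pd.DataFrame(rows).to_csv(out / "stats_summary.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
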