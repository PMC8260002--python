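"""End-to-end synthetic experiment orchestration.

``run_experiment`` wires the stages together: plant a ground-truth embedding
and brain, generate annotator description streams and simulated responses,
build the four feature-space kinds (trained, untrained x instances,
dimension-shuffled x instances, binary occurrence), fit and score voxelwise
encoding models, derive brain RDMs (all voxels plus a top-M selection curve
and per-category subsets), run simulated arrangement sessions to get a
behavior-derived RDM, and compare everything with permutation statistics.
All randomness flows from a single master seed through named per-stage
seeds, so a rerun with the same config reproduces every number exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .arrangement import run_session
from .encoding import (
    DEFAULT_DELAYS,
    default_lambda_grid,
    delay_embed_split,
    detrend_standardize,
    fit_encoding_model,
    region_summary,
    score_model,
    significant_fraction,
)
from .rdm import (
    average_rdms,
    collapse_delays,
    correlation_distance_rdm,
    intersect_rdms,
    project_words,
    read_rdm,
    select_voxels,
    subset_rdm,
    write_rdm,
)
from .stats import permutation_diff_pvalue, permutation_pvalue, rdm_correlation
from .synthetic import (
    DEFAULT_DELAY_GAINS,
    SyntheticGroundTruth,
    make_brain_truth,
    make_embedding_truth,
    make_scene_stream,
    simulate_responses,
    simulated_subject_place,
)
from .types import DissimilarityMatrix
from .wordsets import NOUN_CATEGORIES

__all__ = [
    "ExperimentConfig",
    "ExperimentBundle",
    "run_experiment",
    "make_report",
    "read_rdm",
    "write_rdm",
]

_STAGE_NAMES = (
    "embedding", "scenes", "brain", "responses", "untrained", "shuffled",
    "fit", "behavior", "permutation",
)


@dataclass
class ExperimentConfig:
    """Configuration for one synthetic experiment; JSON round-trippable."""

    master_seed: int = 0
    # embedding / vocabulary: n_categories * vocab_per_category words in total,
    # of which the 60 task nouns are the first 10 of each category (the task
    # word set is a small sample of the description vocabulary, as in natural
    # annotation corpora)
    n_dims: int = 50
    n_categories: int = 6
    vocab_per_category: int = 100
    within_category_corr: float = 0.6
    use_noun_vocabulary: bool = True
    # scene stream (training/test sample counts at TR = 1 s)
    n_train: int = 7200
    n_test: int = 1200
    n_annotators: int = 2
    words_per_description: int = 10
    topic_persistence: float = 0.9
    topic_fidelity: float = 0.7
    # brain
    n_voxels: int = 2000
    n_regions: int = 148
    tuned_fraction: float = 0.5
    noise_sd: float = 2.0
    delays: tuple[int, ...] = DEFAULT_DELAYS
    delay_gains: tuple[float, ...] = DEFAULT_DELAY_GAINS
    detrend_window_seconds: int = 120
    # model fitting
    lambda_grid: tuple[float, ...] | None = None
    n_resamples: int = 10
    train_fraction: float = 0.8
    feature_kinds: tuple[str, ...] = (
        "trained", "untrained", "dimension_shuffled", "binary",
    )
    n_control_instances: int = 5
    binary_top_n: int = 300
    # voxel selection curve (top-M values; "all" is always included)
    voxel_selection: tuple[int, ...] = ()
    # arrangement sessions
    n_sessions: int = 3
    position_noise: float = 0.05
    subset_size: int = 20
    max_trials: int = 25
    evidence_threshold: float = 0.75
    # statistics
    n_perm: int = 10_000

    def __post_init__(self) -> None:
        self.delays = tuple(int(d) for d in self.delays)
        self.delay_gains = tuple(float(g) for g in self.delay_gains)
        if self.lambda_grid is not None:
            self.lambda_grid = tuple(float(v) for v in self.lambda_grid)
        self.feature_kinds = tuple(self.feature_kinds)
        self.voxel_selection = tuple(int(m) for m in self.voxel_selection)
        if self.use_noun_vocabulary and (
            self.n_categories != 6 or self.vocab_per_category < 10
        ):
            raise ValueError(
                "the packaged noun vocabulary needs 6 categories of >= 10 words"
            )

    @property
    def n_words(self) -> int:
        return self.n_categories * self.vocab_per_category

    def vocabulary(self) -> tuple[list[str], list[str]]:
        """(full vocabulary labels, task word labels).

        With ``use_noun_vocabulary`` the 60 task nouns open each category
        block and synthetic filler words complete it; otherwise both are
        synthetic and the task words are the first 10 per category.
        """
        labels: list[str] = []
        task: list[str] = []
        for i in range(self.n_categories):
            if self.use_noun_vocabulary:
                from .wordsets import NOUN_CATEGORIES

                head = list(NOUN_CATEGORIES[list(NOUN_CATEGORIES)[i]])
            else:
                head = [f"cat{i}_word{j}" for j in range(min(10, self.vocab_per_category))]
            filler = [
                f"cat{i}_extra{j}"
                for j in range(self.vocab_per_category - len(head))
            ]
            labels += head + filler
            task += head
        return labels, task

    def resolved_lambda_grid(self) -> np.ndarray:
        if self.lambda_grid is None:
            return default_lambda_grid()
        return np.asarray(self.lambda_grid, dtype=float)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ExperimentConfig":
        """Load from a JSON string or file path; unknown keys are rejected."""
        text = source
        p = Path(str(source))
        if p.exists():
            text = p.read_text()
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds derived from the master seed (all < 2^31)."""
        ss = np.random.SeedSequence(self.master_seed)
        children = ss.spawn(len(_STAGE_NAMES))
        return {
            name: int(child.generate_state(1)[0] >> 1)
            for name, child in zip(_STAGE_NAMES, children)
        }


@dataclass
class ExperimentBundle:
    """Outputs of one experiment run, stage by stage."""

    config: ExperimentConfig
    truth: SyntheticGroundTruth
    descriptions: list
    profiles: dict = field(default_factory=dict)       # kind -> list of AccuracyProfile
    models: dict = field(default_factory=dict)         # kind -> list of EncodingModel
    brain_rdms: dict = field(default_factory=dict)     # kind -> averaged DissimilarityMatrix
    vector_rdm: DissimilarityMatrix | None = None
    behavior_rdm: DissimilarityMatrix | None = None
    voxel_curve: dict = field(default_factory=dict)    # selection -> rho
    category_rhos: dict = field(default_factory=dict)  # category -> rho
    stats: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _feature_spaces(config, truth, seeds):
    """Instances of each configured feature-space kind."""
    spaces = {}
    if "trained" in config.feature_kinds:
        spaces["trained"] = [truth.embedding_truth]
    if "untrained" in config.feature_kinds:
        rng = np.random.default_rng(seeds["untrained"])
        spaces["untrained"] = [
            feat.untrained_space(truth.embedding_truth, int(rng.integers(2**31)))
            for _ in range(config.n_control_instances)
        ]
    if "dimension_shuffled" in config.feature_kinds:
        rng = np.random.default_rng(seeds["shuffled"])
        spaces["dimension_shuffled"] = [
            feat.shuffle_dimensions(truth.embedding_truth, int(rng.integers(2**31)))
            for _ in range(config.n_control_instances)
        ]
    return spaces


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentBundle:
    """Execute the full synthetic experiment; optionally persist outputs."""
    t_start = time.time()
    seeds = config.stage_seeds()
    durations: dict[str, float] = {}

    def tick(stage):
        durations[stage] = time.time() - t_stage[0]
        t_stage[0] = time.time()

    t_stage = [time.time()]

    # --- ground truth -----------------------------------------------------
    vocab, task_words = config.vocabulary()
    embedding, category_of_word = make_embedding_truth(
        config.n_words, config.n_dims, config.n_categories,
        config.within_category_corr, seeds["embedding"], words=vocab,
    )
    if config.use_noun_vocabulary:
        names = list(NOUN_CATEGORIES)
        category_of_word = {
            w: names[int(c.removeprefix("cat"))]
            for w, c in category_of_word.items()
        }
    true_word_rdm = correlation_distance_rdm(embedding.vectors, embedding.words)
    task_rdm = subset_rdm(true_word_rdm, task_words)
    true_weights, region_labels = make_brain_truth(
        config.n_dims, config.n_voxels, config.n_regions,
        config.tuned_fraction, seeds["brain"],
    )
    truth = SyntheticGroundTruth(
        embedding_truth=embedding,
        category_of_word=category_of_word,
        true_weights=true_weights,
        noise_sd=config.noise_sd,
        true_word_rdm=true_word_rdm,
        master_seed=config.master_seed,
        region_labels=region_labels,
        delay_gains=config.delay_gains,
    )
    tick("truth")

    descriptions, scene_series = make_scene_stream(
        embedding,
        n_scenes=config.n_train + config.n_test,
        n_annotators=config.n_annotators,
        words_per_description=config.words_per_description,
        seed=seeds["scenes"],
        n_test=config.n_test,
        topic_persistence=config.topic_persistence,
        topic_fidelity=config.topic_fidelity,
    )
    raw = simulate_responses(
        scene_series, true_weights, delays=config.delays,
        gains=config.delay_gains, noise_sd=config.noise_sd,
        seed=seeds["responses"], region_labels=region_labels,
    )
    responses = detrend_standardize(
        raw.values, window_seconds=config.detrend_window_seconds,
        region_labels=region_labels, split=raw.split,
    )
    R_train, R_test = responses.train_values(), responses.test_values()
    tick("simulate")

    bundle = ExperimentBundle(config=config, truth=truth, descriptions=descriptions)

    # --- features + fits --------------------------------------------------
    spaces = _feature_spaces(config, truth, seeds)
    grid = config.resolved_lambda_grid()
    fit_rng = np.random.default_rng(seeds["fit"])

    for kind, instances in spaces.items():
        bundle.models[kind] = []
        bundle.profiles[kind] = []
        per_instance_rdms = []
        for space in instances:
            if kind == "trained":
                series = scene_series  # scene stream already computed on the truth
            else:
                series = feat.scene_feature_series(
                    descriptions, space,
                    n_scenes=config.n_train + config.n_test,
                    split=scene_series.split,
                )
            Xtr, Xte = delay_embed_split(series, config.delays)
            model = fit_encoding_model(
                Xtr, R_train, lambda_grid=grid,
                n_resamples=config.n_resamples,
                train_fraction=config.train_fraction,
                seed=int(fit_rng.integers(2**31)),
                delays=config.delays, feature_kind=kind,
            )
            profile = score_model(model, Xte, R_test)
            profile.region_labels = region_labels
            bundle.models[kind].append(model)
            bundle.profiles[kind].append(profile)
            collapsed = collapse_delays(model)
            per_instance_rdms.append(
                correlation_distance_rdm(
                    project_words(space.subset(task_words), collapsed),
                    task_words,
                )
            )
        bundle.brain_rdms[kind] = average_rdms(per_instance_rdms)

    if "binary" in config.feature_kinds:
        bin_vocab, series = feat.binary_scene_features(
            descriptions, top_n=config.binary_top_n,
            n_scenes=config.n_train + config.n_test, split=scene_series.split,
        )
        Xtr, Xte = delay_embed_split(series, config.delays)
        model = fit_encoding_model(
            Xtr, R_train, lambda_grid=grid, n_resamples=config.n_resamples,
            train_fraction=config.train_fraction,
            seed=int(fit_rng.integers(2**31)),
            delays=config.delays, feature_kind="binary",
        )
        profile = score_model(model, Xte, R_test)
        profile.region_labels = region_labels
        bundle.models["binary"] = [model]
        bundle.profiles["binary"] = [profile]
        # occurrence models: the collapsed weight rows ARE the word representations
        bundle.brain_rdms["binary"] = correlation_distance_rdm(
            collapse_delays(model), bin_vocab
        )
    tick("fit")

    # word-vector-derived RDM over the task words (no brain transform)
    bundle.vector_rdm = task_rdm

    # --- behavior ---------------------------------------------------------
    rng_beh = np.random.default_rng(seeds["behavior"])
    estimates = []
    session_lengths = []
    for _ in range(config.n_sessions):
        state, trials = run_session(
            task_words,
            lambda subset, s: simulated_subject_place(
                task_rdm, subset, config.position_noise, s
            ),
            evidence_threshold=config.evidence_threshold,
            max_trials=config.max_trials,
            subset_size=config.subset_size,
            seed=int(rng_beh.integers(2**31)),
        )
        estimates.append(state.estimate)
        session_lengths.append(len(trials))
    bundle.behavior_rdm = average_rdms(estimates)
    bundle.stats["session_lengths"] = session_lengths
    tick("behavior")

    # --- statistics -------------------------------------------------------
    perm_rng = np.random.default_rng(seeds["permutation"])
    behavior = bundle.behavior_rdm
    for kind, rdm in bundle.brain_rdms.items():
        beh_k, rdm_k = intersect_rdms(behavior, rdm)
        res = permutation_pvalue(
            beh_k, rdm_k, n_perm=config.n_perm, seed=int(perm_rng.integers(2**31))
        )
        bundle.stats[f"brain_behavior_{kind}"] = {
            "rho": res.observed, "p": res.p_value, "n_words": rdm_k.n_items,
        }
    res = permutation_pvalue(
        behavior, bundle.vector_rdm, n_perm=config.n_perm,
        seed=int(perm_rng.integers(2**31)),
    )
    bundle.stats["vector_behavior"] = {"rho": res.observed, "p": res.p_value,
                                       "n_words": behavior.n_items}
    if "trained" in bundle.brain_rdms and "dimension_shuffled" in bundle.brain_rdms:
        res = permutation_diff_pvalue(
            (behavior, bundle.brain_rdms["trained"]),
            (behavior, bundle.brain_rdms["dimension_shuffled"]),
            n_perm=config.n_perm, seed=int(perm_rng.integers(2**31)),
        )
        bundle.stats["trained_vs_shuffled_diff"] = {
            "delta_rho": res.observed, "p": res.p_value,
        }

    # voxel-selection curve and per-category correlations use the trained model
    if "trained" in bundle.models:
        model = bundle.models["trained"][0]
        profile = bundle.profiles["trained"][0]
        collapsed = collapse_delays(model)
        vectors = embedding.subset(task_words)
        selections: list[tuple[str, np.ndarray]] = [
            ("all", select_voxels(profile, "all"))
        ]
        for m in config.voxel_selection:
            if m <= config.n_voxels:
                selections.append((str(m), select_voxels(profile, "top_m", m)))
        for name, voxels in selections:
            rdm_sel = correlation_distance_rdm(
                project_words(vectors, collapsed, voxels), task_words
            )
            bundle.voxel_curve[name] = rdm_correlation(behavior, rdm_sel)
        trained_rdm = bundle.brain_rdms["trained"]
        for cat in sorted(set(category_of_word.values())):
            members = [w for w in task_words if category_of_word[w] == cat]
            if len(members) >= 3:
                bundle.category_rhos[cat] = rdm_correlation(
                    subset_rdm(behavior, members), subset_rdm(trained_rdm, members)
                )
    tick("stats")

    bundle.manifest = {
        "config": json.loads(config.to_json()),
        "stage_seeds": seeds,
        "stage_durations_s": {k: round(v, 3) for k, v in durations.items()},
        "total_seconds": round(time.time() - t_start, 3),
    }
    if out_dir is not None:
        _persist(bundle, Path(out_dir))
    return bundle


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(bundle: ExperimentBundle) -> dict:
    """Summary tables (DataFrames) and a JSON-serializable metrics dict."""
    missing = [
        name
        for name, ok in [
            ("profiles", bool(bundle.profiles)),
            ("brain_rdms", bool(bundle.brain_rdms)),
            ("behavior_rdm", bundle.behavior_rdm is not None),
            ("stats", bool(bundle.stats)),
        ]
        if not ok
    ]
    if missing:
        raise ValueError(f"bundle is missing stage outputs: {missing}")

    perf_rows = []
    for kind, profiles in bundle.profiles.items():
        for i, (profile, model) in enumerate(
            zip(profiles, bundle.models[kind])
        ):
            perf_rows.append(
                {
                    "feature_kind": kind,
                    "instance": i,
                    "mean_r": float(profile.per_voxel_r.mean()),
                    "significant_fraction": significant_fraction(profile),
                    "lambda": model.lambda_,
                }
            )
    performance = pd.DataFrame(perf_rows)

    bb_rows = [
        {"comparison": key, **val}
        for key, val in bundle.stats.items()
        if isinstance(val, dict) and "rho" in val
    ]
    brain_behavior = pd.DataFrame(bb_rows)

    regions = None
    if "trained" in bundle.profiles:
        regions = region_summary(bundle.profiles["trained"][0])

    voxel_curve = pd.DataFrame(
        [{"selection": k, "rho": v} for k, v in bundle.voxel_curve.items()]
    )
    categories = pd.DataFrame(
        [{"category": k, "rho": v} for k, v in bundle.category_rhos.items()]
    )

    metrics = {
        "performance": perf_rows,
        "brain_behavior": bb_rows,
        "voxel_selection_curve": bundle.voxel_curve,
        "category_rhos": bundle.category_rhos,
        "session_lengths": bundle.stats.get("session_lengths", []),
        "diff_tests": {
            k: v
            for k, v in bundle.stats.items()
            if isinstance(v, dict) and "delta_rho" in v
        },
    }
    report = {
        "performance": performance,
        "brain_behavior": brain_behavior,
        "voxel_selection": voxel_curve,
        "categories": categories,
        "metrics": metrics,
    }
    if regions is not None:
        report["regions"] = regions
    return report


def _persist(bundle: ExperimentBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
    report = make_report(bundle)
    for name in ("performance", "brain_behavior", "voxel_selection", "categories"):
        report[name].to_csv(out_dir / f"{name}.csv", index=False)
    if "regions" in report:
        report["regions"].to_csv(out_dir / "regions.csv")
    (out_dir / "metrics.json").write_text(
        json.dumps(report["metrics"], indent=2, sort_keys=True) + "\n"
    )
    for kind, rdm in bundle.brain_rdms.items():
        write_rdm(rdm, out_dir / f"rdm_brain_{kind}.csv")
    if bundle.behavior_rdm is not None:
        write_rdm(bundle.behavior_rdm, out_dir / "rdm_behavior.csv")
    if bundle.vector_rdm is not None:
        write_rdm(bundle.vector_rdm, out_dir / "rdm_vector.csv")
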