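"""Benchmark orchestration: condition sweep, datasets, CV, ANOVA.

The evaluation design crosses the number of active fascicles (classes:
3, 5, 7, 10) with the noise ratio (5%, 10%, 15%) — 12 conditions.  Each
condition is repeated 10 times with a fresh random fascicle selection and
dataset; every dataset holds 30,000 class-balanced nCAP signatures and is
scored by stratified threefold cross-validation.  Accuracies are
summarized per condition as mean ± SD across repetitions, and a two-way
fixed-effects ANOVA (classes × noise, with interaction) quantifies the
factor influences.  A fascicle-distance analysis correlates each
repetition's mean pairwise centroid distance with its accuracy.

The ``desk`` profile shrinks the dataset to 6,000 samples, 3 repetitions
and a 1/16-width network so a condition runs on one CPU in minutes while
keeping every protocol ratio (balance, folds, noise) intact.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from cuffsim import models as models_mod
from cuffsim import signatures as sig_mod
from cuffsim import simulate as sim_mod
from cuffsim.forward import Leadfield
from cuffsim.geometry import CrossSectionModel, ElectrodeLayout


class ExperimentError(ValueError):
    """Invalid experiment configuration."""


# ---------------------------------------------------------------------------
# Sweep planning
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Run:
    class_count: int
    noise_ratio: float
    repetition: int
    seed: int


@dataclasses.dataclass
class SweepPlan:
    class_counts: list[int]
    noise_ratios: list[float]
    repetitions: int
    folds: int
    dataset_size: int
    master_seed: int
    runs: list[Run]

    @property
    def n_conditions(self) -> int:
        return len(self.class_counts) * len(self.noise_ratios)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic, collision-resistant child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def plan_sweep(
    class_counts: list[int] | None = None,
    noise_ratios: list[float] | None = None,
    repetitions: int = 10,
    folds: int = 3,
    dataset_size: int = 30000,
    master_seed: int = 0,
) -> SweepPlan:
    """Enumerate (class count, noise, repetition) runs with derived seeds."""
    class_counts = class_counts if class_counts is not None else [3, 5, 7, 10]
    noise_ratios = noise_ratios if noise_ratios is not None else [0.05, 0.10, 0.15]
    if not class_counts or not noise_ratios:
        raise ExperimentError("class_counts and noise_ratios must be non-empty")
    if repetitions < 1:
        raise ExperimentError("repetitions must be >= 1")
    runs = [
        Run(
            class_count=c,
            noise_ratio=n,
            repetition=r,
            seed=derive_seed(master_seed, ci, ni, r),
        )
        for ci, c in enumerate(class_counts)
        for ni, n in enumerate(noise_ratios)
        for r in range(repetitions)
    ]
    return SweepPlan(
        class_counts=list(class_counts),
        noise_ratios=list(noise_ratios),
        repetitions=repetitions,
        folds=folds,
        dataset_size=dataset_size,
        master_seed=master_seed,
        runs=runs,
    )


# ---------------------------------------------------------------------------
# Fascicle selection and dataset construction
# ---------------------------------------------------------------------------


def select_fascicles(
    available: np.ndarray | list[int], c: int, seed: int
) -> np.ndarray:
    """Uniformly sample ``c`` fascicle ids without replacement."""
    available = np.asarray(available)
    if c > available.size:
        raise ExperimentError(
            f"cannot select {c} fascicles from {available.size}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(available, size=c, replace=False))


@dataclasses.dataclass
class ExperimentDataset:
    """Balanced signature dataset for one run.

    ``recordings`` holds the referenced, noisy, normalized 56 x 100
    recordings in canonical channel order; SE/TE views are materialized on
    demand through the layout's permutation tables.
    """

    recordings: np.ndarray  # (n, 56, T) float32
    labels: np.ndarray  # (n,) int
    fascicle_ids: np.ndarray  # (c,) chosen fascicles; labels index into this
    layout: ElectrodeLayout
    sample_fascicle: np.ndarray  # (n,) source fascicle id
    sample_node: np.ndarray  # (n,) cross-section node index
    sample_template: np.ndarray  # (n,) waveform template index
    noise_ratio: float
    seed: int

    @property
    def n_samples(self) -> int:
        return self.recordings.shape[0]

    def se(self) -> np.ndarray:
        perm = sig_mod.se_permutation(self.layout)
        return self.recordings[:, perm, :][:, None, :, :]

    def te(self) -> np.ndarray:
        perm = sig_mod.te_permutation(self.layout)
        return self.recordings[:, perm, :][:, None, :, :]


def build_dataset(
    leadfield: Leadfield,
    bank: sim_mod.WaveformBank,
    fascicle_ids: np.ndarray | list[int],
    noise_ratio: float,
    size: int,
    seed: int,
    conduction_velocity: float = 60.0,
    node_spacing: float = 1.0,
) -> ExperimentDataset:
    """Simulate a class-balanced dataset of noisy, normalized recordings.

    Each sample draws a waveform template and a cross-section source node
    uniformly at random within its class fascicle, synthesizes D = L·J,
    adds noise at ``noise_ratio`` and normalizes.  When ``size`` is not
    divisible by the class count, per-class counts are floor(size / c) and
    the remainder is dropped, keeping classes exactly balanced.
    """
    leadfield = leadfield.with_montage()
    fascicle_ids = np.asarray(fascicle_ids)
    c = fascicle_ids.size
    per_class = size // c
    if per_class < 1:
        raise ExperimentError("dataset smaller than the class count")
    node_pool = []
    for fid in fascicle_ids:
        nodes = leadfield.nodes_of_fascicle(int(fid))
        if nodes.size == 0:
            raise ExperimentError(f"fascicle {fid} has no registered source nodes")
        node_pool.append(nodes)
    rng = np.random.default_rng(seed)
    n = per_class * c
    labels = np.repeat(np.arange(c), per_class)
    rng.shuffle(labels)
    m = leadfield.matrix.shape[0]
    t_samples = bank.n_samples
    recordings = np.empty((n, m, t_samples), dtype=np.float32)
    sample_node = np.empty(n, dtype=np.int64)
    sample_template = np.empty(n, dtype=np.int64)
    for i in range(n):
        label = labels[i]
        node = int(rng.choice(node_pool[label]))
        template = int(rng.integers(bank.n_templates))
        event = sim_mod.SourceEvent(
            fascicle_id=int(fascicle_ids[label]),
            node=node,
            template_index=template,
            conduction_velocity=conduction_velocity,
            node_spacing=node_spacing,
        )
        J = sim_mod.build_source_matrix(event, bank, leadfield)
        rec = sim_mod.synthesize_recording(leadfield, J)
        rec = sim_mod.add_noise(rec, noise_ratio, rng)
        rec = sim_mod.normalize_recording(rec)
        recordings[i] = rec.data
        sample_node[i] = node
        sample_template[i] = template
    return ExperimentDataset(
        recordings=recordings,
        labels=labels,
        fascicle_ids=fascicle_ids,
        layout=leadfield.layout,
        sample_fascicle=fascicle_ids[labels],
        sample_node=sample_node,
        sample_template=sample_template,
        noise_ratio=noise_ratio,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified partition: test-index arrays, one per fold."""
    if folds < 2:
        raise ExperimentError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(labels.size, dtype=int)
    # stagger the remainder across classes so fold totals stay exactly
    # equal when the dataset size divides the fold count
    for ci, cls in enumerate(np.unique(labels)):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        if idx.size < folds:
            raise ExperimentError(f"class {cls} has fewer samples than folds")
        assignments[idx] = (np.arange(idx.size) + ci) % folds
    return [np.flatnonzero(assignments == k) for k in range(folds)]


class CNNEstimator:
    """fit/predict adapter wrapping the two-stream classifier."""

    def __init__(
        self,
        spec: models_mod.ModelSpec,
        config: models_mod.TrainConfig,
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.config = config
        self.seed = seed
        self.trained: models_mod.TrainedModel | None = None

    def fit(self, x_se: np.ndarray, x_te: np.ndarray, labels: np.ndarray) -> None:
        model = models_mod.build_model(self.spec, seed=self.seed)
        config = dataclasses.replace(self.config, seed=self.seed)
        self.trained = models_mod.train(model, x_se, x_te, labels, config)

    def predict(self, x_se: np.ndarray, x_te: np.ndarray) -> np.ndarray:
        if self.trained is None:
            raise ExperimentError("estimator is not fitted")
        _, pred = self.trained.predict(x_se, x_te)
        return pred


def crossvalidate(
    dataset: ExperimentDataset,
    estimator_factory,
    folds: int = 3,
    seed: int = 0,
) -> list[float]:
    """Stratified k-fold accuracies for one dataset.

    ``estimator_factory(fold_index)`` must return an object with
    ``fit(x_se, x_te, labels)`` and ``predict(x_se, x_te)``.
    """
    x_se, x_te = dataset.se(), dataset.te()
    labels = dataset.labels
    test_folds = stratified_folds(labels, folds, seed)
    accuracies = []
    for k, test_idx in enumerate(test_folds):
        train_mask = np.ones(labels.size, dtype=bool)
        train_mask[test_idx] = False
        est = estimator_factory(k)
        est.fit(x_se[train_mask], x_te[train_mask], labels[train_mask])
        pred = est.predict(x_se[test_idx], x_te[test_idx])
        accuracies.append(float(np.mean(pred == labels[test_idx])))
    return accuracies


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def two_way_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``table`` needs columns ``value`` (accuracy), ``class_count`` and
    ``noise`` (factor levels).  Returns rows class, noise, interaction and
    residual with sum_sq, df, F and PR(>F); the default sweep shape
    (4 x 3 x 10) gives the interaction test F(6, 108).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("value", "class_count", "noise"):
        if col not in table.columns:
            raise ExperimentError(f"missing column {col!r}")
    counts = table.groupby(["class_count", "noise"]).size()
    if counts.nunique() != 1:
        raise ExperimentError("unbalanced cells: equal replicates required")
    if counts.iloc[0] < 2:
        raise ExperimentError("need >= 2 replicates per cell")
    if table["class_count"].nunique() < 2 or table["noise"].nunique() < 2:
        raise ExperimentError("need >= 2 levels per factor")
    model = smf.ols(
        "value ~ C(class_count) * C(noise)", data=table
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = ["class", "noise", "interaction", "residual"]
    return anova


@dataclasses.dataclass
class DistanceAnalysis:
    table: pd.DataFrame  # per repetition: mean_distance, mean_accuracy
    pearson_r: float | None
    p_value: float | None
    undefined: bool = False


def mean_pairwise_distance(
    cross_section: CrossSectionModel, fascicle_ids: np.ndarray
) -> float:
    """Mean pairwise centroid distance (mm) of the selected fascicles."""
    cent = np.array(cross_section.fascicle_centroids)
    sel = cent[np.asarray(fascicle_ids) - 1]  # ids are 1-based
    if sel.shape[0] < 2:
        return 0.0
    d = np.hypot(
        sel[:, None, 0] - sel[None, :, 0], sel[:, None, 1] - sel[None, :, 1]
    )
    iu = np.triu_indices(sel.shape[0], k=1)
    return float(d[iu].mean())


def fascicle_distance_analysis(
    per_repetition: pd.DataFrame,
) -> DistanceAnalysis:
    """Correlate per-repetition fascicle spread with accuracy.

    ``per_repetition`` needs columns ``mean_distance`` and
    ``mean_accuracy`` (one row per repetition).  A zero-variance input
    yields an explicitly undefined correlation rather than a silent NaN.
    """
    if per_repetition.shape[0] < 3:
        raise ExperimentError("need >= 3 repetitions for a correlation")
    x = per_repetition["mean_distance"].to_numpy(dtype=float)
    y = per_repetition["mean_accuracy"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DistanceAnalysis(
            table=per_repetition, pearson_r=None, p_value=None, undefined=True
        )
    r, p = sp_stats.pearsonr(x, y)
    return DistanceAnalysis(
        table=per_repetition, pearson_r=float(r), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# Condition runner
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConditionResult:
    class_count: int
    noise_ratio: float
    rows: pd.DataFrame  # repetition, fold, accuracy, mean_distance
    mean_accuracy: float
    std_accuracy: float  # SD across repetitions of per-repetition means


def run_condition(
    leadfield: Leadfield,
    bank: sim_mod.WaveformBank,
    cross_section: CrossSectionModel,
    class_count: int,
    noise_ratio: float,
    repetitions: int,
    dataset_size: int,
    model_spec: models_mod.ModelSpec | None = None,
    train_config: models_mod.TrainConfig | None = None,
    folds: int = 3,
    master_seed: int = 0,
    estimator_factory=None,
    verbose: bool = False,
) -> ConditionResult:
    """Run one sweep condition: repetitions x stratified k-fold CV.

    Each repetition redraws the fascicle selection and the dataset
    noise/waveform seeds.  ``estimator_factory(seed)`` overrides the CNN
    (used by stub-classifier checks); by default a fresh desk-profile
    two-stream network is trained per fold.
    """
    model_spec = model_spec or models_mod.ModelSpec.desk(n_classes=class_count)
    train_config = train_config or models_mod.TrainConfig.for_backbone(
        model_spec.backbone
    )
    available = np.arange(1, cross_section.n_fascicles + 1)
    rows = []
    for rep in range(repetitions):
        rep_seed = derive_seed(master_seed, class_count, int(noise_ratio * 1000), rep)
        chosen = select_fascicles(available, class_count, rep_seed)
        dataset = build_dataset(
            leadfield, bank, chosen, noise_ratio, dataset_size, rep_seed
        )
        dist = mean_pairwise_distance(cross_section, chosen)
        if estimator_factory is None:
            def factory(fold, _seed=rep_seed):
                return CNNEstimator(
                    model_spec, train_config, seed=derive_seed(_seed, fold)
                )
        else:
            def factory(fold, _seed=rep_seed):
                return estimator_factory(derive_seed(_seed, fold))
        accs = crossvalidate(dataset, factory, folds=folds, seed=rep_seed)
        for fold, acc in enumerate(accs):
            rows.append(
                {
                    "class_count": class_count,
                    "noise": noise_ratio,
                    "repetition": rep,
                    "fold": fold,
                    "accuracy": acc,
                    "mean_distance": dist,
                }
            )
        if verbose:
            print(
                f"condition c={class_count} n={noise_ratio}: rep {rep} "
                f"accuracies {np.round(accs, 4)}",
                flush=True,
            )
    df = pd.DataFrame(rows)
    rep_means = df.groupby("repetition")["accuracy"].mean()
    return ConditionResult(
        class_count=class_count,
        noise_ratio=noise_ratio,
        rows=df,
        mean_accuracy=float(rep_means.mean()),
        std_accuracy=float(rep_means.std(ddof=1)) if repetitions > 1 else 0.0,
    )
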