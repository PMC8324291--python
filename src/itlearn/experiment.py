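"""End-to-end simulated unsupervised learning experiments.

A simulated "subject" is a freshly sampled IT population plus frozen 2AFC
decoders for the planned sub-tasks. The subject alternates test phases
(200 trials: size-test, baseline and cover images for two object pairs)
with unsupervised exposure phases (swapped or non-swapped event schedules at
one size pair), and the change in pooled d' relative to the first test phase
is tracked per sub-task. The learning effect is the d' change for the target
pair minus the d' change for the control pair at the exposed size. Designs:

* u1 — four swapped epochs (breaks size tolerance),
* u2 — four non-swapped epochs (builds it),
* u3 — two non-swapped then two swapped epochs (build, then break),
* sweep — one 800-event swapped epoch bracketed by two test phases, run
  over a bank of tasks spanning initial difficulty.

Test phases cause no plasticity (the model assumes IT makes no net
unsupervised changes during testing); cover trials are generated and
classified for structural fidelity but excluded from all analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decoder import (
    Confusion2AFC,
    DecoderSpec,
    TrainedDecoder,
    _corr_scores,
    pooled_dprime,
    run_subtask,
    train_decoder,
)
from .plasticity import ExposurePhaseSpec, PlasticityConfig, run_exposure_phase
from .population import BIG, MEDIUM, SMALL, ITPopulation, sample_population
from .stats import ITPopulationStats, ValidationError

__all__ = [
    "ExperimentDesign",
    "TestPhasePlan",
    "SubjectResult",
    "LearningEffect",
    "EnsembleResult",
    "build_test_phase",
    "run_single_model_subject",
    "learning_effect",
    "average_model_runs",
    "rate_robustness_variants",
    "hyperparameter_robustness",
    "difficulty_sweep",
    "build_task_bank",
    "SweepTask",
]

_OTHER_SIZE = {BIG: SMALL, SMALL: BIG}

#: per-object trial counts in one 200-trial test phase
_COUNTS = {"small": 10, "big": 10, "baseline": 5, "cover": 25}


@dataclass
class ExperimentDesign:
    """A longitudinal unsupervised-exposure experiment."""

    name: str
    epoch_flavors: tuple[str, ...]
    events_per_epoch: int
    target_objects: tuple[int, int]
    control_objects: tuple[int, int]
    exposed_size: int = BIG
    lapse_rate: float = 0.0
    n_model_runs: int = 100
    alpha: float = 0.0016
    decoder: DecoderSpec = field(default_factory=DecoderSpec)

    def __post_init__(self) -> None:
        if set(self.target_objects) & set(self.control_objects):
            raise ValidationError("target and control pairs must be disjoint")
        if self.exposed_size not in (SMALL, BIG):
            raise ValidationError("exposed size must be small or big (medium is the hub)")
        for f in self.epoch_flavors:
            if f not in ("swapped", "non_swapped"):
                raise ValidationError(f"unknown flavor {f!r}")

    @property
    def n_test_phases(self) -> int:
        return len(self.epoch_flavors) + 1

    @property
    def non_exposed_size(self) -> int:
        return _OTHER_SIZE[self.exposed_size]

    @property
    def size_pair(self) -> tuple[int, int]:
        return (MEDIUM, self.exposed_size)

    @property
    def event_axis(self) -> np.ndarray:
        return np.arange(self.n_test_phases) * float(self.events_per_epoch)

    def analysis_keys(self) -> dict[str, tuple[str, int]]:
        return {
            "target_exposed": ("target", self.exposed_size),
            "control_exposed": ("control", self.exposed_size),
            "target_nonexposed": ("target", self.non_exposed_size),
        }

    # -- factories ----------------------------------------------------------
    @classmethod
    def u1(cls, **kw) -> "ExperimentDesign":
        return cls._make("u1", ("swapped",) * 4, 400, **kw)

    @classmethod
    def u2(cls, **kw) -> "ExperimentDesign":
        return cls._make("u2", ("non_swapped",) * 4, 400, **kw)

    @classmethod
    def u3(cls, **kw) -> "ExperimentDesign":
        return cls._make(
            "u3", ("non_swapped", "non_swapped", "swapped", "swapped"), 400, **kw
        )

    @classmethod
    def sweep(cls, **kw) -> "ExperimentDesign":
        return cls._make("sweep", ("swapped",), 800, **kw)

    @classmethod
    def _make(cls, name, flavors, events, **kw) -> "ExperimentDesign":
        kw.setdefault("target_objects", (40, 41))
        kw.setdefault("control_objects", (42, 43))
        kw.setdefault("events_per_epoch", events)
        return cls(name=name, epoch_flavors=flavors, **kw)


@dataclass
class TestPhasePlan:
    """Ordered 200-trial plan: size tests, medium baselines, and cover trials."""

    trials: pd.DataFrame  # columns: trial, object, pair, size, role, subtask, analysis
    subtasks: list[tuple[str, int]]  # the six (pair, size) sub-tasks

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_test_phase(design: ExperimentDesign, seed: int = 0) -> TestPhasePlan:
    """Lay out one test phase.

    Per object (four objects): 10 small + 10 big size-test trials, 5 medium
    baselines, and 25 cover trials (excluded from analysis). Trial order is
    randomized. Enumerates the six size-specific sub-tasks (2 pairs x 3
    sizes), of which three are analysis sub-tasks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    pairs = {"target": design.target_objects, "control": design.control_objects}
    for pair_name, objs in pairs.items():
        for obj in objs:
            for size, role, count in (
                (SMALL, "size_test", _COUNTS["small"]),
                (BIG, "size_test", _COUNTS["big"]),
                (MEDIUM, "baseline", _COUNTS["baseline"]),
            ):
                for _ in range(count):
                    rows.append((obj, pair_name, size, role, f"{pair_name}@{size}", True))
            for _ in range(_COUNTS["cover"]):
                # cover images vary mildly in all view parameters; abstracted
                # as a random-size condition flagged out of the analyses
                rows.append(
                    (obj, pair_name, int(rng.integers(3)), "cover", "cover", False)
                )
    df = pd.DataFrame(
        rows, columns=["object", "pair", "size", "role", "subtask", "analysis"]
    )
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    df.insert(0, "trial", np.arange(len(df)))
    subtasks = [(p, z) for p in ("target", "control") for z in (SMALL, MEDIUM, BIG)]
    return TestPhasePlan(trials=df, subtasks=subtasks)


@dataclass
class SubjectResult:
    """Per-phase pooled d' (and trials) for one simulated subject."""

    design: ExperimentDesign
    events: np.ndarray
    dprime: dict[tuple[str, int], np.ndarray]
    confusions: dict[tuple[str, int], list[Confusion2AFC]]
    trials: dict[tuple[str, int], list[pd.DataFrame]]
    population: ITPopulation | None = None
    initial_base: np.ndarray | None = None  # clean responses before exposure

    def delta(self, key: tuple[str, int]) -> np.ndarray:
        """d' change relative to the first (pre-exposure) test phase."""
        d = self.dprime[key]
        return d - d[0]


@dataclass
class LearningEffect:
    """Target-minus-control d' change at the exposed size, per test phase."""

    events: np.ndarray
    effect: np.ndarray
    se: np.ndarray | None = None
    p: np.ndarray | None = None


def _run_cover_trials(
    pop: ITPopulation,
    decoders: dict[str, TrainedDecoder],
    plan: TestPhasePlan,
    rng: np.random.Generator,
) -> None:
    """Generate and classify the cover trials; results are discarded."""
    cover = plan.trials[plan.trials["role"] == "cover"]
    for (pair_name, size), grp in cover.groupby(["pair", "size"]):
        dec = decoders[pair_name]
        for obj, sub in grp.groupby("object"):
            ids = pop.new_exemplar_ids(len(sub))
            means = pop.mean_responses(int(obj), int(size), ids)[:, dec.site_idx]
            resp = means + rng.normal(size=means.shape) * np.sqrt(
                pop.stats.repetition_variance(means)
            )
            _corr_scores(dec.templates, resp)  # choices not analyzed


def _run_test_phase(
    pop: ITPopulation,
    decoders: dict[str, TrainedDecoder],
    design: ExperimentDesign,
    plan: TestPhasePlan,
    seed: int,
) -> tuple[dict, dict]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0x7E,))
    sub_seeds = ss.spawn(len(plan.subtasks) + 1)
    confs, trials = {}, {}
    for (pair_name, size), s in zip(plan.subtasks, sub_seeds):
        n = int(
            plan.trials[
                (plan.trials["subtask"] == f"{pair_name}@{size}")
                & plan.trials["analysis"]
            ].shape[0]
        )
        conf, table = run_subtask(
            pop,
            decoders[pair_name],
            size,
            n,
            lapse_rate=design.lapse_rate,
            seed=int(s.generate_state(1)[0] % 2**31),
        )
        confs[(pair_name, size)] = conf
        trials[(pair_name, size)] = table
    cover_rng = np.random.default_rng(sub_seeds[-1])
    _run_cover_trials(pop, decoders, plan, cover_rng)
    return confs, trials


def run_single_model_subject(
    design: ExperimentDesign,
    stats: ITPopulationStats,
    seed: int = 0,
    keep_trials: bool = True,
) -> SubjectResult:
    """Simulate one subject: sample, train+freeze decoders, test/expose/test...

    A fresh population is drawn; decoders for the target and control pairs
    are trained on generated training images and frozen; test phases and
    exposure phases alternate per the design; pooled d' per sub-task per
    phase and the trial tables are returned.
    """
    ss = np.random.SeedSequence(seed)
    (pop_s, dec_t_s, dec_c_s), rest = ss.spawn(3), ss.spawn(2 * design.n_test_phases)

    def as_int(s) -> int:
        return int(s.generate_state(1)[0] % 2**31)

    pop = sample_population(stats, design.decoder.n_sites, seed=as_int(pop_s))
    decoders = {
        "target": train_decoder(
            pop, design.target_objects, replace(design.decoder, seed=as_int(dec_t_s))
        ),
        "control": train_decoder(
            pop, design.control_objects, replace(design.decoder, seed=as_int(dec_c_s))
        ),
    }
    cfg = PlasticityConfig(alpha=design.alpha)

    initial_base = pop.base.copy()
    keys = [(p, z) for p in ("target", "control") for z in (SMALL, MEDIUM, BIG)]
    dprime = {k: np.zeros(design.n_test_phases) for k in keys}
    confusions = {k: [] for k in keys}
    trials = {k: [] for k in keys}

    for phase in range(design.n_test_phases):
        plan = build_test_phase(design, seed=as_int(rest[2 * phase]))
        confs, tabs = _run_test_phase(
            pop, decoders, design, plan, seed=as_int(rest[2 * phase])
        )
        for k in keys:
            dprime[k][phase] = pooled_dprime(confs[k]).dprime
            confusions[k].append(confs[k])
            if keep_trials:
                trials[k].append(tabs[k])
        if phase < len(design.epoch_flavors):
            spec = ExposurePhaseSpec(
                flavor=design.epoch_flavors[phase],
                objects=design.target_objects,
                size_pair=design.size_pair,
                n_events=design.events_per_epoch,
                seed=as_int(rest[2 * phase + 1]),
            )
            run_exposure_phase(pop, spec, cfg)

    return SubjectResult(
        design=design,
        events=design.event_axis,
        dprime=dprime,
        confusions=confusions,
        trials=trials,
        population=pop,
        initial_base=initial_base,
    )


def learning_effect(subject: SubjectResult, n_boot: int = 0, seed: int = 0) -> LearningEffect:
    """Target-minus-control d' change at the exposed size.

    With ``n_boot`` > 0, trials of the four involved (sub-task, phase) cells
    are resampled jointly to give a bootstrap SE and a two-sided p-value per
    phase.
    """
    design = subject.design
    kt = ("target", design.exposed_size)
    kc = ("control", design.exposed_size)
    if len(subject.dprime[kt]) != len(subject.dprime[kc]):
        raise ValidationError("target and control curves are misaligned")
    effect = subject.delta(kt) - subject.delta(kc)
    se = p = None
    if n_boot > 0:
        if not subject.trials[kt]:
            raise ValidationError("trial tables were not kept; cannot bootstrap")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_phases = len(effect)
        se = np.zeros(n_phases)
        p = np.ones(n_phases)

        def boot(table: pd.DataFrame, positive: int) -> np.ndarray:
            truth = table["true_object"].to_numpy() == positive
            chose = table["choice"].to_numpy() == positive
            n = len(table)
            idx = rng.integers(n, size=(n_boot, n))
            t, c = truth[idx], chose[idx]
            eps = 1e-4
            tpr = np.clip((t & c).sum(1) / np.maximum(t.sum(1), 1), eps, 1 - eps)
            fpr = np.clip(
                ((~t) & c).sum(1) / np.maximum((~t).sum(1), 1), eps, 1 - eps
            )
            from scipy.stats import norm

            return norm.ppf(tpr) - norm.ppf(fpr)

        for ph in range(1, n_phases):
            draws = (
                boot(subject.trials[kt][ph], design.target_objects[0])
                - boot(subject.trials[kt][0], design.target_objects[0])
                - boot(subject.trials[kc][ph], design.control_objects[0])
                + boot(subject.trials[kc][0], design.control_objects[0])
            )
            se[ph] = draws.std(ddof=1)
            p[ph] = min(1.0, 2 * min((draws <= 0).mean(), (draws >= 0).mean()))
    return LearningEffect(events=subject.events, effect=effect, se=se, p=p)


@dataclass
class EnsembleResult:
    """Mean learning effect over independent model runs."""

    design: ExperimentDesign
    events: np.ndarray
    per_run_effects: np.ndarray  # (n_runs, n_phases)
    per_run_delta: dict[str, np.ndarray]  # analysis key -> (n_runs, n_phases)
    pooled_confusions: dict[tuple[str, int], list[Confusion2AFC]]

    @property
    def mean_effect(self) -> np.ndarray:
        return self.per_run_effects.mean(axis=0)

    @property
    def se_effect(self) -> np.ndarray:
        n = self.per_run_effects.shape[0]
        return self.per_run_effects.std(axis=0, ddof=1) / np.sqrt(n)

    def pooled_dprime_curve(self, key: tuple[str, int]) -> np.ndarray:
        return np.array([pooled_dprime(c).dprime for c in self.pooled_confusions[key]])


def average_model_runs(
    design: ExperimentDesign,
    stats: ITPopulationStats,
    n_runs: int | None = None,
    base_seed: int = 0,
) -> EnsembleResult:
    """Repeat the single-subject simulation and average the learning effect.

    Runs are fully independent (fresh population, decoders, exemplars, and
    event orders); the SE is over runs.
    """
    n_runs = n_runs if n_runs is not None else design.n_model_runs
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(base_seed).spawn(n_runs)
    ]
    keys = design.analysis_keys()
    effects = np.zeros((n_runs, design.n_test_phases))
    deltas = {name: np.zeros((n_runs, design.n_test_phases)) for name in keys}
    pooled: dict[tuple[str, int], list[Confusion2AFC]] = {
        k: [Confusion2AFC() for _ in range(design.n_test_phases)]
        for k in keys.values()
    }
    for r, s in enumerate(seeds):
        subj = run_single_model_subject(design, stats, seed=s, keep_trials=False)
        effects[r] = learning_effect(subj).effect
        for name, key in keys.items():
            deltas[name][r] = subj.delta(key)
            for ph in range(design.n_test_phases):
                pooled[key][ph] = pooled[key][ph] + subj.confusions[key][ph]
    return EnsembleResult(
        design=design,
        events=design.event_axis,
        per_run_effects=effects,
        per_run_delta=deltas,
        pooled_confusions=pooled,
    )


def rate_robustness_variants(
    design: ExperimentDesign,
    stats: ITPopulationStats,
    alpha_factors: tuple[float, ...] = (0.25, 1.0, 4.0),
    n_runs: int = 25,
    base_seed: int = 0,
) -> dict[float, EnsembleResult]:
    """Re-run the design at scaled plasticity rates (e.g. 4x smaller/larger)."""
    out = {}
    for f in alpha_factors:
        variant = replace(design, alpha=design.alpha * f)
        out[f] = average_model_runs(variant, stats, n_runs=n_runs, base_seed=base_seed)
    return out


def hyperparameter_robustness(
    design: ExperimentDesign,
    stats: ITPopulationStats,
    pairs: list[tuple[int, int]],
    n_runs: int = 25,
    base_seed: int = 0,
) -> dict[tuple[int, int], EnsembleResult]:
    """Re-run the design with alternative (n_sites, m_train) decoder settings."""
    out = {}
    for n, m in pairs:
        variant = replace(
            design, decoder=replace(design.decoder, n_sites=n, m_train=m)
        )
        out[(n, m)] = average_model_runs(variant, stats, n_runs=n_runs, base_seed=base_seed)
    return out


# ---------------------------------------------------------------------------
# difficulty sweep


@dataclass
class SweepTask:
    """One size-specific discrimination task targeted for swapped exposure."""

    target_objects: tuple[int, int]
    control_objects: tuple[int, int]
    exposed_size: int = BIG
    label: str = ""


def build_task_bank(
    stats: ITPopulationStats,
    exposed_size: int = BIG,
    n_subordinate: int = 6,
    n_basic: int = 3,
) -> list[SweepTask]:
    """A bank of subordinate and basic-level tasks spanning initial difficulty.

    Subordinate tasks are within-category pairs drawn from the tightest
    categories (the tightness grading of the default statistics makes them
    range from near-chance to clearly discriminable, like face pairs);
    basic-level tasks are between-category pairs from the loosest categories
    (far-apart representations, initially saturated performance). Controls
    come from the same task type, mirroring the face-control / basic-control
    pairing of the behavioral design.
    """
    block = stats.n_objects // stats.n_categories
    if block < 4:
        raise ValidationError("need at least 4 objects per category for a task bank")
    n_subordinate = min(n_subordinate, stats.n_categories)
    tasks = []
    for c in range(n_subordinate):
        base = c * block
        tasks.append(
            SweepTask(
                target_objects=(base, base + 1),
                control_objects=(base + 2, base + 3),
                exposed_size=exposed_size,
                label=f"subordinate_{c}",
            )
        )
    # basic-level pairs span the two loosest categories
    ca = (stats.n_categories - 2) * block
    cb = (stats.n_categories - 1) * block
    for i in range(n_basic):
        if cb + 2 * i + 1 >= stats.n_objects:
            break
        tasks.append(
            SweepTask(
                target_objects=(ca + 2 * i, cb + 2 * i),
                control_objects=(ca + 2 * i + 1, cb + 2 * i + 1),
                exposed_size=exposed_size,
                label=f"basic_{i}",
            )
        )
    return tasks


def difficulty_sweep(
    stats: ITPopulationStats,
    task_bank: list[SweepTask] | None = None,
    lapse_rates: tuple[float, ...] = (0.0, 0.09, 0.20),
    n_events: int = 800,
    n_runs: int = 25,
    base_seed: int = 0,
    decoder: DecoderSpec | None = None,
) -> pd.DataFrame:
    """Learning effect vs. initial difficulty under swapped exposure.

    For every lapse rate and every task in the bank, runs the single-epoch
    (``n_events`` swapped events) design ``n_runs`` times and reports the
    pre-exposure d' and the learning effect, both computed from trial counts
    pooled over runs (the analysis pools trials over subjects) alongside the
    run-mean effect and its SE.
    """
    task_bank = task_bank if task_bank is not None else build_task_bank(stats)
    if not task_bank:
        raise ValidationError("task bank is empty")
    decoder = decoder or DecoderSpec()
    rows = []
    for lam in lapse_rates:
        for ti, task in enumerate(task_bank):
            design = ExperimentDesign.sweep(
                target_objects=task.target_objects,
                control_objects=task.control_objects,
                exposed_size=task.exposed_size,
                lapse_rate=lam,
                decoder=decoder,
                events_per_epoch=n_events,
            )
            ens = average_model_runs(
                design, stats, n_runs=n_runs, base_seed=base_seed + 7919 * ti
            )
            kt = ("target", task.exposed_size)
            kc = ("control", task.exposed_size)
            d_t = ens.pooled_dprime_curve(kt)
            d_c = ens.pooled_dprime_curve(kc)
            rows.append(
                {
                    "lapse": lam,
                    "task": task.label or f"task_{ti}",
                    "initial_dprime": d_t[0],
                    "effect_pooled": (d_t[-1] - d_t[0]) - (d_c[-1] - d_c[0]),
                    "effect_run_mean": ens.mean_effect[-1],
                    "effect_run_se": ens.se_effect[-1],
                }
            )
    df = pd.DataFrame(rows)
    span = df[df["lapse"] == df["lapse"].min()]["initial_dprime"]
    if span.min() > 0.5 or span.max() < 2.5:
        warnings.warn(
            "task bank does not span the intended initial-d' range "
            f"({span.min():.2f}-{span.max():.2f})",
            stacklevel=2,
        )
    return df
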