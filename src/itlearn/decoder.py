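"""IT-to-behavior linking model: correlation readout, lapses, pooled d'.

A 2AFC task between two objects is read out from the population by comparing
the Pearson correlation of the evoked test vector with each object's frozen
class-mean template (the mean population response over m training images of
that object). Lapses inject a fair-coin choice on a fraction lambda of trials
regardless of sensory evidence, which caps measurable accuracy at
1 - lambda/2. Performance is summarized as the pooled signal-detection
d' = Z(TPR) - Z(FPR) with epsilon-clipped rates (epsilon = 1e-4, so |d'| is
bounded by ~7.44), with bootstrap standard errors and p-values obtained by
resampling trials with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .population import ITPopulation
from .stats import ITPopulationStats, ValidationError

__all__ = [
    "DecoderSpec",
    "TrainedDecoder",
    "Confusion2AFC",
    "BehavioralPerformance",
    "train_decoder",
    "classify",
    "run_subtask",
    "pooled_dprime",
    "bootstrap_performance",
    "calibrate_hyperparameters",
    "consistency",
]

EPSILON = 1e-4  # rate clipping; caps |d'| at 2*Z(1-1e-4) = 7.438


@dataclass
class DecoderSpec:
    """Hyperparameters of the linking model (defaults match calibration)."""

    n_sites: int = 260
    m_train: int = 20
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValidationError("lapse_rate must lie in [0, 1]")
        if self.n_sites < 1 or self.m_train < 1:
            raise ValidationError("n_sites and m_train must be >= 1")


@dataclass
class TrainedDecoder:
    """Frozen class-mean templates for one object pair."""

    objects: tuple[int, int]
    site_idx: np.ndarray  # indices into the source population
    templates: np.ndarray  # (2, n_sites)
    frozen: bool = True

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.templates.setflags(write=False)


@dataclass
class Confusion2AFC:
    hit: int = 0
    miss: int = 0
    false_alarm: int = 0
    correct_rejection: int = 0

    def __post_init__(self) -> None:
        if min(self.hit, self.miss, self.false_alarm, self.correct_rejection) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hit + self.miss + self.false_alarm + self.correct_rejection

    @property
    def accuracy(self) -> float:
        return (self.hit + self.correct_rejection) / self.total

    def __add__(self, other: "Confusion2AFC") -> "Confusion2AFC":
        return Confusion2AFC(
            self.hit + other.hit,
            self.miss + other.miss,
            self.false_alarm + other.false_alarm,
            self.correct_rejection + other.correct_rejection,
        )


@dataclass
class BehavioralPerformance:
    dprime: float
    tpr: float
    fpr: float
    se_boot: float | None = None
    p_change: float | None = None


def train_decoder(
    pop: ITPopulation, objects: tuple[int, int], spec: DecoderSpec
) -> TrainedDecoder:
    """Train (and freeze) class-mean templates for a 2AFC object pair.

    Subsamples ``spec.n_sites`` sites deterministically by the spec seed.
    Each object's template is the mean over ``m_train`` generated training
    images — fresh exemplars at sizes drawn uniformly over the three levels,
    with clutter and single-trial repetition noise. Test images are never
    used in training.
    """
    if pop.n_sites < spec.n_sites:
        raise ValidationError(
            f"population has {pop.n_sites} sites < spec.n_sites={spec.n_sites}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    site_idx = np.sort(rng.choice(pop.n_sites, spec.n_sites, replace=False))
    templates = np.zeros((2, spec.n_sites))
    for j, obj in enumerate(objects):
        sizes = rng.integers(0, 3, size=spec.m_train)
        acc = np.zeros(spec.n_sites)
        for z in np.unique(sizes):
            k = int((sizes == z).sum())
            ids = pop.new_exemplar_ids(k)
            means = pop.mean_responses(obj, int(z), ids)[:, site_idx]
            noise = rng.normal(size=means.shape) * np.sqrt(
                pop.stats.repetition_variance(means)
            )
            acc += (means + noise).sum(axis=0)
        templates[j] = acc / spec.m_train
    return TrainedDecoder(objects=tuple(objects), site_idx=site_idx, templates=templates)


def _corr_scores(templates: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``x`` with each template.

    Returns (n_rows, 2); constant vectors yield 0 correlation.
    """
    x = np.atleast_2d(x)
    t = templates - templates.mean(axis=1, keepdims=True)
    xc = x - x.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1)
    xn = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (xc @ t.T) / np.outer(xn, tn)
    return np.nan_to_num(scores, nan=0.0)


def classify(
    dec: TrainedDecoder, test_response: np.ndarray, rng: np.random.Generator | None = None
) -> int:
    """Choose the object whose template correlates best with the response.

    Exact ties (including constant test vectors, whose correlations are
    defined as 0) are broken uniformly at random.
    """
    if not dec.frozen:
        raise ValidationError("decoder must be frozen before classification")
    scores = _corr_scores(dec.templates, np.asarray(test_response, float))[0]
    if scores[0] == scores[1]:
        rng = rng or np.random.default_rng()
        return int(dec.objects[rng.integers(2)])
    return int(dec.objects[int(np.argmax(scores))])


def run_subtask(
    pop: ITPopulation,
    dec: TrainedDecoder,
    size: int,
    n_trials: int,
    lapse_rate: float = 0.0,
    seed: int = 0,
) -> tuple[Confusion2AFC, pd.DataFrame]:
    """Run a balanced block of 2AFC trials for one size-specific sub-task.

    Each trial evokes a fresh test image (new exemplar + repetition noise),
    classifies it against the frozen templates, and with probability
    ``lapse_rate`` replaces the choice with a fair coin. Returns the pooled
    2x2 confusion (object A of the pair is the 'signal' class) and the
    trial-level table used for bootstrapping.
    """
    if n_trials % 2:
        raise ValidationError("n_trials must be even (balanced 2AFC)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half = n_trials // 2
    rows = []
    for obj in dec.objects:
        ids = pop.new_exemplar_ids(half)
        means = pop.mean_responses(obj, size, ids)[:, dec.site_idx]
        resp = means + rng.normal(size=means.shape) * np.sqrt(
            pop.stats.repetition_variance(means)
        )
        scores = _corr_scores(dec.templates, resp)
        choice_idx = np.argmax(scores, axis=1)
        ties = scores[:, 0] == scores[:, 1]
        if ties.any():
            choice_idx[ties] = rng.integers(2, size=int(ties.sum()))
        lapsed = rng.random(half) < lapse_rate
        if lapsed.any():
            choice_idx[lapsed] = rng.integers(2, size=int(lapsed.sum()))
        for ci, lp in zip(choice_idx, lapsed):
            rows.append((obj, int(dec.objects[ci]), bool(lp)))
    trials = pd.DataFrame(rows, columns=["true_object", "choice", "lapsed"])
    a = dec.objects[0]
    is_a = trials["true_object"] == a
    chose_a = trials["choice"] == a
    conf = Confusion2AFC(
        hit=int((is_a & chose_a).sum()),
        miss=int((is_a & ~chose_a).sum()),
        false_alarm=int((~is_a & chose_a).sum()),
        correct_rejection=int((~is_a & ~chose_a).sum()),
    )
    return conf, trials


def pooled_dprime(conf: Confusion2AFC, epsilon: float = EPSILON) -> BehavioralPerformance:
    """Signal-detection d' from pooled trial counts with epsilon clipping."""
    if conf.total < 1:
        raise ValidationError("need at least one trial")
    n_pos = conf.hit + conf.miss
    n_neg = conf.false_alarm + conf.correct_rejection
    tpr = conf.hit / n_pos if n_pos else 0.5
    fpr = conf.false_alarm / n_neg if n_neg else 0.5
    tpr = float(np.clip(tpr, epsilon, 1 - epsilon))
    fpr = float(np.clip(fpr, epsilon, 1 - epsilon))
    return BehavioralPerformance(
        dprime=float(norm.ppf(tpr) - norm.ppf(fpr)), tpr=tpr, fpr=fpr
    )


def _conf_from_trials(trials: pd.DataFrame, positive: int) -> Confusion2AFC:
    is_a = trials["true_object"].to_numpy() == positive
    chose_a = trials["choice"].to_numpy() == positive
    return Confusion2AFC(
        hit=int((is_a & chose_a).sum()),
        miss=int((is_a & ~chose_a).sum()),
        false_alarm=int((~is_a & chose_a).sum()),
        correct_rejection=int((~is_a & ~chose_a).sum()),
    )


def bootstrap_performance(
    trials: pd.DataFrame,
    positive: int,
    n_boot: int = 1000,
    seed: int = 0,
    baseline_trials: pd.DataFrame | None = None,
) -> BehavioralPerformance:
    """Bootstrap the pooled d' (or the d' change against a baseline phase).

    Trials are resampled with replacement; the standard error is the standard
    deviation over resamples. With ``baseline_trials`` supplied, the reported
    quantity is the change d' - d'_baseline and ``p_change`` is the two-sided
    tail fraction of the bootstrapped change distribution relative to 0.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if len(trials) == 0:
        raise ValidationError("empty trial table")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def boot_d(df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        idx = rng.integers(n, size=(n_boot, n))
        truth = df["true_object"].to_numpy() == positive
        chose = df["choice"].to_numpy() == positive
        out = np.empty(n_boot)
        for b in range(n_boot):
            t, c = truth[idx[b]], chose[idx[b]]
            conf = Confusion2AFC(
                hit=int((t & c).sum()),
                miss=int((t & ~c).sum()),
                false_alarm=int((~t & c).sum()),
                correct_rejection=int((~t & ~c).sum()),
            )
            out[b] = pooled_dprime(conf).dprime
        return out

    point = pooled_dprime(_conf_from_trials(trials, positive))
    draws = boot_d(trials)
    if baseline_trials is not None:
        base_draws = boot_d(baseline_trials)
        base_point = pooled_dprime(_conf_from_trials(baseline_trials, positive))
        change = draws - base_draws
        p = 2 * min((change <= 0).mean(), (change >= 0).mean())
        return BehavioralPerformance(
            dprime=point.dprime - base_point.dprime,
            tpr=point.tpr,
            fpr=point.fpr,
            se_boot=float(change.std(ddof=1)),
            p_change=float(min(1.0, p)),
        )
    return BehavioralPerformance(
        dprime=point.dprime,
        tpr=point.tpr,
        fpr=point.fpr,
        se_boot=float(draws.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# hyperparameter calibration


@dataclass
class CalibrationResult:
    """Matching (n_sites, m_train) manifold and the chosen pair."""

    crossings: dict[int, float | None]  # m -> interpolated n* (None: unmatched)
    curves: dict[int, np.ndarray]  # m -> mean model d' per n grid point
    n_grid: np.ndarray
    chosen: tuple[int, int] | None  # (n, m) closest to (260, 20)


def calibrate_hyperparameters(
    stats: ITPopulationStats,
    task_set: list[tuple[tuple[int, int], int]],
    human_dprimes: np.ndarray,
    n_grid: np.ndarray | None = None,
    m_grid: np.ndarray | None = None,
    runs: int = 2,
    n_trials: int = 200,
    seed: int = 0,
    reference: tuple[int, int] = (260, 20),
) -> CalibrationResult:
    """Find (n_sites, m_train) pairs where model performance matches targets.

    For every m in the grid, sweeps the number of sites, measures the mean
    model d' across the task set (averaged over ``runs`` fresh populations),
    and interpolates the n at which the model mean crosses the mean target
    d'. Returns all crossing pairs plus the pair closest (in log space) to
    the reference (260, 20).
    """
    from .population import sample_population

    human_dprimes = np.asarray(human_dprimes, dtype=float)
    n_grid = np.asarray(
        n_grid if n_grid is not None else [40, 80, 160, 320, 640, 1000], int
    )
    m_grid = np.asarray(m_grid if m_grid is not None else [5, 10, 20, 40], int)
    target = float(human_dprimes.mean())
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xCA,))
    run_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(runs)]

    curves = {int(m): np.zeros(len(n_grid)) for m in m_grid}
    for run_seed in run_seeds:
        pop_master_seed = run_seed
        for m in m_grid:
            for ni, n in enumerate(n_grid):
                pop = sample_population(stats, int(n), seed=pop_master_seed)
                dps = []
                for ti, (pair, size) in enumerate(task_set):
                    spec = DecoderSpec(
                        n_sites=int(n), m_train=int(m),
                        seed=(run_seed * 1000003 + ti * 97 + int(n)) % 2**31,
                    )
                    dec = train_decoder(pop, pair, spec)
                    conf, _ = run_subtask(
                        pop, dec, size, n_trials, seed=spec.seed + 1
                    )
                    dps.append(pooled_dprime(conf).dprime)
                curves[int(m)][ni] += np.mean(dps) / runs

    crossings: dict[int, float | None] = {}
    for m in m_grid:
        c = curves[int(m)]
        above = c >= target
        if not above.any() or above.all():
            crossings[int(m)] = None if not above.any() else float(n_grid[0])
            continue
        i = int(np.argmax(above))
        if i == 0:
            crossings[int(m)] = float(n_grid[0])
        else:
            x0, x1 = n_grid[i - 1], n_grid[i]
            y0, y1 = c[i - 1], c[i]
            crossings[int(m)] = float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))
    matched = {m: n for m, n in crossings.items() if n is not None}
    chosen = None
    if matched:
        ref_n, ref_m = reference
        chosen_m = min(
            matched,
            key=lambda m: np.hypot(
                np.log(matched[m] / ref_n), np.log(m / ref_m)
            ),
        )
        chosen = (int(round(matched[chosen_m])), int(chosen_m))
    return CalibrationResult(
        crossings=crossings, curves=curves, n_grid=n_grid, chosen=chosen
    )


def consistency(model_dprimes: np.ndarray, human_dprimes: np.ndarray) -> float:
    """Pearson correlation between model and human d' across tasks."""
    x = np.asarray(model_dprimes, float)
    y = np.asarray(human_dprimes, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("need equal-length d' vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant d' vector; consistency defined as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
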