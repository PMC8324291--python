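"""Temporal-contiguity firing-rate plasticity and its calibration.

The rule: after each exposure event (a leading image followed by a lagging
image), the clean mean response to the leading image moves toward the lagging
response,

    dFR_leading = alpha * (FR_lagging - FR_leading),

with a single free parameter, the plasticity rate alpha (0.0016 nru per
exposure event at the calibrated default). The rule is temporally asymmetric;
symmetric session-level changes arise because the leading/lagging order is
counterbalanced ~50/50 across events. Under strict alternation between two
conditions the response gap contracts exactly by (1 - alpha) per event, so
responses to repeatedly paired images converge to a common steady state.

The module also replicates the classic single-electrode size-swap exposure
design (per-site preferred/non-preferred object pairs), the selectivity
bookkeeping used to summarize it, and a grid-search calibration of alpha
against reference trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .population import BIG, CLEAN, MEDIUM, SMALL, ITPopulation, ITSite, ImageCondition
from .stats import ITPopulationStats, ReferencePlasticityTrajectory, ValidationError

__all__ = [
    "PlasticityConfig",
    "ExposureEvent",
    "ExposurePhaseSpec",
    "SiteSelectivityProfile",
    "PlasticityTrajectories",
    "apply_exposure_event",
    "run_exposure_phase",
    "select_P_N",
    "normalized_selectivity_change",
    "replicate_neural_exposure_design",
    "select_subgroups",
    "fit_plasticity_rate",
    "rate_to_spikes",
    "default_alpha_grid",
]

#: calibrated plasticity rate (nru per exposure event)
DEFAULT_ALPHA = 0.0016

#: threshold below which an initial selectivity gap is treated as degenerate
_GAP_TOL = 1e-12


@dataclass
class PlasticityConfig:
    alpha: float = DEFAULT_ALPHA
    update_scope: str = "leading_only"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValidationError("alpha must lie in [0, 1)")
        if self.update_scope != "leading_only":
            raise ValidationError("only update_scope='leading_only' is supported")


@dataclass
class ExposureEvent:
    """A temporally contiguous pair of clean images (leading, then lagging)."""

    leading: ImageCondition
    lagging: ImageCondition

    def __post_init__(self) -> None:
        self.leading = ImageCondition(*self.leading)
        self.lagging = ImageCondition(*self.lagging)
        if self.leading.size == self.lagging.size:
            raise ValidationError("exposure pair must span two different sizes")
        if MEDIUM not in (self.leading.size, self.lagging.size):
            raise ValidationError("one image of the pair must be medium size")
        if self.leading.exemplar_id != CLEAN or self.lagging.exemplar_id != CLEAN:
            raise ValidationError("exposure images are clean (exemplar_id = -1)")


@dataclass
class ExposurePhaseSpec:
    """Schedule of exposure events of one flavor for one object pair."""

    flavor: str  # 'swapped' | 'non_swapped'
    objects: tuple[int, int]
    size_pair: tuple[int, int] = (MEDIUM, BIG)
    n_events: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flavor not in ("swapped", "non_swapped"):
            raise ValidationError(f"unknown exposure flavor {self.flavor!r}")
        a, b = self.objects
        if a == b:
            raise ValidationError("exposure objects must differ")
        if MEDIUM not in self.size_pair or self.size_pair[0] == self.size_pair[1]:
            raise ValidationError("size_pair must contain medium and one other size")
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")

    @property
    def other_size(self) -> int:
        return self.size_pair[0] if self.size_pair[1] == MEDIUM else self.size_pair[1]


@dataclass
class SiteSelectivityProfile:
    """Preferred/non-preferred objects of a site and its selectivity by size.

    ``selectivity_by_size`` is (P - N)/(P + N) on the nru-scale responses;
    ``gap_by_size`` is the raw difference P - N used for normalized changes.
    """

    P: int
    N: int
    selectivity_by_size: np.ndarray
    gap_by_size: np.ndarray
    degenerate: np.ndarray  # per size: True where P + N ~ 0

    def __post_init__(self) -> None:
        if self.P == self.N:
            raise ValidationError("P and N must differ")


# ---------------------------------------------------------------------------
# the rule


def apply_exposure_event(
    pop: ITPopulation, event: ExposureEvent, cfg: PlasticityConfig
) -> ITPopulation:
    """Apply one exposure event to every site (in place).

    Only the clean mean response to the leading condition changes; clutter
    offsets and all other matrix entries are untouched.
    """
    lead, lag = event.leading, event.lagging
    lead.validate(pop.n_objects)
    lag.validate(pop.n_objects)
    fr_lead = pop.base[:, lead.object_id, lead.size]
    fr_lag = pop.base[:, lag.object_id, lag.size]
    pop.base[:, lead.object_id, lead.size] = fr_lead + cfg.alpha * (fr_lag - fr_lead)
    return pop


def _apply_events_per_site(
    pop: ITPopulation,
    lead_obj: np.ndarray,
    lead_size: int,
    lag_obj: np.ndarray,
    lag_size: int,
    alpha: float,
) -> None:
    """One event where each site has its own leading/lagging object."""
    rows = np.arange(pop.n_sites)
    fr_lead = pop.base[rows, lead_obj, lead_size]
    fr_lag = pop.base[rows, lag_obj, lag_size]
    pop.base[rows, lead_obj, lead_size] = fr_lead + alpha * (fr_lag - fr_lead)


def _phase_pairings(spec: ExposurePhaseSpec) -> list[tuple[ImageCondition, ImageCondition]]:
    """The two (medium-image, other-size-image) pairings of a phase flavor."""
    a, b = spec.objects
    other = spec.other_size
    if spec.flavor == "swapped":
        return [
            (ImageCondition(a, MEDIUM), ImageCondition(b, other)),
            (ImageCondition(b, MEDIUM), ImageCondition(a, other)),
        ]
    return [
        (ImageCondition(a, MEDIUM), ImageCondition(a, other)),
        (ImageCondition(b, MEDIUM), ImageCondition(b, other)),
    ]


def run_exposure_phase(
    pop: ITPopulation, spec: ExposurePhaseSpec, cfg: PlasticityConfig
) -> pd.DataFrame:
    """Run one exposure phase in place; return the event log.

    Events split evenly over the two pairings (remainder assigned
    round-robin), the medium-first/other-first order is randomized ~50/50 per
    event, and the whole sequence is shuffled before sequential application.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pairings = _phase_pairings(spec)
    counts = [spec.n_events // 2] * 2
    for i in range(spec.n_events % 2):
        counts[i] += 1
    pair_idx = np.repeat(np.arange(2), counts)
    rng.shuffle(pair_idx)
    medium_first = rng.random(spec.n_events) < 0.5

    log = []
    for k in range(spec.n_events):
        med_img, oth_img = pairings[pair_idx[k]]
        lead, lag = (med_img, oth_img) if medium_first[k] else (oth_img, med_img)
        apply_exposure_event(pop, ExposureEvent(lead, lag), cfg)
        log.append(
            (k, lead.object_id, lead.size, lag.object_id, lag.size)
        )
    return pd.DataFrame(
        log,
        columns=[
            "event_index",
            "leading_object",
            "leading_size",
            "lagging_object",
            "lagging_size",
        ],
    )


# ---------------------------------------------------------------------------
# selectivity bookkeeping


def select_P_N(site: ITSite) -> SiteSelectivityProfile:
    """Pick the preferred and non-preferred objects of a site.

    P and N are the argmax/argmin of the size-averaged mean object responses
    (the generative model's responses are already on the z-score/nru scale).
    Selectivity per size is (P - N)/(P + N); a vanishing denominator falls
    back to an epsilon (1e-6) and flags that size as degenerate.
    """
    base = site.base_matrix
    if base.shape[0] < 2:
        raise ValidationError("need at least 2 objects")
    by_object = base.mean(axis=1)
    P = int(np.argmax(by_object))
    N = int(np.argmin(by_object))
    if P == N:  # flat site: argmax == argmin only when all equal
        N = (P + 1) % base.shape[0]
    p_resp, n_resp = base[P], base[N]
    denom = p_resp + n_resp
    gap = p_resp - n_resp
    small = np.abs(denom) < 1e-6
    safe = np.where(small, np.sign(denom) * 1e-6 + (denom == 0) * 1e-6, denom)
    return SiteSelectivityProfile(
        P=P,
        N=N,
        selectivity_by_size=gap / safe,
        gap_by_size=gap,
        degenerate=small | (gap == 0),
    )


def normalized_selectivity_change(
    before: SiteSelectivityProfile, after: SiteSelectivityProfile, size: int
) -> float:
    """Delta(P - N)/(P - N) at one size; NaN when the initial gap vanishes."""
    g0 = before.gap_by_size[size]
    if abs(g0) < _GAP_TOL:
        return float("nan")
    return float((after.gap_by_size[size] - g0) / g0)


@dataclass
class PlasticityTrajectories:
    """Mean normalized selectivity change per size condition over events."""

    event_axis: np.ndarray
    changes: dict[str, np.ndarray]  # {'swapped','medium','non_swapped'} -> vector
    n_sites: int
    sem: dict[str, np.ndarray] = field(default_factory=dict)


def replicate_neural_exposure_design(
    pop: ITPopulation,
    cfg: PlasticityConfig,
    n_events_per_arrow: int = 400,
    n_checkpoints: int = 4,
    swap_size: int = SMALL,
    nonswap_size: int = BIG,
    seed: int = 0,
) -> PlasticityTrajectories:
    """Replicate the single-site size-swap exposure design on every site.

    Each site is exposed to its own four arrows — P@medium <-> N@swap-size
    and N@medium <-> P@swap-size (the swapped arrows), plus
    P@medium <-> P@non-swap-size and N@medium <-> N@non-swap-size (the
    non-swapped arrows) — interleaved in random order with the leading/lagging
    direction counterbalanced. P/N are selected before exposure and frozen.
    The mean normalized selectivity change (over sites with a positive initial
    gap) is recorded at evenly spaced event-count checkpoints for the swapped,
    medium, and non-swapped sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = [select_P_N(s) for s in pop.sites]
    P = np.array([p.P for p in profiles])
    N = np.array([p.N for p in profiles])
    rows = np.arange(pop.n_sites)
    gap0 = {
        "swapped": pop.base[rows, P, swap_size] - pop.base[rows, N, swap_size],
        "medium": pop.base[rows, P, MEDIUM] - pop.base[rows, N, MEDIUM],
        "non_swapped": pop.base[rows, P, nonswap_size]
        - pop.base[rows, N, nonswap_size],
    }
    included = {k: g > _GAP_TOL for k, g in gap0.items()}

    # arrows: (medium-side object vector, other-side object vector, other size)
    arrows = [
        (P, N, swap_size),
        (N, P, swap_size),
        (P, P, nonswap_size),
        (N, N, nonswap_size),
    ]
    total = 4 * n_events_per_arrow
    order = np.repeat(np.arange(4), n_events_per_arrow)
    rng.shuffle(order)
    medium_first = rng.random(total) < 0.5

    checkpoints = np.linspace(0, total, n_checkpoints + 1).astype(int)
    event_axis = checkpoints.astype(float)
    changes = {k: np.zeros(n_checkpoints + 1) for k in gap0}
    sem = {k: np.zeros(n_checkpoints + 1) for k in gap0}

    def record(ci: int) -> None:
        for key, z in (("swapped", swap_size), ("medium", MEDIUM), ("non_swapped", nonswap_size)):
            gap = pop.base[rows, P, z] - pop.base[rows, N, z]
            inc = included[key]
            if inc.any():
                # change in the mean P-vs-N response over P>N-selective
                # units, normalized by the initial mean gap (site-level
                # ratios are heavy-tailed when initial gaps are tiny)
                g0 = gap0[key][inc].mean()
                changes[key][ci] = (gap[inc].mean() - g0) / g0
                rel = (gap[inc] - gap0[key][inc]) / g0
                sem[key][ci] = (
                    rel.std(ddof=1) / np.sqrt(inc.sum()) if inc.sum() > 1 else 0.0
                )

    record(0)
    ci = 1
    for k in range(total):
        med_obj, oth_obj, oth_size = arrows[order[k]]
        if medium_first[k]:
            _apply_events_per_site(pop, med_obj, MEDIUM, oth_obj, oth_size, cfg.alpha)
        else:
            _apply_events_per_site(pop, oth_obj, oth_size, med_obj, MEDIUM, cfg.alpha)
        while ci <= n_checkpoints and k + 1 == checkpoints[ci]:
            record(ci)
            ci += 1
    return PlasticityTrajectories(
        event_axis=event_axis, changes=changes, n_sites=pop.n_sites, sem=sem
    )


# ---------------------------------------------------------------------------
# subgroup analysis


def select_subgroups(
    pop_profiles: Sequence[SiteSelectivityProfile],
    criteria: dict[str, dict[int, tuple[float, float]]],
    metric: str = "gap",
) -> dict[str, np.ndarray]:
    """Partition sites by their initial pattern of P vs. N selectivity.

    ``criteria`` maps a group name to per-size (low, high) bounds; a site
    belongs to a group when its value falls inside the bounds at every
    listed size. ``metric`` selects the thresholded quantity: the raw
    response gap P - N in nru (default; well behaved on the zero-mean nru
    scale) or the ratio 'selectivity' (P - N)/(P + N). Groups may overlap
    unless the bounds make them disjoint. Empty groups warn.
    """
    if metric not in ("gap", "selectivity"):
        raise ValidationError("metric must be 'gap' or 'selectivity'")
    groups: dict[str, np.ndarray] = {}
    field_name = "gap_by_size" if metric == "gap" else "selectivity_by_size"
    sel = np.array([getattr(p, field_name) for p in pop_profiles])
    for name, bounds in criteria.items():
        mask = np.ones(len(pop_profiles), dtype=bool)
        for size, (lo, hi) in bounds.items():
            mask &= (sel[:, size] >= lo) & (sel[:, size] <= hi)
        idx = np.where(mask)[0]
        if len(idx) == 0:
            warnings.warn(f"subgroup {name!r} is empty", stacklevel=2)
        groups[name] = idx
    return groups


# ---------------------------------------------------------------------------
# rate calibration


def default_alpha_grid() -> np.ndarray:
    """Log-spaced rate grid from 1e-4 to 1e-2, plus the calibrated 0.0016."""
    grid = np.geomspace(1e-4, 1e-2, 13)
    return np.unique(np.append(grid, DEFAULT_ALPHA))


@dataclass
class RateFit:
    alpha_star: float
    grid: np.ndarray
    loss: np.ndarray


def fit_plasticity_rate(
    reference: ReferencePlasticityTrajectory,
    stats: ITPopulationStats,
    grid: Sequence[float] | None = None,
    n_sites: int = 500,
    n_repeats: int = 2,
    seed: int = 0,
) -> RateFit:
    """Grid-search the plasticity rate against reference trajectories.

    For each candidate alpha, the single-site exposure-design replication is
    run on ``n_repeats`` fresh populations; the loss is the unweighted mean
    squared difference between the simulated and reference mean trajectories
    across the swapped, medium, and non-swapped conditions jointly. Returns
    the minimizing rate together with the full loss curve.
    """
    from .population import sample_population

    grid = np.sort(np.asarray(grid if grid is not None else default_alpha_grid(), float))
    if len(grid) == 0:
        raise ValidationError("alpha grid must be non-empty")
    n_checkpoints = len(reference.event_axis) - 1
    n_events_per_arrow = int(round(reference.event_axis[-1] / 4))
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xF1,))
    rep_seeds = [
        tuple(int(v % 2**31) for v in s.generate_state(2)) for s in ss.spawn(n_repeats)
    ]

    loss = np.zeros(len(grid))
    for gi, alpha in enumerate(grid):
        errs = []
        for pop_seed, design_seed in rep_seeds:
            pop = sample_population(stats, n_sites, seed=pop_seed)
            traj = replicate_neural_exposure_design(
                pop,
                PlasticityConfig(alpha=float(alpha)),
                n_events_per_arrow=n_events_per_arrow,
                n_checkpoints=n_checkpoints,
                seed=design_seed,
            )
            diff = np.concatenate(
                [traj.changes[k] - reference.changes[k] for k in reference.changes]
            )
            errs.append(np.mean(diff**2))
        loss[gi] = np.mean(errs)
    if len(grid) > 1 and np.ptp(loss) < 1e-15:
        raise ValidationError(
            "loss is flat across the alpha grid; the reference trajectories "
            "do not constrain the rate"
        )
    return RateFit(alpha_star=float(grid[np.argmin(loss)]), grid=grid, loss=loss)


def rate_to_spikes(alpha: float, stats: ITPopulationStats) -> float:
    """Per-event firing-rate change (spikes/s) for a 1-nru response gap."""
    return alpha * stats.rate_scale
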