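"""Population-level statistics that parameterize the generative IT model.

The downstream simulation needs four distributional ingredients, all expressed
in normalized response units (nru; the z-score scale of a site's across-object
response distribution, roughly 23 spikes/s on top of a 90 spikes/s mean rate):

* a mean vector and covariance matrix of object preferences across sites
  (a multi-dimensional Gaussian over the 64-object response space, with a
  block category structure: higher within- than between-category correlation);
* a pool of 3-point size-tuning kernels (multiplicative gains for the
  small / medium / big presentation sizes);
* per-object clutter variances (response variability induced by the image
  background / exemplar identity);
* a repetition-noise model mapping a mean response to a trial-to-trial
  variance (Poisson-like: variance proportional to the underlying firing
  rate).

Everything here can be generated synthetically from a seeded configuration, or
loaded from a table of recorded trial-level responses via
:func:`load_recorded_statistics`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StatsConfig",
    "ITPopulationStats",
    "ReferencePlasticityTrajectory",
    "generate_population_statistics",
    "generate_reference_trajectories",
    "load_recorded_statistics",
]

#: Eigenvalue tolerance (relative to the trace) for the PSD check.
_PSD_RTOL = 1e-8


class ValidationError(ValueError):
    """Raised when requested statistics violate a structural constraint."""


@dataclass
class StatsConfig:
    """Configuration for the synthetic statistics generator.

    The defaults define the study conditions used throughout the package:
    64 objects in 8 categories, category tightness graded from subordinate
    (face-like, nearly collinear object representations) to basic-level
    (well separated), and clutter / repetition noise levels that place
    within-category 2AFC discrimination in the human-matched d' range when
    read out with the default decoder (260 sites, 20 training images).
    """

    object_variance: float = 1.0
    #: Within-category correlation per category (recycled if fewer than
    #: n_categories). Graded: tight categories behave like subordinate
    #: (face) discriminations, loose ones like basic-level discriminations.
    within_category_corr: Sequence[float] = (
        0.998, 0.995, 0.99, 0.98, 0.965, 0.95, 0.90, 0.75,
    )
    between_category_corr: float = 0.20
    #: Mean of the per-object clutter variance distribution (nru^2).
    clutter_var_mean: float = 0.25
    #: Gamma shape of the per-object clutter variance distribution.
    clutter_var_shape: float = 2.0
    #: Fano-like factor of the repetition noise on the spikes/s scale.
    repetition_fano: float = 1.0
    #: spikes/s per 1 nru and the mean multi-unit rate offset.
    rate_scale: float = 23.0
    rate_offset: float = 90.0
    #: Size-tuning kernel pool: number of kernels and mixture weights over
    #: (flat, increasing, decreasing, medium-peaked) shapes; tilted toward
    #: baseline-size-preferring tuning, as in recorded IT.
    n_kernels: int = 168
    kernel_mixture: Sequence[float] = (0.15, 0.10, 0.35, 0.40)
    #: gain ranges for flat kernels, for a shape's preferred size, and for
    #: its non-preferred sizes (the middle size of a monotone kernel draws
    #: from the span between trough and peak)
    kernel_gain_range: tuple[float, float] = (0.5, 1.5)
    kernel_peak_range: tuple[float, float] = (1.2, 1.8)
    kernel_trough_range: tuple[float, float] = (0.1, 0.8)

    @classmethod
    def from_file(cls, path: str | Path) -> "StatsConfig":
        """Load a config from a YAML or JSON document."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["within_category_corr"] = list(self.within_category_corr)
        d["kernel_mixture"] = list(self.kernel_mixture)
        d["kernel_gain_range"] = list(self.kernel_gain_range)
        return d


@dataclass
class ITPopulationStats:
    """Distributional ingredients from which simulated IT populations are drawn."""

    n_objects: int
    n_categories: int
    object_mean: np.ndarray  # (n_objects,) nru
    object_covariance: np.ndarray  # (n_objects, n_objects) nru^2
    size_kernel_pool: np.ndarray  # (n_kernels, 3) non-negative gains
    clutter_variance_by_object: np.ndarray  # (n_objects,) nru^2
    repetition_fano: float = 1.0
    rate_scale: float = 23.0  # spikes/s per nru
    rate_offset: float = 90.0  # spikes/s mean rate

    def __post_init__(self) -> None:
        self.object_mean = np.asarray(self.object_mean, dtype=float)
        self.object_covariance = np.asarray(self.object_covariance, dtype=float)
        self.size_kernel_pool = np.asarray(self.size_kernel_pool, dtype=float)
        self.clutter_variance_by_object = np.asarray(
            self.clutter_variance_by_object, dtype=float
        )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = self.n_objects
        if self.object_mean.shape != (n,):
            raise ValidationError("object_mean has wrong shape")
        if self.object_covariance.shape != (n, n):
            raise ValidationError("object_covariance has wrong shape")
        if not np.allclose(self.object_covariance, self.object_covariance.T):
            raise ValidationError("object_covariance is not symmetric")
        eig = np.linalg.eigvalsh(self.object_covariance)
        tol = _PSD_RTOL * max(np.trace(self.object_covariance), 1.0)
        if eig.min() < -tol:
            raise ValidationError(
                "object_covariance is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        if self.size_kernel_pool.ndim != 2 or self.size_kernel_pool.shape[1] != 3:
            raise ValidationError("size_kernel_pool must be (n_kernels, 3)")
        if (self.size_kernel_pool < 0).any():
            raise ValidationError("size kernels must be non-negative")
        if not (self.size_kernel_pool.max(axis=1) > 0).all():
            raise ValidationError("every size kernel needs one positive entry")
        if (self.clutter_variance_by_object < 0).any():
            raise ValidationError("clutter variances must be non-negative")
        if self.rate_scale <= 0:
            raise ValidationError("rate_scale (firing_rate_scale) must be > 0")

    # -- noise model --------------------------------------------------------
    def repetition_variance(self, mean_nru: np.ndarray | float) -> np.ndarray:
        """Trial-to-trial variance (nru^2) for a given mean response (nru).

        Poisson-like on the spikes/s scale: var_spk = fano * rate, with the
        rate floored at zero, then mapped back to nru^2.
        """
        rate = self.rate_offset + self.rate_scale * np.asarray(mean_nru, dtype=float)
        var_spk = self.repetition_fano * np.clip(rate, 0.0, None)
        return var_spk / self.rate_scale**2

    def clutter_std(self, object_id: int | np.ndarray) -> np.ndarray:
        return np.sqrt(self.clutter_variance_by_object[object_id])

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the stats to an NPZ bundle (documented keys)."""
        np.savez(
            path,
            mean=self.object_mean,
            cov=self.object_covariance,
            kernels=self.size_kernel_pool,
            clutter_var=self.clutter_variance_by_object,
            noise_coef=np.array([self.repetition_fano]),
            rate_scale=np.array([self.rate_scale, self.rate_offset]),
            shape=np.array([self.n_objects, self.n_categories]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ITPopulationStats":
        with np.load(path) as z:
            n_objects, n_categories = (int(v) for v in z["shape"])
            return cls(
                n_objects=n_objects,
                n_categories=n_categories,
                object_mean=z["mean"],
                object_covariance=z["cov"],
                size_kernel_pool=z["kernels"],
                clutter_variance_by_object=z["clutter_var"],
                repetition_fano=float(z["noise_coef"][0]),
                rate_scale=float(z["rate_scale"][0]),
                rate_offset=float(z["rate_scale"][1]),
            )

    def category_of(self, object_id: np.ndarray | int) -> np.ndarray:
        """Category index of each object (objects are laid out in blocks)."""
        block = self.n_objects // self.n_categories
        return np.minimum(
            np.asarray(object_id) // block, self.n_categories - 1
        )


@dataclass
class ReferencePlasticityTrajectory:
    """Mean normalized selectivity change under the single-site swap design.

    ``changes`` maps condition name ({'swapped', 'medium', 'non_swapped'}) to
    a vector aligned with ``event_axis`` (cumulative exposure events, starting
    at 0 where the change is 0 by definition).
    """

    exposure_design: str
    event_axis: np.ndarray
    changes: dict[str, np.ndarray]
    n_reference_sites: int

    def __post_init__(self) -> None:
        self.event_axis = np.asarray(self.event_axis, dtype=float)
        self.changes = {k: np.asarray(v, dtype=float) for k, v in self.changes.items()}
        if self.event_axis[0] != 0:
            raise ValidationError("event_axis must start at 0")
        if np.any(np.diff(self.event_axis) <= 0):
            raise ValidationError("event_axis must be strictly increasing")
        for name, v in self.changes.items():
            if v.shape != self.event_axis.shape:
                raise ValidationError(f"trajectory '{name}' misaligned with event_axis")
            if v[0] != 0:
                raise ValidationError(f"trajectory '{name}' must start at 0 change")


# ---------------------------------------------------------------------------
# generation


def _build_covariance(
    n_objects: int, n_categories: int, config: StatsConfig
) -> np.ndarray:
    within = np.resize(np.asarray(config.within_category_corr, float), n_categories)
    between = float(config.between_category_corr)
    if np.any(within > 1) or np.any(within < 0):
        raise ValidationError("within_category_corr must lie in [0, 1]")
    if between < 0 or (n_categories > 1 and between > within.min()):
        # between-correlation above the weakest within-block level makes the
        # block matrix indefinite
        raise ValidationError(
            "between_category_corr must be <= min(within_category_corr) "
            f"({between} > {within.min()})"
        )
    block = n_objects // n_categories
    cats = np.minimum(np.arange(n_objects) // block, n_categories - 1)
    corr = np.full((n_objects, n_objects), between)
    for c in range(n_categories):
        idx = np.where(cats == c)[0]
        corr[np.ix_(idx, idx)] = within[c]
    np.fill_diagonal(corr, 1.0)
    return config.object_variance * corr


def _build_kernel_pool(rng: np.random.Generator, config: StatsConfig) -> np.ndarray:
    flat_lo, flat_hi = config.kernel_gain_range
    pk_lo, pk_hi = config.kernel_peak_range
    tr_lo, tr_hi = config.kernel_trough_range
    if min(flat_lo, pk_lo, tr_lo) < 0:
        raise ValidationError("kernel gain ranges must be non-negative")
    weights = np.asarray(config.kernel_mixture, dtype=float)
    weights = weights / weights.sum()
    shapes = rng.choice(4, size=config.n_kernels, p=weights)
    pool = np.empty((config.n_kernels, 3))
    for i, s in enumerate(shapes):
        if s == 0:  # flat (size-invariant gain)
            pool[i] = rng.uniform(flat_lo, flat_hi)
        elif s == 3:  # peaked at the medium (baseline) size
            pool[i] = (
                rng.uniform(tr_lo, tr_hi),
                rng.uniform(pk_lo, pk_hi),
                rng.uniform(tr_lo, tr_hi),
            )
        else:  # monotone across sizes
            lo_g = rng.uniform(tr_lo, tr_hi)
            hi_g = rng.uniform(pk_lo, pk_hi)
            mid = rng.uniform(lo_g, hi_g)
            tup = (lo_g, mid, hi_g) if s == 1 else (hi_g, mid, lo_g)
            pool[i] = tup
    return pool


def generate_population_statistics(
    n_objects: int = 64,
    n_categories: int = 8,
    seed: int = 0,
    config: StatsConfig | None = None,
) -> ITPopulationStats:
    """Generate synthetic population statistics for the generative IT model.

    Deterministic for a fixed ``seed``. The covariance has a block category
    structure (higher within- than between-category correlation); the kernel
    pool mixes flat, monotone and medium-peaked size-tuning shapes; clutter
    variances are drawn i.i.d. per object from a gamma distribution.
    """
    if n_objects < 2:
        raise ValidationError("n_objects must be >= 2")
    if n_categories < 1 or n_categories > n_objects:
        raise ValidationError("n_categories must be in [1, n_objects]")
    config = config or StatsConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    cov = _build_covariance(n_objects, n_categories, config)
    pool = _build_kernel_pool(rng, config)
    shape = config.clutter_var_shape
    clutter = rng.gamma(shape, config.clutter_var_mean / shape, size=n_objects)
    return ITPopulationStats(
        n_objects=n_objects,
        n_categories=n_categories,
        object_mean=np.zeros(n_objects),
        object_covariance=cov,
        size_kernel_pool=pool,
        clutter_variance_by_object=clutter,
        repetition_fano=config.repetition_fano,
        rate_scale=config.rate_scale,
        rate_offset=config.rate_offset,
    )


def generate_reference_trajectories(
    alpha_true: float,
    design: str = "li2010_size_swap",
    n_sites: int = 42,
    seed: int = 0,
    stats: ITPopulationStats | None = None,
    n_events_per_arrow: int = 400,
    n_checkpoints: int = 4,
) -> ReferencePlasticityTrajectory:
    """Synthetic stand-in for recorded single-site plasticity trajectories.

    Runs the single-site exposure-design replication on a freshly sampled
    population at ``alpha_true`` and averages the normalized selectivity
    change exactly as the plasticity-rate fit expects, enabling
    parameter-recovery tests without any archived data.
    """
    if design != "li2010_size_swap":
        raise ValidationError(f"unknown exposure design: {design!r}")
    if n_sites < 2:
        raise ValidationError("n_sites must be >= 2 for a robust mean")
    if not (0.0 <= alpha_true < 1.0):
        raise ValidationError("alpha_true must lie in [0, 1)")
    from .plasticity import PlasticityConfig, replicate_neural_exposure_design
    from .population import sample_population

    stats = stats or generate_population_statistics(seed=seed)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    pop_seed, design_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    pop = sample_population(stats, n_sites, seed=pop_seed)
    traj = replicate_neural_exposure_design(
        pop,
        PlasticityConfig(alpha=alpha_true),
        n_events_per_arrow=n_events_per_arrow,
        n_checkpoints=n_checkpoints,
        seed=design_seed,
    )
    return ReferencePlasticityTrajectory(
        exposure_design=design,
        event_axis=traj.event_axis,
        changes=traj.changes,
        n_reference_sites=n_sites,
    )


# ---------------------------------------------------------------------------
# adapter for recorded data


def load_recorded_statistics(path: str | Path) -> ITPopulationStats:
    """Compute population statistics from a recorded trial-level response table.

    ``path`` must be a CSV with columns
    ``site, object, size, exemplar, rep, response`` holding trial-averaged or
    trial-level responses on the z-score (nru) scale; sizes coded 0/1/2 for
    small/medium/big. Object means and the object covariance are computed
    across sites; size kernels are the per-site mean response by size
    (shifted to be non-negative); clutter variances are the across-exemplar
    variances per object; the repetition fano factor is fit from the
    variance-vs-mean relation across (site, object, size, exemplar) cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found; use generate_population_statistics() for "
            "synthetic statistics instead"
        )
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(
            f"could not parse {path} ({exc}); use "
            "generate_population_statistics() instead"
        ) from exc
    required = {"site", "object", "size", "exemplar", "rep", "response"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path} is missing columns {sorted(required - set(df.columns))}; "
            "use generate_population_statistics() instead"
        )

    n_objects = int(df["object"].max()) + 1
    # sites x objects trial-averaged matrix
    table = (
        df.groupby(["site", "object"])["response"].mean().unstack(fill_value=0.0)
    )
    table = table.reindex(columns=range(n_objects), fill_value=0.0)
    mean = table.mean(axis=0).to_numpy()
    cov = np.cov(table.to_numpy(), rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    # clip tiny negative eigenvalues from finite sampling
    eig, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    cov = (vecs * np.clip(eig, 0.0, None)) @ vecs.T
    cov = (cov + cov.T) / 2.0

    by_size = df.groupby(["site", "size"])["response"].mean().unstack()
    by_size = by_size.reindex(columns=[0, 1, 2]).ffill(axis=1).bfill(axis=1)
    kernels = by_size.to_numpy()
    kernels = kernels - kernels.min(axis=1, keepdims=True)  # shift non-negative
    flat = kernels.max(axis=1) <= 0
    kernels[flat] = 1.0  # flat tuning -> unit gain kernel

    cell = df.groupby(["object", "size", "site", "exemplar"])["response"].mean()
    clutter = np.zeros(n_objects)
    for o in range(n_objects):
        if o in cell.index.get_level_values(0):
            v = cell.loc[o].groupby(["size", "site"]).var(ddof=0)
            clutter[o] = float(np.nanmean(v)) if len(v) else 0.0
    clutter = np.nan_to_num(clutter)

    rate_scale, rate_offset = 23.0, 90.0
    rep = df.groupby(["site", "object", "size", "exemplar"])["response"].agg(
        ["mean", "var", "count"]
    )
    rep = rep[rep["count"] >= 2].dropna()
    if len(rep):
        rate = rate_offset + rate_scale * rep["mean"].to_numpy()
        var_spk = rep["var"].to_numpy() * rate_scale**2
        denom = float(np.sum(rate * rate))
        fano = float(np.sum(var_spk * rate) / denom) if denom > 0 else 1.0
        fano = max(fano, 0.0)
    else:
        fano = 1.0

    n_categories = max(1, n_objects // 8)
    return ITPopulationStats(
        n_objects=n_objects,
        n_categories=n_categories,
        object_mean=mean,
        object_covariance=cov,
        size_kernel_pool=kernels,
        clutter_variance_by_object=clutter,
        repetition_fano=fano,
        rate_scale=rate_scale,
        rate_offset=rate_offset,
    )
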