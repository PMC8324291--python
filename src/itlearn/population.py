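"""Generative model of IT population responses.

Each simulated site is one draw from a multi-dimensional Gaussian over the
object-preference space, multiplied (outer product) by a size-tuning kernel
drawn from a pool — a perfectly separable (size-tolerant) objects x sizes
response matrix. Responses to concrete images add a cached per-condition
clutter offset (background / exemplar identity) and, at the trial level,
repetition noise whose variance scales with the mean response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .stats import ITPopulationStats, ValidationError

__all__ = [
    "SMALL",
    "MEDIUM",
    "BIG",
    "SIZE_NAMES",
    "ImageCondition",
    "ITSite",
    "ITPopulation",
    "sample_population",
    "mean_response",
    "respond",
    "response_distance_matrix",
    "rsm_similarity",
    "unique_pairs",
    "gaussianity_fraction",
]

# presentation sizes: 0.5x / 1x / 2x of the ~2 degree baseline object
SMALL, MEDIUM, BIG = 0, 1, 2
SIZE_NAMES = {SMALL: "small", MEDIUM: "medium", BIG: "big"}

#: exemplar id of the clean (no background) exposure image
CLEAN = -1


class ImageCondition(NamedTuple):
    """An abstract image: an object, at a size, on an exemplar background.

    ``exemplar_id = -1`` denotes the clean exposure image, which carries no
    clutter term.
    """

    object_id: int
    size: int
    exemplar_id: int = CLEAN

    def validate(self, n_objects: int | None = None) -> "ImageCondition":
        if self.size not in (SMALL, MEDIUM, BIG):
            raise ValidationError(f"size must be one of 0/1/2, got {self.size}")
        if self.exemplar_id < CLEAN:
            raise ValidationError("exemplar_id must be >= -1")
        if n_objects is not None and not (0 <= self.object_id < n_objects):
            raise IndexError(f"object_id {self.object_id} out of range")
        return self


@dataclass
class ITSite:
    """View of one simulated site within a population."""

    population: "ITPopulation"
    site_id: int

    @property
    def base_matrix(self) -> np.ndarray:
        """(n_objects, 3) clean mean-response matrix (nru)."""
        return self.population.base[self.site_id]


class ITPopulation:
    """A population of simulated IT sites sharing one set of statistics.

    Attributes
    ----------
    prefs : (n_sites, n_objects) object-preference draws from the MDG.
    kernels : (n_sites, 3) size-tuning kernels.
    base : (n_sites, n_objects, 3) clean mean responses; plasticity edits
        this tensor in place.
    """

    def __init__(
        self,
        stats: ITPopulationStats,
        prefs: np.ndarray,
        kernels: np.ndarray,
        seed: int,
    ) -> None:
        self.stats = stats
        self.prefs = prefs
        self.kernels = kernels
        self.base = prefs[:, :, None] * kernels[:, None, :]
        self.n_sites = prefs.shape[0]
        self.seed = seed
        # dedicated stream for lazily drawn clutter offsets
        self._clutter_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(0xC1,))
        )
        self._clutter: dict[tuple[int, int], dict[int, np.ndarray]] = {}
        self._exemplar_counter = 0

    # -- sites --------------------------------------------------------------
    @property
    def sites(self) -> list[ITSite]:
        return [ITSite(self, i) for i in range(self.n_sites)]

    def site(self, i: int) -> ITSite:
        return ITSite(self, i)

    @property
    def n_objects(self) -> int:
        return self.stats.n_objects

    # -- exemplars ----------------------------------------------------------
    def new_exemplar_ids(self, k: int) -> np.ndarray:
        """Reserve ``k`` fresh exemplar identities."""
        ids = np.arange(self._exemplar_counter, self._exemplar_counter + k)
        self._exemplar_counter += k
        return ids

    def clutter_offsets(self, object_id: int, size: int, exemplar_ids) -> np.ndarray:
        """(n_exemplars, n_sites) cached clutter offsets for the conditions.

        Offsets for a given (object, size, exemplar) key are drawn once and
        never change: exemplar identity is fixed across test phases.
        """
        exemplar_ids = np.atleast_1d(exemplar_ids)
        cache = self._clutter.setdefault((object_id, size), {})
        out = np.zeros((len(exemplar_ids), self.n_sites))
        std = float(self.stats.clutter_std(object_id))
        missing = [e for e in exemplar_ids if e != CLEAN and e not in cache]
        if missing:
            draws = self._clutter_rng.normal(
                0.0, std, size=(len(missing), self.n_sites)
            )
            for e, row in zip(missing, draws):
                cache[int(e)] = row
        for i, e in enumerate(exemplar_ids):
            if e != CLEAN:
                out[i] = cache[int(e)]
        return out

    def mean_responses(self, object_id: int, size: int, exemplar_ids) -> np.ndarray:
        """(n_exemplars, n_sites) mean responses (clean mean + clutter)."""
        ImageCondition(object_id, size).validate(self.n_objects)
        return self.base[:, object_id, size] + self.clutter_offsets(
            object_id, size, exemplar_ids
        )


def sample_population(
    stats: ITPopulationStats, n_sites: int, seed: int = 0
) -> ITPopulation:
    """Draw a population: one MDG preference vector and one kernel per site."""
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    stats.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    prefs = rng.multivariate_normal(
        stats.object_mean, stats.object_covariance, size=n_sites, method="eigh"
    )
    kidx = rng.integers(len(stats.size_kernel_pool), size=n_sites)
    kernels = stats.size_kernel_pool[kidx]
    return ITPopulation(stats, prefs, kernels, seed=seed)


def mean_response(site: ITSite, cond: ImageCondition) -> float:
    """Mean (trial-averaged) response of one site to one image condition."""
    cond = ImageCondition(*cond).validate(site.population.n_objects)
    pop = site.population
    offset = pop.clutter_offsets(cond.object_id, cond.size, [cond.exemplar_id])
    return float(pop.base[site.site_id, cond.object_id, cond.size] + offset[0, site.site_id])


def respond(
    pop: ITPopulation, cond: ImageCondition, n_reps: int, seed: int = 0
) -> np.ndarray:
    """(n_sites, n_reps) trial-level responses with repetition noise."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    cond = ImageCondition(*cond).validate(pop.n_objects)
    mean = pop.mean_responses(cond.object_id, cond.size, [cond.exemplar_id])[0]
    var = pop.stats.repetition_variance(mean)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return mean[:, None] + rng.normal(size=(pop.n_sites, n_reps)) * np.sqrt(var)[:, None]


def response_distance_matrix(
    pop: ITPopulation,
    exemplars_per_object: int = 10,
    seed: int = 0,
    pool_sizes: bool = True,
) -> np.ndarray:
    """Pearson-correlation matrix between object population responses.

    For each object, the population response vector is the trial-averaged
    response over fresh exemplars (pooled over the three sizes by default, or
    medium only). Entries are raw Pearson correlations (not 1 - r); the
    diagonal is 1. Degenerate (constant) population vectors yield zero rows
    with a warning.
    """
    n_obj = pop.n_objects
    if n_obj < 2:
        raise ValidationError("need at least 2 objects")
    sizes = (SMALL, MEDIUM, BIG) if pool_sizes else (MEDIUM,)
    vectors = np.zeros((n_obj, pop.n_sites))
    for o in range(n_obj):
        acc = np.zeros(pop.n_sites)
        for z in sizes:
            ids = pop.new_exemplar_ids(exemplars_per_object)
            acc += pop.mean_responses(o, z, ids).mean(axis=0)
        vectors[o] = acc / len(sizes)
    stds = vectors.std(axis=1)
    degenerate = stds <= 0
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} object vectors are constant; their "
            "correlations are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(vectors)
    mat = np.nan_to_num(mat, nan=0.0)
    mat[degenerate, :] = 0.0
    mat[:, degenerate] = 0.0
    np.fill_diagonal(mat, 1.0)
    return mat


def unique_pairs(matrix: np.ndarray) -> np.ndarray:
    """Flat vector of the n(n-1)/2 unique off-diagonal entries."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def rsm_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two distance matrices' unique entries."""
    if a.shape != b.shape:
        raise ValidationError("distance matrices must have the same shape")
    x, y = unique_pairs(a), unique_pairs(b)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant distance vector; similarity defined as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def gaussianity_fraction(
    response_table: np.ndarray, p_threshold: float = 0.01
) -> float:
    """Fraction of object columns whose across-site distribution looks Gaussian.

    Applies a D'Agostino-type omnibus normality test to each column of the
    (sites x objects) table and reports the fraction NOT rejected at
    ``p_threshold``.
    """
    table = np.asarray(response_table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("response_table must be 2-D (sites x objects)")
    if table.shape[0] < 8:
        raise ValidationError("need at least 8 sites per object for the test")
    _, pvals = sps.normaltest(table, axis=0)
    return float(np.mean(pvals >= p_threshold))
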