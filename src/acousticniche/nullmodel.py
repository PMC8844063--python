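"""Geographically constrained null model and standardized effect sizes.

Each observed assemblage is compared against random assemblages of matching
richness drawn from its *species pool*: all species recorded in any
assemblage within a 50 km radius. Constraining the pool geographically keeps
the comparison local — random assemblages built from a continental pool would
make real assemblages look spuriously similar for reasons (habitat, climate)
that have nothing to do with acoustic competition.

The standardized effect size for a measure is

    SES = (observed − mean(null)) / sd(null)

with the sign reversed for spectral overlap (an overlap *below* the null
expectation means partitioning), so that positive SES always indicates
acoustic niche partitioning and negative SES aggregation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from datetime import date as date_type

import numpy as np
import pandas as pd

from .similarity import (
    MEASURES,
    PCA_MEASURE_SUBSET,
    CallTable,
    PairwiseMatrices,
    SIMILARITY_ORIENTED,
)

EARTH_RADIUS_KM = 6371.0088
DEFAULT_RADIUS_KM = 50.0
DEFAULT_N_NULL = 1000
DEFAULT_MIN_RICHNESS = 4


@dataclass(frozen=True)
class AssemblageRecord:
    """A georeferenced, dated set of species recorded calling together."""

    assemblage_id: str
    latitude: float
    longitude: float
    date: date_type
    species: frozenset[str]
    habitat: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.assemblage_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.assemblage_id}: longitude {self.longitude} out of range")
        if not self.species:
            raise ValueError(f"{self.assemblage_id}: empty species set")
        object.__setattr__(self, "species", frozenset(self.species))


@dataclass(frozen=True)
class SpeciesPool:
    """All species recorded within ``radius_km`` of a focal assemblage."""

    assemblage_id: str
    radius_km: float
    species: frozenset[str]
    n_extra: int  # pooled species not in the focal assemblage


@dataclass
class NullDistribution:
    """The randomized similarity values for one assemblage and measure."""

    assemblage_id: str
    measure: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        # all-identical values short-circuit: summation rounding would
        # otherwise leave the mean off by ~1 ulp and the sd spuriously > 0
        if np.ptp(self.values) == 0.0:
            return float(self.values[0])
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        # sample sd, n-1 denominator
        if np.ptp(self.values) == 0.0:
            return 0.0
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class SESResult:
    """Standardized effect size for one assemblage and measure."""

    assemblage_id: str
    measure: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when degenerate (null_sd == 0)
    sign_reversed: bool

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.ses)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or numpy arrays (broadcast)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("longitude out of range [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def build_pool(
    focal: AssemblageRecord,
    assemblages: list[AssemblageRecord],
    radius_km: float = DEFAULT_RADIUS_KM,
) -> SpeciesPool:
    """Union of species over every assemblage within ``radius_km`` of the
    focal one (inclusive boundary; the focal assemblage itself counts)."""
    lats = np.array([a.latitude for a in assemblages])
    lons = np.array([a.longitude for a in assemblages])
    dists = haversine_km(focal.latitude, focal.longitude, lats, lons)
    pool: set[str] = set(focal.species)
    for rec, d in zip(assemblages, np.atleast_1d(dists)):
        if d <= radius_km:
            pool.update(rec.species)
    return SpeciesPool(
        assemblage_id=focal.assemblage_id,
        radius_km=radius_km,
        species=frozenset(pool),
        n_extra=len(pool) - len(focal.species),
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def required_species(table: CallTable, measures: tuple[str, ...]) -> pd.Index:
    """Species usable for the given measure set: all six parameters for any
    PCA or overlap measure, dominant frequency only if the set is just
    domfreq_distance."""
    needs_all6 = any(m in PCA_MEASURE_SUBSET or m == "spectral_overlap" for m in measures)
    return table.complete_species if needs_all6 else table.domfreq_species


def filter_dataset(
    assemblages: list[AssemblageRecord],
    table: CallTable,
    measures: tuple[str, ...] = MEASURES,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_richness: int = DEFAULT_MIN_RICHNESS,
) -> tuple[list[AssemblageRecord], dict[str, SpeciesPool], pd.DataFrame]:
    """Apply the dataset filters and build species pools.

    Retains assemblages with (1) at least ``min_richness`` species,
    (2) call parameters available for every species present (all six for the
    PCA/overlap measures, dominant frequency only for a domfreq-only run),
    and (3) at least one extra species within ``radius_km``. Pools are built
    from the assemblages surviving (1)+(2), so every pooled species is
    measurable in null draws. Returns retained records, pools keyed by
    assemblage id, and an exclusion log naming the first violated rule per
    dropped assemblage.
    """
    usable = set(required_species(table, measures))
    exclusions: list[tuple[str, str, str]] = []
    covered: list[AssemblageRecord] = []
    for rec in assemblages:
        if len(rec.species) < min_richness:
            exclusions.append((rec.assemblage_id, "min_richness",
                               f"{len(rec.species)} < {min_richness}"))
            continue
        missing = sorted(rec.species - usable)
        if missing:
            exclusions.append((rec.assemblage_id, "missing_parameters",
                               ";".join(missing)))
            continue
        covered.append(rec)

    retained: list[AssemblageRecord] = []
    pools: dict[str, SpeciesPool] = {}
    for rec in covered:
        pool = build_pool(rec, covered, radius_km=radius_km)
        if pool.n_extra < 1:
            exclusions.append((rec.assemblage_id, "no_extra_species_in_pool",
                               f"pool size {len(pool.species)}"))
            continue
        retained.append(rec)
        pools[rec.assemblage_id] = pool
    log = pd.DataFrame(exclusions, columns=["assemblage_id", "rule", "detail"])
    return retained, pools, log


# ---------------------------------------------------------------------------
# Null sampling
# ---------------------------------------------------------------------------

def sample_null_assemblage(
    pool: SpeciesPool | set[str] | frozenset[str],
    size: int,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Uniform sample of ``size`` distinct species from the pool (without
    replacement); reproducible under a seeded generator."""
    species = sorted(pool.species if isinstance(pool, SpeciesPool) else pool)
    if size > len(species):
        raise ValueError(f"cannot draw {size} species from pool of {len(species)}")
    idx = rng.choice(len(species), size=size, replace=False)
    return frozenset(species[i] for i in idx)


def _sample_index_batch(
    pool_idx: np.ndarray, size: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """n_draws uniform without-replacement samples of pool indices, drawn
    as the first ``size`` entries of independent random permutations."""
    keys = rng.random((n_draws, len(pool_idx)))
    order = np.argsort(keys, axis=1)[:, :size]
    # sort within draws: identical species sets then sum in identical order,
    # so a pool equal to the focal assemblage yields sd exactly 0
    return np.sort(pool_idx[order], axis=1)


def assemblage_rng(master_seed: int, assemblage_id: str) -> np.random.Generator:
    """Child random generator keyed by assemblage id, so results do not
    depend on processing order."""
    key = zlib.crc32(str(assemblage_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def null_distribution(
    focal: AssemblageRecord,
    pool: SpeciesPool,
    matrices: PairwiseMatrices,
    n_null: int = DEFAULT_N_NULL,
    rng: np.random.Generator | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> dict[str, NullDistribution]:
    """Similarity of ``n_null`` random matching-size assemblages from the
    pool, computed for each measure via the same pairwise machinery as the
    observed assemblages."""
    if rng is None:
        rng = np.random.default_rng()
    k = len(focal.species)
    pool_idx = np.array(sorted(matrices.index_of[s] for s in pool.species))
    if k > len(pool_idx):
        raise ValueError("pool smaller than focal assemblage")
    draws = _sample_index_batch(pool_idx, k, n_null, rng)  # (n_null, k)
    iu, ju = np.triu_indices(k, 1)
    rows = draws[:, iu]
    cols = draws[:, ju]
    out: dict[str, NullDistribution] = {}
    for measure in measures:
        M = matrices.matrices[measure]
        vals = M[rows, cols].mean(axis=1)
        out[measure] = NullDistribution(
            assemblage_id=focal.assemblage_id, measure=measure, values=vals
        )
    return out


def standardized_effect_size(
    observed: float, null: NullDistribution, measure: str
) -> SESResult:
    """SES = (observed − null mean)/null sd, sign-reversed for spectral
    overlap so positive always means partitioning. A zero null sd yields a
    degenerate (NaN) SES rather than an error."""
    mean, sd = null.mean, null.sd
    reversed_ = measure in SIMILARITY_ORIENTED
    if sd > 0:
        ses = (observed - mean) / sd
        if reversed_:
            ses = -ses
    else:
        ses = float("nan")
    return SESResult(
        assemblage_id=null.assemblage_id,
        measure=measure,
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        ses=ses,
        sign_reversed=reversed_,
    )


def proportion_below_null_mean(ses_results: list[SESResult] | pd.DataFrame) -> float:
    """Fraction of (non-degenerate) assemblages less acoustically similar
    than their null mean — i.e. with SES > 0 after the sign convention."""
    if isinstance(ses_results, pd.DataFrame):
        ses = ses_results["ses"].to_numpy(dtype=float)
    else:
        ses = np.array([r.ses for r in ses_results], dtype=float)
    ses = ses[np.isfinite(ses)]
    if len(ses) == 0:
        raise ValueError("no non-degenerate assemblages")
    return float(np.mean(ses > 0))


def run_null_model(
    assemblages: list[AssemblageRecord],
    pools: dict[str, SpeciesPool],
    matrices: PairwiseMatrices,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    measures: tuple[str, ...] = MEASURES,
) -> pd.DataFrame:
    """Observed similarity, null distribution and SES for every assemblage
    and measure. Returns a tidy frame with one row per assemblage × measure.

    Randomness uses per-assemblage child streams of ``seed``, so the result
    is independent of iteration order.
    """
    records = []
    for rec in assemblages:
        pool = pools[rec.assemblage_id]
        rng = assemblage_rng(seed, rec.assemblage_id)
        nulls = null_distribution(rec, pool, matrices, n_null, rng, measures)
        for measure in measures:
            obs = matrices.assemblage_mean(rec.species, measure)
            res = standardized_effect_size(obs, nulls[measure], measure)
            records.append(
                {
                    "assemblage_id": rec.assemblage_id,
                    "measure": measure,
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "ses": res.ses,
                    "n_species": len(rec.species),
                    "n_extra_50km": pool.n_extra,
                }
            )
    return pd.DataFrame.from_records(records)
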