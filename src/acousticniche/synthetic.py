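"""Synthetic call audio and assemblage datasets with known ground truth.

Two generators make the whole pipeline testable without any real data:

* :func:`gen_call_audio` synthesises a single-call waveform (a pulse train
  of Hann-windowed tonal notes) whose dominant frequency, note rate and
  envelope peak position are known exactly from the generating parameters.

* :func:`gen_dataset` builds a full occurrence dataset: a regional species
  pool with log10-scale call traits, spatially clustered recording sites
  (clusters far beyond the 50 km pooling radius, sites within it), and
  assemblages assembled from the local cluster pool either uniformly at
  random (the null scenario) or with repulsion/attraction in acoustic
  space. Repulsion acts on dominant-frequency distance: species join an
  assemblage with probability proportional to exp(+beta * min distance to
  the members already chosen), so large beta forces spectral spacing while
  leaving temporal traits untouched — a built-in negative control for the
  temporal similarity measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .calls import CallParams, Waveform
from .nullmodel import AssemblageRecord, haversine_km, sample_null_assemblage
from .similarity import CallTable, PARAM_COLS


@dataclass(frozen=True)
class SyntheticCallSpec:
    """Parameters of one synthetic single-call recording."""

    carrier_hz: float = 2000.0
    bandwidth_hz: float = 300.0  # FM sweep width
    pulse_rate: float = 8.0  # notes per second (note-onset rate)
    n_notes: int = 8
    note_duration: float = 0.06  # seconds; must leave silence between notes
    peak_position: float = 0.5  # where the loudest note sits, 0-1
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_rate * self.note_duration >= 1.0:
            raise ValueError("notes must be separated by silence "
                             "(pulse_rate * note_duration < 1)")
        if not 0 <= self.peak_position <= 1:
            raise ValueError("peak_position must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration for a full synthetic assemblage dataset."""

    n_species: int = 30
    n_sites: int = 500
    n_clusters: int = 5
    mode: str = "random"  # random | repulsion | attraction
    beta: float = 0.0
    mean_richness: float = 6.0  # truncated-Poisson mean, minimum 4
    min_richness: int = 4
    cluster_pool_size: int = 12
    # trait distribution: log10 dominant frequency ~ Normal(mu_f, sigma_f)
    mu_f: float = 3.30  # ~2 kHz
    sigma_f: float = 0.25
    bw_mean_log10: float = 0.15  # 90% bandwidth in log10 Hz
    bw_sd_log10: float = 0.05
    map_extent: tuple[float, float, float, float] = (-38.0, -16.0, 116.0, 152.0)
    cluster_spread_km: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "repulsion", "attraction"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.cluster_pool_size > self.n_species:
            raise ValueError("cluster pool larger than the species pool")


# ---------------------------------------------------------------------------
# Call audio
# ---------------------------------------------------------------------------

def gen_call_audio(
    spec: SyntheticCallSpec, sample_rate: int = 44100
) -> tuple[Waveform, CallParams]:
    """Synthesise one call and return it with ground-truth parameters.

    The call is a train of ``n_notes`` Hann-windowed notes (a linear FM
    sweep of ``bandwidth_hz`` around the carrier) with note amplitudes
    following a triangular profile peaking at ``peak_position``. Ground
    truth: dominant frequency = carrier; note rate = n_notes / call
    duration; peak time = realized argmax position of the constructed
    amplitude profile (exact, since the call is discrete in notes).
    """
    if not 0 < spec.carrier_hz < sample_rate / 2:
        raise ValueError(f"carrier {spec.carrier_hz} Hz violates Nyquist "
                         f"({sample_rate / 2} Hz)")
    period = 1.0 / spec.pulse_rate
    note_len = int(round(spec.note_duration * sample_rate))
    call_duration = (spec.n_notes - 1) * period + spec.note_duration
    n_total = int(round(((spec.n_notes - 1) * period + spec.note_duration
                         + 0.05) * sample_rate)) + 1
    samples = np.zeros(n_total)
    t_note = np.arange(note_len) / sample_rate
    window = np.hanning(note_len)
    # FM sweep symmetric about the carrier keeps the spectral peak there
    f0 = spec.carrier_hz - spec.bandwidth_hz / 2
    sweep = f0 * t_note + spec.bandwidth_hz / (2 * spec.note_duration) * t_note**2
    tone = np.sin(2 * np.pi * sweep)

    # triangular amplitude profile over note indices, floored well above
    # the 10% silence threshold used in note segmentation
    centers_rel = (np.arange(spec.n_notes) * period + spec.note_duration / 2) / call_duration
    prof = 1.0 - np.abs(centers_rel - spec.peak_position)
    prof = 0.4 + 0.6 * (prof - prof.min()) / max(prof.max() - prof.min(), 1e-12)

    peak_note = int(np.argmax(prof))  # ties -> earliest, as in measurement
    for j in range(spec.n_notes):
        start = int(round(j * period * sample_rate))
        samples[start : start + note_len] += spec.amplitude * prof[j] * window * tone

    # ground-truth peak time: centre of the loudest note's Hann peak,
    # relative to the call extent (onset of first note to end of last)
    t_start = 0.0
    t_peak = peak_note * period + spec.note_duration / 2
    truth = CallParams(
        species_id=f"synthetic_{spec.seed}",
        freq5=float(np.log10(max(f0, 1.0))),
        freq95=float(np.log10(spec.carrier_hz + spec.bandwidth_hz / 2)),
        dom_freq=float(np.log10(spec.carrier_hz)),
        dur90=0.9 * call_duration,
        peak_time_rel=(t_peak - t_start) / call_duration,
        note_rate=spec.n_notes / call_duration,
    )
    return Waveform(samples=samples, sample_rate=sample_rate), truth


def random_call_spec(rng: np.random.Generator) -> SyntheticCallSpec:
    """A realistic random call: carrier log-uniform over 600 Hz - 6 kHz,
    moderate FM bandwidth, 4-14 notes/s with duty cycle 30-70%."""
    pulse_rate = float(rng.uniform(4.0, 14.0))
    return SyntheticCallSpec(
        carrier_hz=float(10 ** rng.uniform(np.log10(600.0), np.log10(6000.0))),
        bandwidth_hz=float(rng.uniform(50.0, 400.0)),
        pulse_rate=pulse_rate,
        n_notes=int(rng.integers(4, 13)),
        note_duration=float(rng.uniform(0.3, 0.7)) / pulse_rate,
        peak_position=float(rng.uniform(0.1, 0.9)),
        seed=int(rng.integers(2**31)),
    )


# ---------------------------------------------------------------------------
# Species traits
# ---------------------------------------------------------------------------

def gen_species_traits(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> CallTable:
    """Draw one six-parameter trait vector per species.

    Dominant frequencies are Normal on the log10 scale; the 90% bandwidth
    is placed symmetrically around the dominant frequency; temporal traits
    are drawn independently of the spectral ones.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.n_species
    dom = rng.normal(scenario.mu_f, scenario.sigma_f, n)
    bw = np.abs(rng.normal(scenario.bw_mean_log10, scenario.bw_sd_log10, n))
    bw = np.maximum(bw, 0.02)
    dur = rng.lognormal(np.log(0.8), 0.4, n)
    peak = rng.beta(2.0, 2.0, n)
    rate = rng.lognormal(np.log(8.0), 0.5, n)
    ids = [f"sp{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "freq5_log10hz": dom - bw / 2,
            "freq95_log10hz": dom + bw / 2,
            "domfreq_log10hz": dom,
            "dur90_s": dur,
            "peaktime_rel": peak,
            "note_rate_hz": rate,
        },
        index=pd.Index(ids, name="species_id"),
    )
    return CallTable(df)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

KM_PER_DEG_LAT = 111.32


def gen_sites(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Clustered site coordinates: cluster centres spread on a coarse grid
    over the map extent (pairwise distances far beyond 50 km), sites
    scattered within ``cluster_spread_km`` of their centre. Returns a frame
    with site_id, latitude, longitude, cluster."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    lat0, lat1, lon0, lon1 = scenario.map_extent
    k = scenario.n_clusters
    # grid layout guarantees inter-centre separation
    ncol = int(np.ceil(np.sqrt(k)))
    nrow = int(np.ceil(k / ncol))
    lats = np.linspace(lat0, lat1, nrow + 2)[1:-1]
    lons = np.linspace(lon0, lon1, ncol + 2)[1:-1]
    centers = [(la, lo) for la in lats for lo in lons][:k]
    spread_lat = scenario.cluster_spread_km / KM_PER_DEG_LAT
    rows = []
    for i in range(scenario.n_sites):
        c = i % k
        cla, clo = centers[c]
        la = cla + rng.normal(0, spread_lat / 2)
        lo = clo + rng.normal(0, spread_lat / 2) / np.cos(np.radians(cla))
        rows.append({"site_id": f"site{i:04d}", "latitude": la,
                     "longitude": lo, "cluster": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def assemble_community(
    local_pool,
    richness: int,
    mode: str,
    beta: float,
    table: CallTable,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Draw one assemblage of ``richness`` species from a local pool.

    ``random`` (or beta == 0) is a uniform draw without replacement — the
    identical law to the null-model sampler, by shared implementation.
    ``repulsion`` builds the set sequentially, each candidate joining with
    probability proportional to exp(+beta * min dominant-frequency distance
    to the current members); ``attraction`` uses exp(-beta * ...).
    """
    pool = sorted(local_pool)
    if richness > len(pool):
        raise ValueError(f"richness {richness} exceeds pool size {len(pool)}")
    if mode == "random" or beta == 0.0:
        return sample_null_assemblage(frozenset(pool), richness, rng)
    sign = 1.0 if mode == "repulsion" else -1.0
    dom = table.params["domfreq_log10hz"]
    freqs = {s: float(dom.loc[s]) for s in pool}
    members = [pool[int(rng.integers(len(pool)))]]
    remaining = [s for s in pool if s != members[0]]
    while len(members) < richness:
        mind = np.array(
            [min(abs(freqs[s] - freqs[m]) for m in members) for s in remaining]
        )
        logw = sign * beta * mind
        w = np.exp(logw - logw.max())
        w /= w.sum()
        pick = int(rng.choice(len(remaining), p=w))
        members.append(remaining.pop(pick))
    return frozenset(members)


def _truncated_poisson(
    mean: float, minimum: int, maximum: int, rng: np.random.Generator
) -> int:
    """Poisson draw shifted/rejected to [minimum, maximum]."""
    for _ in range(1000):
        k = int(rng.poisson(mean))
        if minimum <= k <= maximum:
            return k
    return minimum


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground-truth manifest."""

    assemblages: list[AssemblageRecord]
    table: CallTable
    manifest: dict = field(default_factory=dict)


def gen_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate a complete assemblage dataset under the scenario.

    Each cluster receives a regional pool of roughly ``cluster_pool_size``
    species (sizes vary by ±2 between clusters, as regional richness does;
    pools are contiguous blocks of the species list, wrapping, so
    neighbouring clusters share some species); every site's assemblage is
    assembled from its cluster pool under the scenario's mode. Dates are
    spread across one year; habitat labels follow the cluster.
    """
    rng = np.random.default_rng(scenario.seed)
    table = gen_species_traits(scenario, np.random.default_rng(scenario.seed + 10))
    sites = gen_sites(scenario, np.random.default_rng(scenario.seed + 20))
    species = list(table.params.index)
    k = scenario.n_clusters
    pools = []
    step = max(1, (scenario.n_species - scenario.cluster_pool_size) // max(k - 1, 1)) \
        if k > 1 else 0
    sizes = scenario.cluster_pool_size + rng.integers(-2, 3, size=k)
    sizes = np.clip(sizes, scenario.min_richness + 2, scenario.n_species)
    for c in range(k):
        start = (c * step) % scenario.n_species
        pool = [species[(start + j) % scenario.n_species]
                for j in range(int(sizes[c]))]
        pools.append(sorted(set(pool)))

    start_date = date(2018, 1, 1)
    records = []
    per_assemblage = {}
    for row in sites.itertuples(index=False):
        pool = pools[row.cluster]
        max_rich = len(pool) - 1  # leaves >= 1 extra species in the pool
        rich = _truncated_poisson(scenario.mean_richness, scenario.min_richness,
                                  max_rich, rng)
        comm = assemble_community(pool, rich, scenario.mode, scenario.beta,
                                  table, rng)
        rec = AssemblageRecord(
            assemblage_id=row.site_id,
            latitude=float(row.latitude),
            longitude=float(row.longitude),
            date=start_date + timedelta(days=int(rng.integers(0, 365))),
            species=comm,
            habitat=f"habitat{row.cluster}",
        )
        records.append(rec)
        per_assemblage[row.site_id] = {"cluster": int(row.cluster),
                                       "mode": scenario.mode,
                                       "beta": scenario.beta}
    manifest = {
        "seed": scenario.seed,
        "mode": scenario.mode,
        "beta": scenario.beta,
        "n_species": scenario.n_species,
        "n_sites": scenario.n_sites,
        "n_clusters": scenario.n_clusters,
        "cluster_pools": {f"cluster{c}": pools[c] for c in range(k)},
        "assemblages": per_assemblage,
    }
    return SyntheticDataset(assemblages=records, table=table, manifest=manifest)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write assemblages.csv, calls.csv and manifest.json in the schemas the
    pipeline readers consume."""
    from .io import write_assemblages, write_call_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assemblages": out / "assemblages.csv",
        "calls": out / "calls.csv",
        "manifest": out / "manifest.json",
    }
    write_assemblages(dataset.assemblages, paths["assemblages"])
    write_call_table(dataset.table, paths["calls"])
    paths["manifest"].write_text(json.dumps(dataset.manifest, indent=2))
    return paths
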