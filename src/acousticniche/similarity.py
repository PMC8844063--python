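"""Acoustic-similarity measures between species and assemblages.

Five measures quantify how similar the calls of co-occurring species are:

* ``PCA_All`` / ``PCA_Spectral`` / ``PCA_Temporal`` — mean pairwise Euclidean
  distance between species scores on the first three principal components of
  a centred-and-scaled PCA over all six, the three spectral, or the three
  temporal call parameters respectively (distance d, larger = less similar);
* ``spectral_overlap`` — mean proportion of overlap between two species'
  90% log10 frequency bandwidths (p in [0, 1], larger = more similar);
* ``domfreq_distance`` — absolute distance between log10 dominant
  frequencies (log10 Hz, larger = less similar).

Assemblage-level values are unweighted means over all unordered species pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .calls import BIN_WIDTH_HZ, CallParams

#: CSV column names for the six parameters, in canonical order.
PARAM_COLS = [
    "freq5_log10hz",
    "freq95_log10hz",
    "domfreq_log10hz",
    "dur90_s",
    "peaktime_rel",
    "note_rate_hz",
]
SPECTRAL_COLS = PARAM_COLS[:3]
TEMPORAL_COLS = PARAM_COLS[3:]

SUBSET_COLS = {
    "All": PARAM_COLS,
    "Spectral": SPECTRAL_COLS,
    "Temporal": TEMPORAL_COLS,
}

#: The five similarity measures, in reporting order.
MEASURES = (
    "PCA_All",
    "PCA_Spectral",
    "PCA_Temporal",
    "spectral_overlap",
    "domfreq_distance",
)
#: Measures where a larger value means *more* similar (sign is reversed
#: when standardising effect sizes).
SIMILARITY_ORIENTED = frozenset({"spectral_overlap"})

PCA_MEASURE_SUBSET = {
    "PCA_All": "All",
    "PCA_Spectral": "Spectral",
    "PCA_Temporal": "Temporal",
}


class MissingParametersError(ValueError):
    """Raised when species required for a computation lack call parameters."""


@dataclass
class CallTable:
    """Species call-parameter table.

    One row per species (multiple measured calls per species are averaged on
    the stored scales). A species is *complete* when all six parameters are
    present, and *domfreq-only* when just the dominant frequency is known
    (e.g. taken from published literature).
    """

    params: pd.DataFrame  # index: species_id; columns: PARAM_COLS

    def __post_init__(self) -> None:
        missing = [c for c in PARAM_COLS if c not in self.params.columns]
        if missing:
            raise ValueError(f"call table missing columns: {missing}")
        if self.params.index.has_duplicates:
            dupes = self.params.index[self.params.index.duplicated()].unique()
            raise ValueError(f"duplicate species_id: {list(dupes)}")
        self.params = self.params[PARAM_COLS].astype(float)

    @classmethod
    def from_callparams(cls, calls: list[CallParams]) -> "CallTable":
        """Build a table from measured calls, averaging repeats per species."""
        rows = pd.DataFrame(
            {
                "species_id": [c.species_id for c in calls],
                "freq5_log10hz": [c.freq5 for c in calls],
                "freq95_log10hz": [c.freq95 for c in calls],
                "domfreq_log10hz": [c.dom_freq for c in calls],
                "dur90_s": [c.dur90 for c in calls],
                "peaktime_rel": [c.peak_time_rel for c in calls],
                "note_rate_hz": [c.note_rate for c in calls],
            }
        )
        return cls(rows.groupby("species_id").mean())

    @property
    def complete_species(self) -> pd.Index:
        """Species with all six parameters measured."""
        return self.params.index[self.params.notna().all(axis=1)]

    @property
    def domfreq_species(self) -> pd.Index:
        """Species with at least a dominant frequency."""
        return self.params.index[self.params["domfreq_log10hz"].notna()]

    def species_with(self, columns: list[str]) -> pd.Index:
        return self.params.index[self.params[columns].notna().all(axis=1)]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.params.index

    def __len__(self) -> int:
        return len(self.params)


@dataclass
class PCSpace:
    """A fitted principal-component space over one parameter subset.

    Species scores live on the first three components of a PCA of the
    centred-and-scaled parameters; pairwise Euclidean distances between
    scores are the PCA_* similarity measures.
    """

    subset: str
    columns: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_params, 3), columns orthonormal
    scores: pd.DataFrame  # index species_id, columns PC1..PC3
    eigenvalues: np.ndarray  # all components; sums to n_params (correlation PCA)
    explained_var: np.ndarray  # fractions over all components

    def score(self, species_id: str) -> np.ndarray:
        if species_id not in self.scores.index:
            raise KeyError(f"species {species_id!r} not scored in PCA_{self.subset}")
        return self.scores.loc[species_id].to_numpy()


def fit_pca(table: CallTable, subset: str = "All") -> PCSpace:
    """Fit a correlation-matrix PCA over one parameter subset.

    Variables are centred and scaled (sd with n-1 denominator) across all
    species complete for the subset; exactly three components are retained
    (the full space for three-parameter subsets). Component signs are fixed
    by forcing each component's largest-magnitude loading positive.
    """
    if subset not in SUBSET_COLS:
        raise ValueError(f"unknown subset {subset!r}")
    cols = SUBSET_COLS[subset]
    species = table.species_with(cols)
    if len(species) < 4:
        raise ValueError(
            f"PCA_{subset} needs >= 4 complete species, got {len(species)}"
        )
    values = table.params.loc[species, cols].to_numpy()
    center = values.mean(axis=0)
    scale = values.std(axis=0, ddof=1)
    zero_var = [c for c, s in zip(cols, scale) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance parameter(s): {zero_var}")
    X = (values - center) / scale
    # SVD of the standardized matrix: principal axes are rows of Vt
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (len(species) - 1)
    loadings = Vt[:3].T.copy()
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    scores = X @ loadings
    return PCSpace(
        subset=subset,
        columns=list(cols),
        center=center,
        scale=scale,
        loadings=loadings,
        scores=pd.DataFrame(
            scores, index=species, columns=["PC1", "PC2", "PC3"]
        ),
        eigenvalues=eigvals,
        explained_var=eigvals / eigvals.sum(),
    )


def pc_distance(space: PCSpace, a: str, b: str) -> float:
    """Euclidean distance between two species in the PC space."""
    return float(np.linalg.norm(space.score(a) - space.score(b)))


def _floored_bandwidth(f5: float, f95: float) -> float:
    """90% bandwidth in log10 Hz, floored at one spectral bin above f5 so
    degenerate single-bin calls never yield a zero denominator."""
    floor = np.log10(10.0**f5 + BIN_WIDTH_HZ) - f5
    bw = f95 - f5
    if bw < 0:
        raise ValueError(f"negative bandwidth: freq5={f5}, freq95={f95}")
    return max(bw, floor)


def spectral_overlap(a, b) -> float:
    """Mean proportion of overlap between two species' 90% log10 frequency
    bandwidths: the overlap length as a fraction of each bandwidth, averaged.

    Accepts CallParams or any objects with ``freq5``/``freq95`` attributes,
    or (f5, f95) pairs.
    """
    f5a, f95a = _interval(a)
    f5b, f95b = _interval(b)
    L = max(0.0, min(f95a, f95b) - max(f5a, f5b))
    bwa = _floored_bandwidth(f5a, f95a)
    bwb = _floored_bandwidth(f5b, f95b)
    return 0.5 * (L / bwa + L / bwb)


def _interval(x) -> tuple[float, float]:
    if hasattr(x, "freq5"):
        f5, f95 = float(x.freq5), float(x.freq95)
    else:
        f5, f95 = float(x[0]), float(x[1])
    if np.isnan(f5) or np.isnan(f95):
        raise MissingParametersError("missing freq5/freq95")
    return f5, f95


def domfreq_distance(a, b) -> float:
    """Absolute distance between two species' log10 dominant frequencies."""
    fa = float(a.dom_freq) if hasattr(a, "dom_freq") else float(a)
    fb = float(b.dom_freq) if hasattr(b, "dom_freq") else float(b)
    if np.isnan(fa) or np.isnan(fb):
        raise MissingParametersError("missing dominant frequency")
    return abs(fa - fb)


def fit_all_spaces(table: CallTable) -> dict[str, PCSpace]:
    """Fit the three PC spaces (All, Spectral, Temporal) on the full table."""
    return {s: fit_pca(table, s) for s in SUBSET_COLS}


def assemblage_similarity(
    species: set[str] | list[str],
    table: CallTable,
    spaces: dict[str, PCSpace],
    measures: tuple[str, ...] = MEASURES,
) -> dict[str, float]:
    """Mean pairwise acoustic similarity of an assemblage for each measure.

    Each value is the unweighted mean over all C(n, 2) unordered species
    pairs; requires >= 2 species with the parameters each measure needs.
    """
    ids = sorted(set(species))
    if len(ids) < 2:
        raise ValueError("assemblage similarity needs >= 2 species")
    missing = [s for s in ids if s not in table]
    if missing:
        raise MissingParametersError(f"species not in call table: {missing}")
    out: dict[str, float] = {}
    rows = table.params.loc[ids]
    pairs = list(combinations(range(len(ids)), 2))
    for measure in measures:
        if measure in PCA_MEASURE_SUBSET:
            space = spaces[PCA_MEASURE_SUBSET[measure]]
            not_scored = [s for s in ids if s not in space.scores.index]
            if not_scored:
                raise MissingParametersError(
                    f"{measure}: species missing parameters: {not_scored}"
                )
            pts = space.scores.loc[ids].to_numpy()
            vals = [np.linalg.norm(pts[i] - pts[j]) for i, j in pairs]
        elif measure == "spectral_overlap":
            _check_present(rows, ["freq5_log10hz", "freq95_log10hz"], measure)
            f5 = rows["freq5_log10hz"].to_numpy()
            f95 = rows["freq95_log10hz"].to_numpy()
            vals = [spectral_overlap((f5[i], f95[i]), (f5[j], f95[j])) for i, j in pairs]
        elif measure == "domfreq_distance":
            _check_present(rows, ["domfreq_log10hz"], measure)
            dom = rows["domfreq_log10hz"].to_numpy()
            vals = [abs(dom[i] - dom[j]) for i, j in pairs]
        else:
            raise ValueError(f"unknown measure {measure!r}")
        out[measure] = float(np.mean(vals))
    return out


def _check_present(rows: pd.DataFrame, cols: list[str], measure: str) -> None:
    bad = rows.index[rows[cols].isna().any(axis=1)]
    if len(bad):
        raise MissingParametersError(
            f"{measure}: species missing parameters: {list(bad)}"
        )


# ---------------------------------------------------------------------------
# Vectorised pairwise machinery (used by the null model)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseMatrices:
    """Dense species-by-species matrices of all five pairwise measures.

    Precomputing these lets assemblage and null-assemblage means be read off
    as sub-matrix averages instead of re-deriving every pair.
    """

    ids: pd.Index
    matrices: dict[str, np.ndarray]
    index_of: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index_of = {s: i for i, s in enumerate(self.ids)}

    def assemblage_mean(self, species, measure: str) -> float:
        idx = np.array(sorted(self.index_of[s] for s in species))
        M = self.matrices[measure][np.ix_(idx, idx)]
        n = len(idx)
        return float(M[np.triu_indices(n, 1)].mean())


def pairwise_matrices(
    table: CallTable,
    spaces: dict[str, PCSpace],
    species: list[str] | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> PairwiseMatrices:
    """Compute the pairwise similarity matrix for each measure over the
    given species (default: all species complete for every measure)."""
    if species is None:
        species = list(table.complete_species)
    ids = pd.Index(sorted(species))
    rows = table.params.loc[ids]
    n = len(ids)
    out: dict[str, np.ndarray] = {}
    for measure in measures:
        if measure in PCA_MEASURE_SUBSET:
            pts = spaces[PCA_MEASURE_SUBSET[measure]].scores.loc[ids].to_numpy()
            diff = pts[:, None, :] - pts[None, :, :]
            out[measure] = np.sqrt((diff**2).sum(-1))
        elif measure == "spectral_overlap":
            f5 = rows["freq5_log10hz"].to_numpy()
            f95 = rows["freq95_log10hz"].to_numpy()
            bw = np.array([_floored_bandwidth(a, b) for a, b in zip(f5, f95)])
            L = np.maximum(
                0.0,
                np.minimum(f95[:, None], f95[None, :])
                - np.maximum(f5[:, None], f5[None, :]),
            )
            out[measure] = 0.5 * (L / bw[:, None] + L / bw[None, :])
        elif measure == "domfreq_distance":
            dom = rows["domfreq_log10hz"].to_numpy()
            out[measure] = np.abs(dom[:, None] - dom[None, :])
        else:
            raise ValueError(f"unknown measure {measure!r}")
        if np.isnan(out[measure]).any():
            bad = ids[np.isnan(out[measure]).any(axis=0)]
            raise MissingParametersError(
                f"{measure}: species missing parameters: {list(bad)}"
            )
    return PairwiseMatrices(ids=ids, matrices=out)
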