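"""End-to-end analysis pipeline.

Stage order: read inputs -> filter assemblages and build 50 km pools ->
fit PC spaces -> observed similarity -> null distributions -> standardized
effect sizes -> BCa bootstrap summaries -> optional mixed-model check.
Every stage is deterministic under the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .inference import (
    DEFAULT_LEVEL,
    DEFAULT_N_BOOT,
    bca_ci,
    fit_lmm,
    make_lmm_table,
    ses_significance,
)
from .io import read_assemblages, read_call_table, write_ses, write_similarity
from .nullmodel import (
    DEFAULT_MIN_RICHNESS,
    DEFAULT_N_NULL,
    DEFAULT_RADIUS_KM,
    AssemblageRecord,
    filter_dataset,
    required_species,
    run_null_model,
)
from .similarity import MEASURES, CallTable, fit_all_spaces, pairwise_matrices

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one analysis run."""

    calls_path: str | None = None
    assemblages_path: str | None = None
    out_dir: str = "out"
    radius_km: float = DEFAULT_RADIUS_KM
    n_null: int = DEFAULT_N_NULL
    n_boot: int = DEFAULT_N_BOOT
    min_richness: int = DEFAULT_MIN_RICHNESS
    level: float = DEFAULT_LEVEL
    seed: int = 0
    measures: tuple[str, ...] = MEASURES
    fit_lmm: bool = False
    lmm_form: str = "long"

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        for name in ("n_null", "n_boot", "min_richness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.measures = tuple(self.measures)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bitwise: the config snapshot,
    software version, seeds, and per-stage row counts."""

    config: dict
    version: str
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def analyze(
    assemblages: list[AssemblageRecord],
    table: CallTable,
    config: PipelineConfig,
) -> dict:
    """Run the in-memory analysis and return all stage outputs.

    Returns a dict with keys ``retained``, ``pools``, ``exclusions``,
    ``similarity`` (observed values), ``ses`` (tidy SES frame), ``summary``
    (per-measure bootstrap summaries) and optionally ``lmm``.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    retained, pools, exclusions = filter_dataset(
        assemblages, table, config.measures, config.radius_km, config.min_richness
    )
    if not retained:
        raise PipelineError("filter", "no assemblages retained")
    timings["filter"] = time.perf_counter() - t0

    t = time.perf_counter()
    needs_pca = any(m.startswith("PCA_") for m in config.measures)
    spaces = fit_all_spaces(table) if needs_pca else {}
    usable = required_species(table, config.measures)
    matrices = pairwise_matrices(
        table, spaces, species=list(usable), measures=config.measures
    )
    timings["pairwise"] = time.perf_counter() - t

    t = time.perf_counter()
    sim_rows = [
        {
            "assemblage_id": rec.assemblage_id,
            "measure": m,
            "observed_value": matrices.assemblage_mean(rec.species, m),
            "n_species": len(rec.species),
        }
        for rec in retained
        for m in config.measures
    ]
    similarity_df = pd.DataFrame(sim_rows)
    timings["similarity"] = time.perf_counter() - t

    t = time.perf_counter()
    ses_df = run_null_model(
        retained, pools, matrices, config.n_null, config.seed, config.measures
    )
    timings["null_model"] = time.perf_counter() - t

    t = time.perf_counter()
    summary = {}
    import numpy as np

    from .nullmodel import proportion_below_null_mean

    for m in config.measures:
        sub = ses_df[ses_df["measure"] == m]
        ses_vals = sub["ses"].to_numpy(dtype=float)
        finite = ses_vals[np.isfinite(ses_vals)]
        n_degenerate = int(len(ses_vals) - len(finite))
        ci = bca_ci(
            finite,
            n_boot=config.n_boot,
            level=config.level,
            rng=np.random.default_rng([int(config.seed), hash_measure(m)]),
            measure=m,
            seed=config.seed,
        )
        summary[m] = {
            "mean_ses": ci.mean_ses,
            "ci_low": ci.ci_low,
            "ci_high": ci.ci_high,
            "n": ci.n,
            "n_degenerate": n_degenerate,
            "proportion_below_null_mean": proportion_below_null_mean(sub),
            "verdict": ses_significance(ci),
        }
    timings["bootstrap"] = time.perf_counter() - t

    out = {
        "retained": retained,
        "pools": pools,
        "exclusions": exclusions,
        "similarity": similarity_df,
        "ses": ses_df,
        "summary": summary,
        "timings_s": timings,
    }

    if config.fit_lmm:
        t = time.perf_counter()
        out["lmm"] = {
            m: fit_lmm(make_lmm_table(ses_df, retained, m),
                       measure=m, form=config.lmm_form)
            for m in config.measures
        }
        timings["lmm"] = time.perf_counter() - t
    return out


def hash_measure(measure: str) -> int:
    import zlib

    return zlib.crc32(measure.encode("utf-8"))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline from files to files and write the manifest."""
    if not config.calls_path or not config.assemblages_path:
        raise PipelineError("read", "calls_path and assemblages_path are required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        table = read_call_table(config.calls_path)
        assemblages = read_assemblages(config.assemblages_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    results = analyze(assemblages, table, config)

    results["exclusions"].to_csv(out_dir / "exclusions.csv", index=False)
    write_similarity(results["similarity"], out_dir / "similarity.csv")
    write_ses(results["ses"], out_dir / "ses.csv")
    (out_dir / "summary.json").write_text(
        json.dumps(results["summary"], indent=2, sort_keys=True)
    )
    if "lmm" in results:
        lmm_rows = []
        for m, res in results["lmm"].items():
            for term, row in res.params.iterrows():
                lmm_rows.append({"measure": m, "term": term, **row.to_dict(),
                                 "converged": res.converged})
        pd.DataFrame(lmm_rows).to_csv(out_dir / "lmm.csv", index=False)

    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        counts={
            "assemblages_in": len(assemblages),
            "assemblages_retained": len(results["retained"]),
            "excluded": len(results["exclusions"]),
            "species_in_table": len(table),
        },
        timings_s={k: round(v, 3) for k, v in results["timings_s"].items()},
    )
    manifest.write(out_dir / "manifest.json")
    for stage, t in results["timings_s"].items():
        logger.info("stage %s: %.2fs", stage, t)
    return manifest
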