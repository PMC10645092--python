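"""End-to-end orchestration: read → filter → null SES → pool → regress.

Every stage writes its table to the output directory, and each stage's
CSV is a faithful checkpoint: re-running downstream stages from a saved
table reproduces identical results. A single master seed fans out
deterministically to per-watershed null chains and per-model
permutation streams, so results are independent of execution order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

import traitcooc
from traitcooc._seeds import rng_for
from traitcooc.distances import build_design_table, zscore_traits
from traitcooc.io import (
    IncidenceMatrix,
    TraitTable,
    check_coverage,
    filter_watersheds,
    impute_temperature,
    read_incidence,
    read_traits,
)
from traitcooc.nullmodel import PairSESRecord, pool_mean_ses, watershed_pair_ses
from traitcooc.regression import MODELS, RegressionReport, run_hypotheses

logger = logging.getLogger(__name__)

SES_COLUMNS = [
    "watershed_id",
    "species_a",
    "species_b",
    "c_obs",
    "null_mean",
    "null_sd",
    "ses",
    "degenerate",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run."""

    manifest: str
    traits: str
    out_dir: str
    n_null: int = 999
    n_perm: int = 9999
    burn_in: int = 1000
    thin: int = 100
    perm_mode: str = "pair_shuffle"
    master_seed: int = 0
    min_lakes: int = 20
    min_species: int = 20
    standardize_over: str = "analysed"  # or "all": full trait CSV

    def __post_init__(self) -> None:
        if self.n_null < 2:
            raise ValueError("n_null must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.standardize_over not in ("analysed", "all"):
            raise ValueError("standardize_over must be 'analysed' or 'all'")


def compute_pair_ses(
    matrices: list[IncidenceMatrix],
    n_null: int = 999,
    burn_in: int = 1000,
    thin: int = 100,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Per-watershed pair SES table, one independent chain per watershed."""
    records: list[PairSESRecord] = []
    for m in matrices:
        rng = rng_for(master_seed, "watershed", m.watershed_id)
        records.extend(
            watershed_pair_ses(
                m, n_samples=n_null, burn_in=burn_in, thin=thin, rng=rng
            )
        )
    return pd.DataFrame([asdict(r) for r in records], columns=SES_COLUMNS)


def _records_from_frame(df: pd.DataFrame) -> list[PairSESRecord]:
    return [
        PairSESRecord(
            watershed_id=str(r.watershed_id),
            species_a=str(r.species_a),
            species_b=str(r.species_b),
            c_obs=int(r.c_obs),
            null_mean=float(r.null_mean),
            null_sd=float(r.null_sd),
            ses=float(r.ses),
            degenerate=bool(r.degenerate),
        )
        for r in df.itertuples()
    ]


def design_from_pooled(
    pooled: pd.DataFrame, traits: TraitTable, standardize_over: str = "analysed"
) -> pd.DataFrame:
    """Standardize traits and build the regression design table."""
    if standardize_over == "analysed":
        species = sorted(set(pooled["species_a"]) | set(pooled["species_b"]))
        z = zscore_traits(traits, species)
    else:
        z = zscore_traits(traits)
    return build_design_table(pooled, z)


def report_render(reports: list[RegressionReport]) -> str:
    """Fixed-width report: per model, one row per term with estimate,
    SE, t, parametric p and permutation p."""
    if not reports:
        logger.warning("no regression reports to render")
        return "(no models fitted)\n"
    blocks = []
    for rep in reports:
        df = rep.table.copy()
        df.columns = ["estimate slope", "standard error", "t-value",
                      "p-value regression model", "p-value randomization test"]
        blocks.append(
            f"model {rep.model_id}  (n_pairs={rep.n_pairs}, "
            f"n_perm={rep.n_perm}, mode={rep.perm_mode})\n"
            + df.to_string(float_format=lambda v: f"{v:.4g}")
        )
    return "\n\n".join(blocks) + "\n"


def regress_from_design(
    design: pd.DataFrame,
    n_perm: int = 9999,
    perm_mode: str = "pair_shuffle",
    master_seed: int = 0,
) -> list[RegressionReport]:
    return run_hypotheses(
        design, n_perm=n_perm, mode=perm_mode, seed=master_seed
    )


def load_design(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the CSV a bit-exact checkpoint
    return pd.read_csv(
        path,
        index_col=["species_a", "species_b"],
        float_precision="round_trip",
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write all artifacts.

    Returns a mapping from artifact name to path: ``pair_ses``,
    ``pooled``, ``design``, ``reports`` (CSV), ``report_txt`` and
    ``run_manifest``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices = read_incidence(config.manifest)
    matrices = filter_watersheds(
        matrices, min_lakes=config.min_lakes, min_species=config.min_species
    )
    traits = impute_temperature(read_traits(config.traits))
    check_coverage(matrices, traits)

    ses_df = compute_pair_ses(
        matrices,
        n_null=config.n_null,
        burn_in=config.burn_in,
        thin=config.thin,
        master_seed=config.master_seed,
    )
    paths = {"pair_ses": out / "pair_ses.csv"}
    ses_df.to_csv(paths["pair_ses"], index=False)

    pooled = pool_mean_ses(_records_from_frame(ses_df))
    paths["pooled"] = out / "pooled_pairs.csv"
    pooled.to_csv(paths["pooled"], index=False)

    design = design_from_pooled(pooled, traits, config.standardize_over)
    paths["design"] = out / "design_table.csv"
    design.to_csv(paths["design"])
    # regress on the serialized table so the CSV is a bit-exact checkpoint
    design = load_design(paths["design"])

    reports = regress_from_design(
        design,
        n_perm=config.n_perm,
        perm_mode=config.perm_mode,
        master_seed=config.master_seed,
    )
    paths["reports"] = out / "regression_reports.csv"
    pd.concat([r.to_frame() for r in reports]).to_csv(
        paths["reports"], index=False
    )
    paths["report_txt"] = out / "report.txt"
    paths["report_txt"].write_text(report_render(reports))

    paths["run_manifest"] = out / "run_manifest.json"
    manifest = {
        "config": asdict(config),
        "package_version": traitcooc.__version__,
        "n_watersheds": len(matrices),
        "n_pairs_pooled": int(len(pooled)),
        "models": list(MODELS),
        "wall_time_s": round(time.time() - t0, 3),
    }
    paths["run_manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline finished in %.1fs", manifest["wall_time_s"])
    return paths
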