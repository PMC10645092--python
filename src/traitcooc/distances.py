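"""Trait standardization and the per-pair distance design table.

Traits are z-scored over the analysed species so effect sizes are
comparable across traits; the per-trait Euclidean distance between two
species then reduces to the absolute z-score difference. The design
table holds, per pooled species pair, the mean SES response and five
predictors: d_body, d_body², d_temp, d_trophic, d_trophic².
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from traitcooc.io import TRAIT_COLUMNS, TraitTable

#: design-table predictor column per (trait, power)
DESIGN_COLUMNS = ["mean_ses", "d_body", "d_body_sq", "d_temp", "d_trophic", "d_trophic_sq"]

_TRAIT_TO_COL = {
    "body_size": "d_body",
    "temp_pref": "d_temp",
    "trophic_level": "d_trophic",
}


def zscore_traits(
    traits: TraitTable, species: list[str] | None = None
) -> pd.DataFrame:
    """Standardize each trait to mean 0, sample SD 1 (ddof=1).

    *species* restricts (and orders) the table to the analysed species
    set — standardization statistics are computed over exactly that
    set. A zero-variance trait column is a hard error.
    """
    if not traits.complete:
        raise ValueError(
            "trait table has missing temperature preferences; impute first"
        )
    df = traits.data if species is None else traits.subset(list(species)).data
    z = pd.DataFrame(index=df.index.copy())
    for col in TRAIT_COLUMNS:
        x = df[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"trait {col!r} has zero variance; cannot z-score")
        z[col] = (x - x.mean()) / sd
    return z


def pair_trait_distance(z: pd.DataFrame, trait: str, a: str, b: str) -> float:
    """Single-trait Euclidean distance between two species: |z_a − z_b|."""
    if trait not in z.columns:
        raise KeyError(f"unknown trait {trait!r}")
    for sp in (a, b):
        if sp not in z.index:
            raise KeyError(f"species {sp!r} not in standardized trait table")
    return float(abs(z.at[a, trait] - z.at[b, trait]))


def build_design_table(pooled: pd.DataFrame, z: pd.DataFrame) -> pd.DataFrame:
    """Join pooled mean SES with per-trait distances and quadratic terms.

    *pooled* is the output of :func:`traitcooc.nullmodel.pool_mean_ses`.
    Quadratic terms are squares of the z-scale distances, not
    re-standardized. Returns one row per pooled pair, indexed by
    (species_a, species_b).
    """
    needed = sorted(
        (set(pooled["species_a"]) | set(pooled["species_b"])) - set(z.index)
    )
    if needed:
        raise KeyError(f"pairs reference species missing from traits: {needed}")
    za = z.loc[pooled["species_a"]].to_numpy()
    zb = z.loc[pooled["species_b"]].to_numpy()
    dist = np.abs(za - zb)  # columns follow TRAIT_COLUMNS order
    out = pd.DataFrame(
        {
            "mean_ses": pooled["mean_ses"].to_numpy(),
            "d_body": dist[:, 0],
            "d_temp": dist[:, 1],
            "d_trophic": dist[:, 2],
        },
        index=pd.MultiIndex.from_frame(
            pooled[["species_a", "species_b"]]
        ),
    )
    out["d_body_sq"] = out["d_body"] ** 2
    out["d_trophic_sq"] = out["d_trophic"] ** 2
    return out[DESIGN_COLUMNS]
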