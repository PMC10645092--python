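"""Synthetic metacommunities with known trait-driven assembly effects.

The generator emulates a multi-watershed lake survey: each watershed is
a set of lakes with their own thermal environments, and species
occupancy is shaped by up to three tunable mechanisms mirroring the
hypothesized trait–co-occurrence relationships:

* **environmental filtering** (``beta_env``): a species' occupancy
  probability drops logistically with the squared mismatch between its
  temperature preference and the lake temperature — so small pairwise
  temperature distances breed aggregation, large ones segregation;
* **predation** (``beta_pred``): a species co-occurring with another
  whose trophic level exceeds its own by more than ``pred_gap`` is
  culled with probability ``1 − exp(−beta_pred·excess)``, where
  ``excess`` is the largest trophic-level overshoot beyond the gap
  among co-occurring species — predation pressure grows with trophic
  separation, so segregation *accelerates* at large trophic distances
  (the convex, quadratic-term signature);
* **competition** (``beta_comp``): in pairs closer than ``comp_width``
  body-size z-score units, one random member is culled with
  probability ``1 − exp(−beta_comp)`` — segregating similar-sized pairs.

With all strengths at zero, occupancy is i.i.d. Bernoulli and every
co-occurrence pattern is random by construction. Culls are applied once
(environment → predation → competition), not iterated to equilibrium,
which keeps the planted effect directions analyzable. The generator
never calls the pipeline's own statistics, so recovery tests are not
circular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from traitcooc._seeds import rng_for
from traitcooc.io import IncidenceMatrix, TraitTable

logger = logging.getLogger(__name__)

#: cull strengths used by recovery scenarios as "strong" planted effects
#: (chosen by pilot power analysis so the planted signal dominates
#: sampling noise at the scenario scale): STRONG_ENV gives a species
#: four logistic units of occupancy penalty per (temp_scale)² of thermal
#: mismatch; STRONG_PRED culls a prey species half a trophic level below
#: the gap with probability 1 − e^−3 ≈ 0.95 per lake shared with the
#: predator.
STRONG_ENV = 4.0
STRONG_PRED = 6.0
STRONG_COMP = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Metacommunity generator settings.

    Defaults mirror a large boreal lake-fish survey: 70 species across
    many watersheds of at least 20 lakes each, with temperature
    preferences spread over roughly 10–28 °C and trophic levels between
    2 and 4.5. ``temp_scale`` (°C) sets the thermal mismatch unit for
    environmental filtering; ``missing_temp_frac`` leaves that share of
    species without a temperature preference to exercise imputation.
    """

    n_species: int = 70
    n_watersheds: int = 86
    lakes_per_watershed: int = 25
    base_occupancy: float = 0.3
    beta_env: float = 0.0
    beta_pred: float = 0.0
    pred_gap: float = 1.5
    beta_comp: float = 0.0
    comp_width: float = 0.5
    temp_mean: float = 18.0
    temp_sd: float = 4.0
    temp_scale: float = 4.0
    missing_temp_frac: float = 0.0
    genus_size: int = 3
    seed: int = 0
    max_retries: int = 50
    min_lakes: int = 20
    min_species: int = 20

    def __post_init__(self) -> None:
        if self.n_species < max(2, self.min_species):
            raise ValueError("n_species too small for the watershed filter")
        if self.lakes_per_watershed < self.min_lakes:
            raise ValueError("lakes_per_watershed must be >= min_lakes")
        if not 0.0 < self.base_occupancy < 1.0:
            raise ValueError("base_occupancy must be in (0, 1)")
        for name in ("beta_env", "beta_pred", "beta_comp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_temp_frac < 1.0:
            raise ValueError("missing_temp_frac must be in [0, 1)")


def generate_traits(
    config: SimConfig, rng: np.random.Generator | None = None
) -> TraitTable:
    """Draw a species trait table.

    Body size (total length, cm) is log-normal — many small-bodied
    species, few large ones; temperature preference is normal around
    ``temp_mean``; trophic level is stratified-uniform on [2, 4.5] so
    each pool spans herbivores through top predators. Genus labels
    are assigned in blocks of ``genus_size`` so every species has
    congeners, and a ``missing_temp_frac`` share of species (never a
    whole genus) loses its temperature value.
    """
    if rng is None:
        rng = rng_for(config.seed, "traits")
    n = config.n_species
    species = [f"sp{i:03d}" for i in range(n)]
    genus = [f"genus{i // config.genus_size:03d}" for i in range(n)]
    body = np.exp(rng.normal(np.log(30.0), 0.7, n))
    temp = rng.normal(config.temp_mean, config.temp_sd, n)
    # stratified uniform on [2, 4.5]: one draw per equal-width bin, then
    # shuffled — marginally uniform, but every species pool spans the
    # full trophic range (a pool with no top predators is not a
    # realistic fish community)
    edges = np.linspace(2.0, 4.5, n + 1)
    trophic = rng.permutation(edges[:-1] + rng.random(n) * np.diff(edges))
    df = pd.DataFrame(
        {
            "genus": genus,
            "body_size": body,
            "temp_pref": temp,
            "trophic_level": trophic,
        },
        index=pd.Index(species, name="species_id"),
    )
    n_missing = int(round(config.missing_temp_frac * n))
    if n_missing:
        # at most one knockout per genus, so a congeneric mean always exists
        candidates = rng.permutation(n)
        hit_genus: set[str] = set()
        for i in candidates:
            if len(hit_genus) == n_missing:
                break
            g = genus[i]
            if g not in hit_genus and sum(x == g for x in genus) > 1:
                df.iloc[i, df.columns.get_loc("temp_pref")] = np.nan
                hit_genus.add(g)
    return TraitTable(df)


def _assemble_watershed(
    wid: str,
    traits_df: pd.DataFrame,
    body_z: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One presence/absence draw (species × lakes), before row filtering."""
    n_sp = len(traits_df)
    n_lakes = config.lakes_per_watershed
    lake_temp = rng.normal(config.temp_mean, config.temp_sd, n_lakes)
    temp_pref = traits_df["temp_pref"].to_numpy(float)
    mismatch = (temp_pref[:, None] - lake_temp[None, :]) / config.temp_scale
    logit_p = logit(config.base_occupancy) - config.beta_env * mismatch**2
    present = rng.random((n_sp, n_lakes)) < expit(logit_p)

    if config.beta_pred > 0:
        trophic = traits_df["trophic_level"].to_numpy(float)
        # hazard grows with the worst trophic overshoot beyond the gap
        # among co-occurring species in that lake
        top = np.where(present, trophic[:, None], -np.inf).max(axis=0)
        excess = np.clip(top[None, :] - config.pred_gap - trophic[:, None], 0.0, None)
        p_cull = 1.0 - np.exp(-config.beta_pred * excess)
        present = present & ~(rng.random(present.shape) < p_cull)

    if config.beta_comp > 0:
        p_cull = 1.0 - np.exp(-config.beta_comp)
        ii, jj = np.triu_indices(n_sp, k=1)
        close = np.abs(body_z[ii] - body_z[jj]) < config.comp_width
        pairs = list(zip(ii[close], jj[close]))
        drop = np.zeros_like(present)
        for lake in range(config.lakes_per_watershed):
            col = present[:, lake]
            for i, j in pairs:
                if col[i] and col[j] and rng.random() < p_cull:
                    drop[j if rng.integers(2) else i, lake] = True
        present = present & ~drop

    return present.astype(np.int8)


def generate_metacommunity(
    traits: TraitTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[IncidenceMatrix]:
    """Generate one incidence matrix per watershed.

    Watersheds whose draw leaves fewer than ``min_species`` occurring
    species are redrawn (up to ``max_retries``) so every output passes
    the downstream watershed filter. Requires a complete trait table.
    """
    if not traits.complete:
        raise ValueError("traits must be complete (impute temp_pref first)")
    df = traits.data
    body = df["body_size"].to_numpy(float)
    body_z = (body - body.mean()) / body.std(ddof=1)
    matrices = []
    for w in range(config.n_watersheds):
        wid = f"ws{w:03d}"
        w_rng = rng if rng is not None else rng_for(config.seed, "watershed", wid)
        for attempt in range(config.max_retries):
            cells = _assemble_watershed(wid, df, body_z, config, w_rng)
            keep = cells.sum(axis=1) > 0
            if keep.sum() >= config.min_species:
                matrices.append(
                    IncidenceMatrix(
                        wid,
                        tuple(np.array(df.index)[keep]),
                        tuple(f"{wid}_lake{k:03d}" for k in range(config.lakes_per_watershed)),
                        cells[keep],
                    )
                )
                break
            logger.warning(
                "%s: draw %d left %d species (< %d), redrawing",
                wid,
                attempt,
                int(keep.sum()),
                config.min_species,
            )
        else:
            raise RuntimeError(
                f"{wid}: could not assemble >= {config.min_species} species in "
                f"{config.max_retries} draws; weaken the cull strengths"
            )
    return matrices


def ground_truth(config: SimConfig) -> dict[str, str]:
    """Expected sign of each regression term given the planted effects.

    ``"+"`` — slope expected positive; ``"0"`` — no planted effect,
    slope expected null; ``"nonzero"`` — effect planted but direction
    depends on the linear/quadratic split.
    """
    truth = {c: "0" for c in ("d_body", "d_body_sq", "d_temp", "d_trophic", "d_trophic_sq")}
    if config.beta_env > 0:
        truth["d_temp"] = "+"
    if config.beta_pred > 0:
        # predation segregates large trophic gaps: curvature upward
        truth["d_trophic_sq"] = "+"
    if config.beta_comp > 0:
        truth["d_body"] = "nonzero"
        truth["d_body_sq"] = "nonzero"
    return {"config": asdict(config), **truth}  # type: ignore[dict-item]
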