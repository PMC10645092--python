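"""Pairwise C-scores and SES under a fixed-fixed curveball null model.

For a species pair with occupancies r_a, r_b and s shared sites, the
C-score is ``(r_a - s)(r_b - s)`` checkerboard units: 0 when one range
nests in the other, maximal when ranges are disjoint. Each observed
C-score is standardized against a null ensemble that preserves every
row total (species occupancy) and column total (site richness),
sampled with the curveball trading algorithm — a Markov chain whose
stationary distribution is uniform over the fixed-marginal matrix set:

    SES = (C_obs - C_exp) / SD_exp

Positive SES means the pair is segregated (co-occurs less than the
null expects), negative means aggregated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from traitcooc.io import IncidenceMatrix

logger = logging.getLogger(__name__)

#: Null-ensemble spreads at or below this are treated as exactly zero
#: (the pair's C-score is invariant under the null — SES undefined).
_SD_EPS = 1e-12


@dataclass(frozen=True)
class PairSESRecord:
    """SES of one species pair in one watershed.

    ``species_a < species_b`` lexicographically. ``ses`` is NaN and
    ``degenerate`` True when the null SD is zero.
    """

    watershed_id: str
    species_a: str
    species_b: str
    c_obs: int
    null_mean: float
    null_sd: float
    ses: float
    degenerate: bool


def pair_c_score(matrix: IncidenceMatrix, a: str, b: str) -> int:
    """Observed C-score ``(r_a - s)(r_b - s)`` for one species pair."""
    if a == b:
        raise ValueError("C-score requires two distinct species")
    ia, ib = matrix.species_index(a), matrix.species_index(b)
    ra = int(matrix.cells[ia].sum())
    rb = int(matrix.cells[ib].sum())
    s = int((matrix.cells[ia] & matrix.cells[ib]).sum())
    return (ra - s) * (rb - s)


def _c_score_matrix(cells: np.ndarray) -> np.ndarray:
    """All-pairs C-score matrix for a binary species × sites array."""
    m = cells.astype(np.int64)
    shared = m @ m.T
    r = m.sum(axis=1)
    return (r[:, None] - shared) * (r[None, :] - shared)


# ---------------------------------------------------------------------------
# curveball chain


def _rows_as_sets(cells: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(row).tolist()) for row in cells]


def _sets_to_cells(rows: list[set[int]], n_cols: int) -> np.ndarray:
    cells = np.zeros((len(rows), n_cols), dtype=np.int8)
    for i, s in enumerate(rows):
        cells[i, list(s)] = 1
    return cells


def _trade(rows: list[set[int]], rng: np.random.Generator) -> None:
    """One in-place curveball trade between two random rows.

    The columns exclusive to either row are pooled and re-partitioned
    uniformly at random, keeping each row's number of exclusive columns
    (hence all marginals) fixed. If either row has no exclusive column
    the trade is a no-op (the chain stays put, which is required for
    uniformity of the stationary distribution).
    """
    n = len(rows)
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    si, sj = rows[i], rows[j]
    a_only = si - sj
    b_only = sj - si
    na, nb = len(a_only), len(b_only)
    if na == 0 or nb == 0:
        return
    pool = sorted(a_only | b_only)
    rng.shuffle(pool)
    shared = si & sj
    rows[i] = shared | set(pool[:na])
    rows[j] = shared | set(pool[na:])


def curveball_trade(
    matrix: IncidenceMatrix, rng: np.random.Generator
) -> IncidenceMatrix:
    """Apply a single curveball trade; returns a new matrix.

    Row and column totals are preserved exactly.
    """
    if matrix.n_species < 2:
        raise ValueError("curveball trade requires at least 2 species rows")
    rows = _rows_as_sets(np.asarray(matrix.cells))
    _trade(rows, rng)
    return matrix.with_cells(_sets_to_cells(rows, matrix.n_lakes))


def _chain(
    cells: np.ndarray,
    n_samples: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
) -> Iterator[np.ndarray]:
    """Yield ``n_samples`` fixed-marginal arrays from a curveball chain."""
    rows = _rows_as_sets(cells)
    n_cols = cells.shape[1]
    for _ in range(burn_in):
        _trade(rows, rng)
    for _ in range(n_samples):
        for _ in range(thin):
            _trade(rows, rng)
        yield _sets_to_cells(rows, n_cols)


def sample_null(
    matrix: IncidenceMatrix,
    n_samples: int = 999,
    burn_in: int = 1000,
    thin: int = 100,
    rng: np.random.Generator | None = None,
) -> Iterator[IncidenceMatrix]:
    """Stream *n_samples* null matrices with the observed marginals.

    A single Markov chain of curveball trades: *burn_in* trades first,
    then one sample every *thin* trades. The observed matrix itself is
    never emitted as a sample.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (null SD undefined otherwise)")
    if matrix.n_species < 2:
        raise ValueError("null model requires at least 2 species rows")
    if rng is None:
        rng = np.random.default_rng()
    for cells in _chain(np.asarray(matrix.cells), n_samples, burn_in, thin, rng):
        yield matrix.with_cells(cells)


# ---------------------------------------------------------------------------
# SES per watershed and pooling


def watershed_pair_ses(
    matrix: IncidenceMatrix,
    n_samples: int = 999,
    burn_in: int = 1000,
    thin: int = 100,
    rng: np.random.Generator | None = None,
) -> list[PairSESRecord]:
    """SES for every unordered species pair in one watershed.

    Null mean and SD (sample SD, n−1 denominator) come from the pair
    C-scores of *n_samples* curveball-null matrices. Pairs whose null
    distribution has zero spread are marked degenerate (SES = NaN).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (null SD undefined otherwise)")
    if matrix.n_species < 2:
        raise ValueError("null model requires at least 2 species rows")
    if rng is None:
        rng = np.random.default_rng()
    cells = np.asarray(matrix.cells)
    c_obs = _c_score_matrix(cells)
    acc = np.zeros(c_obs.shape, dtype=np.float64)
    acc_sq = np.zeros_like(acc)
    for sample in _chain(cells, n_samples, burn_in, thin, rng):
        c = _c_score_matrix(sample)
        acc += c
        acc_sq += c * c
    mean = acc / n_samples
    var = (acc_sq - n_samples * mean * mean) / (n_samples - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))

    records = []
    n_degenerate = 0
    for i in range(matrix.n_species):
        for j in range(i + 1, matrix.n_species):
            a, b = sorted((matrix.species_ids[i], matrix.species_ids[j]))
            sd_ij = float(sd[i, j])
            degenerate = sd_ij <= _SD_EPS
            if degenerate:
                n_degenerate += 1
                ses = math.nan
                sd_ij = 0.0
            else:
                ses = (int(c_obs[i, j]) - float(mean[i, j])) / sd_ij
            records.append(
                PairSESRecord(
                    watershed_id=matrix.watershed_id,
                    species_a=a,
                    species_b=b,
                    c_obs=int(c_obs[i, j]),
                    null_mean=float(mean[i, j]),
                    null_sd=sd_ij,
                    ses=ses,
                    degenerate=degenerate,
                )
            )
    logger.info(
        "watershed %s: %d pairs, %d degenerate",
        matrix.watershed_id,
        len(records),
        n_degenerate,
    )
    return records


def pool_mean_ses(records: list[PairSESRecord]) -> "pd.DataFrame":
    """Mean SES per species pair across watersheds.

    Degenerate records contribute to neither the mean nor the watershed
    count; pairs with only degenerate records are dropped with a
    warning. Returns a DataFrame with columns species_a, species_b,
    mean_ses, n_watersheds, sorted by pair.
    """
    import pandas as pd

    if not records:
        raise ValueError("no SES records to pool")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    dropped: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.species_a, rec.species_b)
        if rec.degenerate:
            dropped.add(key)
            continue
        sums[key] = sums.get(key, 0.0) + rec.ses
        counts[key] = counts.get(key, 0) + 1
    only_degenerate = dropped - set(sums)
    if only_degenerate:
        logger.warning(
            "dropping %d pair(s) with only degenerate SES records: %s",
            len(only_degenerate),
            sorted(only_degenerate),
        )
    rows = [
        {
            "species_a": a,
            "species_b": b,
            "mean_ses": sums[(a, b)] / counts[(a, b)],
            "n_watersheds": counts[(a, b)],
        }
        for (a, b) in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "mean_ses", "n_watersheds"])
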