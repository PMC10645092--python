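"""OLS hypothesis models with Mantel-style permutation inference.

Four models relate pooled mean SES to trait distances:

* ``H1_full``    — all five predictors (three linear distances plus the
  body-size and trophic-level quadratic terms);
* ``H2_body``    — d_body + d_body²;
* ``H3_temp``    — d_temp;
* ``H4_trophic`` — d_trophic + d_trophic².

Each slope gets a parametric t-test p-value and a permutation p-value
obtained by shuffling the SES response over pairs while holding the
trait-distance design fixed, refitting, and comparing |slope|. Because
pairwise distances are not independent observations, the permutation
p is the headline inference; the parametric p is reported for
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from traitcooc._seeds import rng_for

#: model id -> predictor columns (intercept always added)
MODELS: dict[str, list[str]] = {
    "H1_full": ["d_body", "d_body_sq", "d_temp", "d_trophic", "d_trophic_sq"],
    "H2_body": ["d_body", "d_body_sq"],
    "H3_temp": ["d_temp"],
    "H4_trophic": ["d_trophic", "d_trophic_sq"],
}

PERM_MODES = ("pair_shuffle", "species_identity")


@dataclass(frozen=True)
class RegressionReport:
    """Per-term inference for one hypothesis model.

    ``table`` rows are the model's predictors (intercept excluded),
    with columns estimate, se, t, p_param, p_perm.
    """

    model_id: str
    table: pd.DataFrame
    n_pairs: int
    n_perm: int
    perm_mode: str

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "model", self.model_id)
        df.insert(1, "term", df.index)
        return df.reset_index(drop=True)


def _design_matrix(design: pd.DataFrame, terms: list[str]) -> np.ndarray:
    missing = [t for t in terms if t not in design.columns]
    if missing:
        raise KeyError(f"unknown design columns: {missing}")
    X = np.column_stack(
        [np.ones(len(design))] + [design[t].to_numpy(float) for t in terms]
    )
    if len(design) <= X.shape[1]:
        raise ValueError(
            f"need more pairs ({len(design)}) than parameters ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); most "
            f"collinear terms: {terms[i]!r}, {terms[j]!r}"
        )
    return X


def ols_fit(design: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """OLS of mean SES on *terms* (intercept included).

    Returns a per-term frame (intercept row first) with estimate, se,
    t and the two-sided parametric p-value.
    """
    X = _design_matrix(design, terms)
    y = design["mean_ses"].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_param": fit.pvalues,
        },
        index=pd.Index(["intercept"] + list(terms), name="term"),
    )


def _pair_species(design: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Species list and (n_pairs, 2) integer pair index from the design index."""
    if design.index.nlevels != 2:
        raise ValueError(
            "species_identity mode needs a (species_a, species_b) pair index"
        )
    a = design.index.get_level_values(0)
    b = design.index.get_level_values(1)
    species = sorted(set(a) | set(b))
    lookup = {s: k for k, s in enumerate(species)}
    idx = np.array([[lookup[x] for x in a], [lookup[x] for x in b]]).T
    return species, idx


def permutation_test(
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    mode: str = "pair_shuffle",
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Two-sided permutation p-value per term.

    ``pair_shuffle`` permutes the mean-SES vector freely over pairs.
    ``species_identity`` permutes species labels and re-reads each
    pair's response from the relabelled pair, preserving the pair-level
    dependence structure (the Mantel-test analogue); it requires the
    design to contain every pair of its species set. Both modes use the
    add-one estimator ``p = (1 + #{|b*| >= |b_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in PERM_MODES:
        raise ValueError(f"mode must be one of {PERM_MODES}, got {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    X = _design_matrix(design, terms)
    y = design["mean_ses"].to_numpy(float)
    proj = np.linalg.solve(X.T @ X, X.T)  # (k+1, n): b = proj @ y
    b_obs = proj @ y

    if mode == "pair_shuffle":
        perms = np.empty((n_perm, len(y)), dtype=np.intp)
        base = np.arange(len(y))
        for r in range(n_perm):
            perms[r] = rng.permutation(base)
    else:
        species, pair_idx = _pair_species(design)
        n_sp = len(species)
        if len(design) != n_sp * (n_sp - 1) // 2:
            raise ValueError(
                "species_identity mode requires a complete pair table "
                f"({n_sp} species -> {n_sp * (n_sp - 1) // 2} pairs, "
                f"got {len(design)})"
            )
        pos = np.full((n_sp, n_sp), -1, dtype=np.intp)
        for k, (i, j) in enumerate(pair_idx):
            pos[i, j] = pos[j, i] = k
        perms = np.empty((n_perm, len(y)), dtype=np.intp)
        for r in range(n_perm):
            pi = rng.permutation(n_sp)
            perms[r] = pos[pi[pair_idx[:, 0]], pi[pair_idx[:, 1]]]

    # all permuted slope vectors at once: (k+1, n_perm); ties between
    # |b*| and |b_obs| count as exceedances (tolerance absorbs rounding)
    tol = 1e-9 * (np.abs(b_obs) + 1.0)
    b_perm = proj @ y[perms].T
    exceed = (np.abs(b_perm) >= (np.abs(b_obs) - tol)[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.Series(p, index=pd.Index(["intercept"] + list(terms), name="term"))


def run_hypotheses(
    design: pd.DataFrame,
    n_perm: int = 9999,
    mode: str = "pair_shuffle",
    seed: int | None = None,
    models: dict[str, list[str]] | None = None,
) -> list[RegressionReport]:
    """Fit all hypothesis models with parametric and permutation inference."""
    if models is None:
        models = MODELS
    reports = []
    for model_id, terms in models.items():
        fit = ols_fit(design, terms)
        rng = (
            np.random.default_rng()
            if seed is None
            else rng_for(seed, "perm", model_id)
        )
        p_perm = permutation_test(design, terms, n_perm=n_perm, mode=mode, rng=rng)
        table = fit.loc[terms].copy()
        table["p_perm"] = p_perm.loc[terms]
        reports.append(
            RegressionReport(
                model_id=model_id,
                table=table,
                n_pairs=len(design),
                n_perm=n_perm,
                perm_mode=mode,
            )
        )
    return reports
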