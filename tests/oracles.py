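"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and
per-element counting — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def brute_c_score(cells: np.ndarray, i: int, j: int) -> int:
    """C-score of rows i, j by explicit per-lake counting."""
    ri = rj = s = 0
    for k in range(cells.shape[1]):
        ri += cells[i, k]
        rj += cells[j, k]
        if cells[i, k] and cells[j, k]:
            s += 1
    return (ri - s) * (rj - s)


def enumerate_fixed_marginal(cells: np.ndarray) -> list[np.ndarray]:
    """All binary matrices sharing the row and column sums of *cells*.

    Depth-first over rows: each row places its ones into columns with
    remaining capacity; column capacities shrink as rows are placed.
    Feasible only for tiny matrices.
    """
    cells = np.asarray(cells)
    n_rows, n_cols = cells.shape
    row_sums = cells.sum(axis=1)
    col_caps = cells.sum(axis=0).astype(int)
    out: list[np.ndarray] = []
    mat = np.zeros((n_rows, n_cols), dtype=np.int8)

    def place(r: int, caps: tuple[int, ...]) -> None:
        if r == n_rows:
            if all(c == 0 for c in caps):
                out.append(mat.copy())
            return
        # prune: remaining ones to place must cover remaining capacity
        if sum(row_sums[r:]) != sum(caps):
            return
        open_cols = [c for c in range(n_cols) if caps[c] > 0]
        for chosen in combinations(open_cols, int(row_sums[r])):
            mat[r, :] = 0
            new_caps = list(caps)
            for c in chosen:
                mat[r, c] = 1
                new_caps[c] -= 1
            place(r + 1, tuple(new_caps))
        mat[r, :] = 0

    place(0, tuple(col_caps))
    return out


def exact_null_moments(
    cells: np.ndarray, i: int, j: int
) -> tuple[float, float, float]:
    """(mean, sd, fourth central moment) of the pair C-score over the
    exhaustive fixed-marginal ensemble (sd uses the population formula
    over the complete enumeration)."""
    states = enumerate_fixed_marginal(cells)
    vals = np.array([brute_c_score(m, i, j) for m in states], dtype=float)
    mean = vals.mean()
    sd = vals.std()
    mu4 = ((vals - mean) ** 4).mean()
    return float(mean), float(sd), float(mu4)


def exhaustive_permutation_p(
    X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Two-sided permutation p per coefficient over all n! shuffles of y.

    X includes the intercept column. p = #{|b*| >= |b_obs|} / n!
    (the identity permutation is part of the enumeration, so this
    matches the add-one sampled estimator's target).
    """
    proj = np.linalg.solve(X.T @ X, X.T)
    b_obs = proj @ y
    n = len(y)
    count = np.zeros(X.shape[1])
    total = 0
    for perm in permutations(range(n)):
        b = proj @ y[list(perm)]
        count += np.abs(b) >= np.abs(b_obs) - 1e-12
        total += 1
    return count / total


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients by explicitly inverting X'X (naive oracle)."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)
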