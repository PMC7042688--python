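"""Distance-based permutation statistics on diet-proportion matrices.

Implements a chi-square distance for compositional rows, a sequential
(Type I) sums-of-squares permutational MANOVA on an arbitrary distance
matrix, Holm step-down multiple-comparison adjustment, per-prey and
pairwise-class wrappers, Spearman trend tests on annual means, and
ice-covariate models.

Conventions
-----------
* Permutation p-values use the add-one convention
  ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` so p is never 0.
* Observation labels are permuted freely (no restricted blocks).
* ``exact=True`` enumerates all n! label permutations (identity included)
  and reports ``p = #{F_perm >= F_obs} / n!``.
* Numeric factor columns are treated as continuous covariates (1 df);
  everything else as categorical.  Pass years as strings/categoricals to
  treat them as factor levels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import IceIndexTable, SignatureValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "TrendResult",
    "chi_square_distance",
    "permanova",
    "holm_adjust",
    "per_prey_permanova",
    "pairwise_class_tests",
    "annual_mean_trend",
    "ice_covariate_permanova",
]

ALPHA = 0.05  # family-wise significance threshold used by the wrappers


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal."""

    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got {d.shape}")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        d = d.copy()
        np.fill_diagonal(d, 0.0)
        d.flags.writeable = False
        object.__setattr__(self, "values", d)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class PermanovaResult:
    """ANOVA-style table for a distance-based permutation MANOVA."""

    table: pd.DataFrame = field(repr=False)
    n_perm: int
    seed: int | None
    n_obs: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p_perm"])

    def F(self, name: str) -> float:
        return float(self.table.loc[name, "pseudo_F"])


@dataclass(frozen=True)
class TrendResult:
    """Spearman rank correlation of annual means against year."""

    r_s: float
    p: float
    n: int

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.r_s <= 1.0 + 1e-12):
            raise ValueError(f"r_s out of range: {self.r_s}")


def chi_square_distance(P) -> DistanceMatrix:
    """Chi-square distance between rows of a nonnegative proportion matrix.

    ``d(i,j) = sqrt( sum_c ( (p_ic/p_i+ - p_jc/p_j+)^2 / (p_+c/p_++) ) )``
    with row totals ``p_i+``, column totals ``p_+c`` and grand total
    ``p_++`` — the profile-standardized Euclidean distance of
    correspondence analysis.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("expected a 2-D matrix of proportions")
    if np.any(P < 0):
        raise ValueError("proportions must be nonnegative")
    row_tot = P.sum(axis=1)
    if np.any(row_tot <= 0):
        bad = np.flatnonzero(row_tot <= 0).tolist()
        raise ValueError(f"all-zero rows at positions {bad}")
    col_tot = P.sum(axis=0)
    if np.any(col_tot <= 0):
        bad = np.flatnonzero(col_tot <= 0).tolist()
        raise ValueError(f"all-zero columns at positions {bad}")
    profiles = P / row_tot[:, None]
    col_mass = col_tot / P.sum()
    diff = profiles[:, None, :] - profiles[None, :, :]
    d2 = np.einsum("ijc,c->ij", diff**2, 1.0 / col_mass)
    d2 = np.clip(d2, 0.0, None)
    return DistanceMatrix(np.sqrt(d2))


# ---------------------------------------------------------------------------
# perMANOVA engine
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    )


def _term_block(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term (``a:b`` denotes an interaction)."""
    parts = term.split(":")
    block = np.ones((len(factors), 1))
    for part in parts:
        if part not in factors.columns:
            raise SignatureValidationError(f"unknown factor {part!r}")
        col = factors[part]
        if _is_numeric(col):
            sub = col.to_numpy(dtype=float)[:, None]
        else:
            levels = pd.unique(col.astype(str))
            if len(levels) < 2 and len(parts) == 1:
                raise SignatureValidationError(
                    f"factor {part!r} has a single level"
                )
            sub = pd.get_dummies(col.astype(str)).to_numpy(dtype=float)
        # column-wise cross products (Khatri-Rao) build the interaction
        block = (block[:, :, None] * sub[:, None, :]).reshape(len(factors), -1)
    return block


def _projector(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of X, and its rank."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    ur = u[:, :r]
    return ur @ ur.T, r


def permanova(
    D: DistanceMatrix | np.ndarray,
    factors: pd.DataFrame,
    terms: Sequence[str],
    *,
    n_perm: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Sequential-SS permutational MANOVA on a distance matrix.

    Terms are fit in the given order (Type I sums of squares); ``"a:b"``
    requests the interaction of two factors.  The pseudo-F for each term
    is ``(SS_term/df_term) / (SS_resid/df_resid)``; p-values come from
    free permutation of observation labels.

    Continuous covariates with zero variance yield an SS of 0 with a
    warning; rank-deficient (confounded) categorical terms are an error.
    """
    if not isinstance(D, DistanceMatrix):
        D = DistanceMatrix(np.asarray(D))
    n = len(D)
    if len(factors) != n:
        raise SignatureValidationError(
            f"factor table has {len(factors)} rows for {n} observations"
        )
    if not terms:
        raise SignatureValidationError("no model terms supplied")
    G = _gower_center(D.values)

    # sequential projector differences
    X = np.ones((n, 1))
    P_prev, r_prev = _projector(X)
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        X = np.hstack([X, _term_block(factors, term)])
        P_cur, r_cur = _projector(X)
        df = r_cur - r_prev
        if df == 0:
            parts = term.split(":")
            numeric = any(_is_numeric(factors[p]) for p in parts if p in factors.columns)
            if numeric:
                warnings.warn(
                    f"covariate term {term!r} adds no rank (constant); SS set to 0",
                    stacklevel=2,
                )
            else:
                raise SignatureValidationError(
                    f"term {term!r} is confounded with earlier terms"
                )
        hats.append(P_cur - P_prev)
        dfs.append(df)
        P_prev, r_prev = P_cur, r_cur
    P_full = P_prev
    df_res = n - r_prev
    if df_res <= 0:
        raise SignatureValidationError("model saturates the data (residual df <= 0)")
    R = np.eye(n) - P_full

    def stats_for(Gp: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        ss = np.array([float(np.sum(H * Gp)) for H in hats])
        ss_res = float(np.sum(R * Gp))
        with np.errstate(divide="ignore", invalid="ignore"):
            ms = np.where(np.array(dfs) > 0, ss / np.maximum(dfs, 1), 0.0)
            ms_res = ss_res / df_res
            F = np.where(ms_res > 0, ms / ms_res, 0.0)
        F = np.where(np.array(ss) <= 1e-12, 0.0, F)
        return ss, ss_res, F

    ss_obs, ss_res_obs, F_obs = stats_for(G)

    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        if perms.shape[0] > 500_000:
            raise SignatureValidationError(
                "exact enumeration infeasible for this many observations"
            )
        counts = np.zeros(len(terms))
        for p in perms:
            Gp = G[np.ix_(p, p)]
            _, _, Fp = stats_for(Gp)
            counts += Fp >= F_obs - 1e-12
        p_perm = counts / perms.shape[0]
        n_used = perms.shape[0] - 1
    else:
        if n_perm < 99:
            raise SignatureValidationError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        counts = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            Gp = G[np.ix_(p, p)]
            _, _, Fp = stats_for(Gp)
            counts += Fp >= F_obs - 1e-12
        p_perm = (1.0 + counts) / (1.0 + n_perm)
        n_used = n_perm

    rows = []
    for i, term in enumerate(terms):
        rows.append([term, dfs[i], ss_obs[i], F_obs[i], p_perm[i]])
    rows.append(["Residual", df_res, ss_res_obs, np.nan, np.nan])
    rows.append(["Total", n - 1, float(np.trace(G)), np.nan, np.nan])
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "pseudo_F", "p_perm"]
    ).set_index("term")
    return PermanovaResult(table=table, n_perm=n_used, seed=seed, n_obs=n)


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values.

    Sort ascending; ``adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j))``; restore
    the original order.  Adjusted values are never below raw values and the
    smallest equals its Bonferroni correction.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def per_prey_permanova(
    diet_table: pd.DataFrame,
    factors: pd.DataFrame,
    terms: Sequence[str],
    prey: Sequence[str],
    *,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One-prey-at-a-time perMANOVAs with Holm adjustment across prey.

    For each prey ``k`` the response is the two-column composition
    ``(p_k, 1 - p_k)`` under the chi-square distance, modelled with the
    supplied terms (normally the significant terms of the overall model).
    Returns a long table (prey x term) with raw and Holm-adjusted p.
    """
    records = []
    for k, sp in enumerate(prey):
        pk = diet_table[sp].to_numpy(dtype=float)
        comp = np.column_stack([pk, 1.0 - pk])
        if np.allclose(comp.std(axis=0), 0.0):
            # constant proportion: distance identically zero
            for term in terms:
                records.append([sp, term, np.nan, 0.0, 0.0, 1.0])
            continue
        D = chi_square_distance(comp)
        res = permanova(D, factors, terms, n_perm=n_perm,
                        seed=None if seed is None else seed + k)
        for term in terms:
            row = res.term(term)
            records.append([sp, term, row["df"], row["SS"], row["pseudo_F"], row["p_perm"]])
    out = pd.DataFrame(records, columns=["prey", "term", "df", "SS", "pseudo_F", "p_raw"])
    out["p_holm"] = np.nan
    for term in set(out["term"]):
        mask = out["term"] == term
        out.loc[mask, "p_holm"] = holm_adjust(out.loc[mask, "p_raw"].to_numpy())
    return out


def pairwise_class_tests(
    diet_table: pd.DataFrame,
    prey: str,
    *,
    class_column: str = "class",
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pairwise perMANOVAs of one prey's ``(p_k, 1-p_k)`` between classes.

    Classes with fewer than 2 members are excluded with a warning; p-values
    are Holm-adjusted over the tested pairs.
    """
    classes = diet_table[class_column].astype(str)
    counts = classes.value_counts()
    keep = sorted(counts[counts >= 2].index)
    dropped = sorted(counts[counts < 2].index)
    if dropped:
        warnings.warn(f"classes with < 2 members excluded: {dropped}", stacklevel=2)
    if len(keep) < 2:
        raise SignatureValidationError("need >= 2 classes with >= 2 members")

    records = []
    for i, (a, b) in enumerate(itertools.combinations(keep, 2)):
        mask = classes.isin([a, b]).to_numpy()
        pk = diet_table.loc[mask, prey].to_numpy(dtype=float)
        comp = np.column_stack([pk, 1.0 - pk])
        sub_classes = pd.DataFrame({class_column: classes[mask].to_numpy()})
        if np.allclose(comp.std(axis=0), 0.0):
            records.append([a, b, int(mask.sum()), 0.0, 1.0])
            continue
        D = chi_square_distance(comp)
        res = permanova(D, sub_classes, [class_column], n_perm=n_perm,
                        seed=None if seed is None else seed + i)
        records.append([a, b, int(mask.sum()), res.F(class_column), res.p(class_column)])
    out = pd.DataFrame(records, columns=["class_a", "class_b", "n", "pseudo_F", "p_raw"])
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman correlation (n <= 9)."""
    perms = np.array(list(itertools.permutations(x_ranks)))
    xc = perms - perms.mean(axis=1, keepdims=True)
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    r_all = (xc @ yc) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def annual_mean_trend(
    diet_table: pd.DataFrame,
    prey: Sequence[str],
    *,
    year_column: str = "year",
) -> dict[str, TrendResult]:
    """Spearman trend of each prey's annual mean proportion against year.

    Exact two-sided permutation p for <= 9 years, large-sample approximation
    otherwise.  Requires at least 3 distinct years.
    """
    years = sorted(pd.unique(diet_table[year_column].astype(int)))
    if len(years) < 3:
        raise SignatureValidationError("need >= 3 distinct years for a trend test")
    out = {}
    yr = np.array(years, dtype=float)
    for sp in prey:
        means = (
            diet_table.groupby(diet_table[year_column].astype(int))[sp]
            .mean()
            .reindex(years)
            .to_numpy(dtype=float)
        )
        r, p_approx = stats.spearmanr(means, yr)
        r = float(r)
        n = len(years)
        if n <= 9:
            p = _spearman_exact_p(stats.rankdata(means), stats.rankdata(yr), r)
        else:
            p = float(p_approx)
        out[sp] = TrendResult(r_s=r, p=p, n=n)
    return out


def ice_covariate_permanova(
    diet_table: pd.DataFrame,
    ice: IceIndexTable,
    index: str,
    *,
    prey: Sequence[str],
    class_column: str = "class",
    year_column: str = "year",
    include_interaction: bool = True,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """perMANOVA with an annual sea-ice index replacing the year factor.

    The chosen index (``ifd50``, ``ifd15`` or ``melt_season``) enters as a
    1-df continuous covariate, followed by sex/age class and optionally
    their interaction; the response is the chi-square distance between diet
    compositions.  Years absent from the ice table are an error.
    """
    cov = ice.index_for_years(diet_table[year_column].astype(int).tolist(), index)
    factors = pd.DataFrame(
        {index: cov, class_column: diet_table[class_column].astype(str).to_numpy()}
    )
    terms = [index, class_column]
    if include_interaction:
        terms.append(f"{index}:{class_column}")
    D = chi_square_distance(diet_table.loc[:, list(prey)].to_numpy(dtype=float))
    return permanova(D, factors, terms, n_perm=n_perm, seed=seed)
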