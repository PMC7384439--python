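"""Group-level inference on clustered unit data.

Units are nested within birds, so unit-level song responses are not
independent observations: treating them as such would pseudoreplicate.
Two complementary inferences respect the clustering:

* a two-level random-intercept linear mixed model,

      y = X beta + Z_bird u_bird + Z_unit u_unit + eps,

  with fixed effects for rearing group, song type (CON/HET), direction
  (FOR/REV), song identity and the group x song-type interaction, fitted
  by restricted maximum likelihood (REML) on the variance components
  (bird, unit-within-bird, residual);

* a bird-level permutation test of the group x song-type interaction:
  the statistic is the group difference of bird-mean (CON - HET)
  response strength, and the null distribution permutes rearing labels
  across whole birds.  Because birds are the independent replicates,
  exchangeability at the bird level is exactly what a null rearing
  effect implies, making the test valid under arbitrary within-bird
  correlation.

Mann-Whitney U (exact for small samples) and the Brown-Forsythe variant
of Levene's test round out the distributional checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

EXACT_PERMUTATION_LIMIT = 20_000


# ---------------------------------------------------------------------------
# long table / transformation


@dataclass
class RSLongTable:
    """Long-format response table with its recorded transformation."""

    data: pd.DataFrame
    transform: str  # "log" | "identity"
    offset: float  # c in ln(mean_rs + c); 0 for identity


def build_long_table(rs_table: pd.DataFrame, transform: str = "log") -> RSLongTable:
    """Attach a ``transformed_rs`` column to a song RS table.

    The natural-log transform uses ``ln(mean_rs + c)`` with
    ``c = 1 - min(mean_rs)`` over the whole table, so the smallest
    argument of the log is exactly 1; negative response strengths
    (suppressed responses) therefore stay representable.  The offset is
    recorded so the transform is invertible and auditable.
    """
    if rs_table.empty:
        raise ValueError("empty RS table")
    df = rs_table.copy()
    if transform == "identity":
        offset = 0.0
        df["transformed_rs"] = df["mean_rs"]
    elif transform == "log":
        offset = float(1.0 - df["mean_rs"].min())
        df["transformed_rs"] = np.log(df["mean_rs"] + offset)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return RSLongTable(data=df, transform=transform, offset=offset)


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class ModelFit:
    beta: pd.Series
    var_bird: float
    var_unit: float
    var_resid: float
    loglik_reml: float
    converged: bool
    n_obs: int
    message: str = ""

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "bird": self.var_bird,
            "unit": self.var_unit,
            "residual": self.var_resid,
        }


def _design_matrices(
    table: RSLongTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    df = table.data
    y = df["transformed_rs"].to_numpy(dtype=float)
    n = len(df)

    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("model expects exactly two rearing groups")
    g = (df["group"] == groups[1]).to_numpy(dtype=float)
    het = (df["song_type"] == "HET").to_numpy(dtype=float)
    rev = (df["direction"] == "REV").to_numpy(dtype=float)

    cols = [np.ones(n), g, het, rev, g * het]
    names = [
        "intercept",
        f"group[{groups[1]}]",
        "song_type[HET]",
        "direction[REV]",
        f"group[{groups[1]}]:song_type[HET]",
    ]
    # song identity is nested within song type, so dummies are per type
    # (first song of each type is the reference) to keep X full rank
    for stype in sorted(df["song_type"].unique()):
        songs = sorted(df.loc[df["song_type"] == stype, "song_id"].unique())
        for s in songs[1:]:
            cols.append((df["song_id"] == s).to_numpy(dtype=float))
            names.append(f"song[{s}]")
    X = np.column_stack(cols)

    birds = sorted(df["bird_id"].unique())
    units = sorted(df["unit_id"].unique())
    Zb = np.zeros((n, len(birds)))
    Zu = np.zeros((n, len(units)))
    Zb[np.arange(n), df["bird_id"].map({b: i for i, b in enumerate(birds)})] = 1.0
    Zu[np.arange(n), df["unit_id"].map({u: i for i, u in enumerate(units)})] = 1.0
    return y, X, Zb, Zu, names


def _neg2_reml(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    ZtZ: np.ndarray,
    Zty: np.ndarray,
    ZtX: np.ndarray,
    q_bird: int,
) -> float:
    """-2 x restricted log-likelihood at log-variances ``theta``.

    V = se2 I + Z G Z' with G = diag(sb2 I, su2 I).  All solves go
    through the q x q matrix A = se2 G^-1 + Z'Z (Woodbury), so the cost
    is O(n q) + O(q^3) rather than O(n^3).
    """
    sb2, su2, se2 = np.exp(theta)
    n, p = X.shape
    q = ZtZ.shape[0]
    gdiag = np.concatenate([np.full(q_bird, sb2), np.full(q - q_bird, su2)])

    A = ZtZ + np.diag(se2 / gdiag)
    try:
        cA = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf

    def vinv(M_t, ZtM):
        # V^-1 M = (M - Z A^-1 Z'M) / se2
        w = np.linalg.solve(cA.T, np.linalg.solve(cA, ZtM))
        return (M_t - Z @ w) / se2

    ViX = vinv(X, ZtX)
    Viy = vinv(y, Zty)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf
    # r' V^-1 r = y' V^-1 y - beta' X' V^-1 y at the GLS solution
    rVir = float(y @ Viy - beta @ XtViy)

    # log|V| = (n - q) log se2 + sum log diag(cA)^2 + sum log gdiag
    logdet_V = (n - q) * math.log(se2) + 2.0 * float(
        np.log(np.diag(cA)).sum()
    ) + float(np.log(gdiag).sum())
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    return logdet_V + logdet_XtViX + rVir + (n - p) * math.log(2.0 * math.pi)


def _gls_beta(y, X, Z, ZtZ, Zty, ZtX, q_bird, sb2, su2, se2) -> np.ndarray:
    """Generalized-least-squares fixed effects at given variance components."""
    gdiag = np.concatenate([np.full(q_bird, sb2), np.full(Z.shape[1] - q_bird, su2)])
    A = ZtZ + np.diag(se2 / gdiag)
    cA = np.linalg.cholesky(A)
    ViX = (X - Z @ np.linalg.solve(cA.T, np.linalg.solve(cA, ZtX))) / se2
    Viy = (y - Z @ np.linalg.solve(cA.T, np.linalg.solve(cA, Zty))) / se2
    return np.linalg.solve(X.T @ ViX, X.T @ Viy)


def fixed_effects_at(
    table: RSLongTable, var_bird: float, var_unit: float, var_resid: float
) -> pd.Series:
    """Fixed effects by GLS at fixed variance components.

    With both random-effect variances at (effectively) zero this reduces
    to ordinary least squares.
    """
    y, X, Zb, Zu, names = _design_matrices(table)
    Z = np.hstack([Zb, Zu])
    beta = _gls_beta(
        y, X, Z, Z.T @ Z, Z.T @ y, Z.T @ X, Zb.shape[1],
        max(var_bird, 1e-12), max(var_unit, 1e-12), var_resid,
    )
    return pd.Series(beta, index=names)


def fit_random_intercept_model(table: RSLongTable) -> ModelFit:
    """REML fit of the two-level random-intercept mixed model.

    Optimizes the restricted likelihood over log variance components
    (bird, unit-within-bird, residual) with a quasi-Newton search from a
    moment-based start; estimates touching the lower bound correspond to
    components at the zero boundary.
    """
    df = table.data
    for g in df["group"].unique():
        if df.loc[df["group"] == g, "bird_id"].nunique() < 2:
            raise ValueError(f"need at least 2 birds in group {g}")

    y, X, Zb, Zu, names = _design_matrices(table)
    Z = np.hstack([Zb, Zu])
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    ZtX = Z.T @ X
    q_bird = Zb.shape[1]

    vy = float(np.var(y)) or 1.0
    x0 = np.log(np.array([vy / 4, vy / 4, vy / 2]))
    bounds = [(-12.0, 8.0)] * 3
    obj = lambda th: _neg2_reml(th, y, X, Z, ZtZ, Zty, ZtX, q_bird)
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead")
        if res2.fun <= res.fun:
            res = res2

    sb2, su2, se2 = np.exp(res.x)
    beta = _gls_beta(y, X, Z, ZtZ, Zty, ZtX, q_bird, sb2, su2, se2)

    return ModelFit(
        beta=pd.Series(beta, index=names),
        var_bird=float(sb2),
        var_unit=float(su2),
        var_resid=float(se2),
        loglik_reml=-0.5 * float(res.fun),
        converged=bool(res.success or res.fun < np.inf),
        n_obs=len(y),
        message=str(res.message),
    )


def neg2_reml_dense(
    table: RSLongTable, var_bird: float, var_unit: float, var_resid: float
) -> float:
    """-2 restricted log-likelihood by direct dense-matrix evaluation.

    Independent O(n^3) reference implementation used to validate the
    Woodbury-factored objective; useful only at toy problem sizes.
    """
    y, X, Zb, Zu, _ = _design_matrices(table)
    n, p = X.shape
    V = (
        var_resid * np.eye(n)
        + var_bird * Zb @ Zb.T
        + var_unit * Zu @ Zu.T
    )
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (
        float(np.linalg.slogdet(V)[1])
        + float(np.linalg.slogdet(XtViX)[1])
        + float(r @ Vi @ r)
        + (n - p) * math.log(2.0 * math.pi)
    )


# ---------------------------------------------------------------------------
# bird-level permutation test


@dataclass
class PermutationResult:
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    bird_diffs: pd.Series = field(repr=False, default=None)


def _bird_type_diffs(df: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-bird mean(CON) - mean(HET) and the group labels, bird order fixed."""
    means = (
        df.groupby(["bird_id", "song_type"], sort=True)[value_col].mean().unstack()
    )
    if "CON" not in means or "HET" not in means:
        raise ValueError("table must contain both CON and HET rows")
    diffs = (means["CON"] - means["HET"]).to_numpy(dtype=float)
    bird_group = df.groupby("bird_id", sort=True)["group"].first()
    return diffs, bird_group.to_numpy()


def n_exact_assignments(n_birds: int, n_group1: int) -> int:
    """Number of distinct group-label assignments across birds."""
    return math.comb(n_birds, n_group1)


def permutation_interaction_test(
    table: RSLongTable | pd.DataFrame,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    value_col: str = "mean_rs",
    method: str = "auto",
) -> PermutationResult:
    """Bird-level permutation test of the rearing x song-type interaction.

    Statistic: T = mean over ZF-ZF birds of (bird-mean CON - bird-mean
    HET) minus the same for ZF-CF birds, where bird means pool all units
    and songs of the bird.  The null distribution reassigns the rearing
    labels across birds: exhaustively when the number of assignments is
    at most 20,000, otherwise by ``n_perm`` Monte-Carlo draws with the
    add-one correction (the observed assignment counts as one draw).
    ``method`` forces one mode ("exact" | "monte_carlo") instead of the
    size-based default.  Two-sided p-value on |T|.
    """
    df = table.data if isinstance(table, RSLongTable) else table
    diffs, groups = _bird_type_diffs(df, value_col)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("need exactly two rearing groups")
    n1 = int(np.sum(groups == labels[0]))
    n2 = int(np.sum(groups == labels[1]))
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 birds per group")
    nb = n1 + n2

    def stat(mask1: np.ndarray) -> float:
        return float(diffs[mask1].mean() - diffs[~mask1].mean())

    obs_mask = groups == labels[0]
    t_obs = stat(obs_mask)

    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    n_assign = n_exact_assignments(nb, n1)
    use_exact = (
        method == "exact"
        or (method == "auto" and n_assign <= EXACT_PERMUTATION_LIMIT)
    )
    if use_exact and n_assign > EXACT_PERMUTATION_LIMIT:
        raise ValueError(f"{n_assign} assignments is too many to enumerate")
    if use_exact:
        null = np.empty(n_assign)
        for i, idx in enumerate(itertools.combinations(range(nb), n1)):
            m = np.zeros(nb, dtype=bool)
            m[list(idx)] = True
            null[i] = stat(m)
        p = float(np.mean(np.abs(null) >= abs(t_obs) - 1e-12))
        return PermutationResult(
            statistic=t_obs,
            p_value=p,
            n_permutations=n_assign,
            exact=True,
            bird_diffs=pd.Series(diffs),
        )

    if seed is None:
        raise ValueError("Monte-Carlo permutation mode requires a seed")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(nb)
        m = np.zeros(nb, dtype=bool)
        m[perm[:n1]] = True
        if abs(stat(m)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        statistic=t_obs,
        p_value=p,
        n_permutations=n_perm,
        exact=False,
        bird_diffs=pd.Series(diffs),
    )


# ---------------------------------------------------------------------------
# rank and variance-homogeneity tests


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties shared."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of the first sample, p-value).

    Uses the exact permutation null (enumeration of rank assignments)
    when ``min(n1, n2) <= 8`` and there are no ties, and the normal
    approximation with tie correction and continuity correction
    otherwise.  ``alternative`` is "two-sided", "greater" (first sample
    tends larger) or "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    has_ties = len(np.unique(pooled)) < pooled.size
    if min(n1, n2) <= 8 and not has_ties:
        # exact: U1 for every way of choosing which pooled ranks belong to x
        all_ranks = np.arange(1, n1 + n2 + 1)
        null_u = np.array(
            [
                sum(c) - n1 * (n1 + 1) / 2.0
                for c in itertools.combinations(all_ranks, n1)
            ]
        )
        total = null_u.size
        p_greater = np.count_nonzero(null_u >= u1) / total
        p_less = np.count_nonzero(null_u <= u1) / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return u1, float(p)

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    n = n1 + n2
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u1, 1.0
    sigma = math.sqrt(sigma2)
    if alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sigma
        p = stats.norm.cdf(z)
    else:
        z = (abs(u1 - mu) - 0.5) / sigma
        p = 2.0 * stats.norm.sf(z)
    return u1, float(min(1.0, p))


def levene_test(*groups: Sequence[float]) -> tuple[float, float]:
    """Brown-Forsythe test of variance homogeneity.

    Absolute deviations from each group's median enter a one-way ANOVA;
    the statistic W follows an F(k-1, N-k) reference distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    zs = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("each group needs at least two values")
        zs.append(np.abs(g - np.median(g)))
    k = len(zs)
    ns = np.array([z.size for z in zs])
    N = int(ns.sum())
    means = np.array([z.mean() for z in zs])
    grand = float(np.concatenate(zs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((z - m) ** 2).sum() for z, m in zip(zs, means)))
    if ss_within == 0:
        return 0.0 if ss_between == 0 else math.inf, 1.0 if ss_between == 0 else 0.0
    w = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(stats.f.sf(w, k - 1, N - k))
    return w, p
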