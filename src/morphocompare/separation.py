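"""Separative power and measurer effect: CVA and two-way PERMANOVA.

For these analyses each (individual, measurer) contributes one randomly
chosen repeat, giving a matrix of n_sites * n_individuals * n_measurers
specimens per species and method.  Canonical variate analysis ordinates the
specimens to maximize between-group relative to within-group variance;
pairwise population detachment is tested by two-group permutation tests on
the Euclidean distance matrix.  A crossed two-way PERMANOVA (site x
measurer) partitions the summed squared Euclidean distances and compares
the pseudo-F of the biological factor (site) against the pseudo-F of the
nuisance factor (measurer): a method whose measurer F dominates is
subjective, its population signal overwritten by who measured.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, squareform


class UnbalancedDesignError(ValueError):
    """The crossed design has unequal cell sizes."""


@dataclass
class AnalysisMatrix:
    """One randomly chosen repeat per (individual, measurer)."""

    labels: pd.DataFrame  # species, site, individual, measurer, chosen_repeat
    values: np.ndarray
    variable_names: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.labels)


def select_random_repeat(labels: pd.DataFrame, values: np.ndarray,
                         seed: int | np.random.SeedSequence | None = None,
                         ) -> AnalysisMatrix:
    """Choose one repeat uniformly at random per (individual, measurer).

    All (species, site, individual, measurer) cells must offer the same set
    of repeats (complete design).
    """
    values = np.asarray(values, dtype=float)
    if isinstance(values, np.ndarray) and values.ndim == 1:
        values = values[:, None]
    rng = np.random.default_rng(seed)
    groups = labels.groupby(["species", "site", "individual", "measurer"],
                            sort=True)
    repeat_sets = {tuple(sorted(sub["repeat"])) for _, sub in groups}
    if len(repeat_sets) != 1:
        raise ValueError("incomplete design: repeat sets differ across "
                         f"(individual, measurer) cells: {sorted(repeat_sets)[:4]}")
    rows = []
    for _, sub in groups:
        rows.append(sub.index[rng.integers(len(sub))])
    rows = np.array(rows)
    chosen = labels.loc[rows].reset_index(drop=True)
    chosen = chosen.rename(columns={"repeat": "chosen_repeat"})
    var_names = [f"v{i + 1}" for i in range(values.shape[1])]
    return AnalysisMatrix(labels=chosen, values=values[rows],
                         variable_names=var_names)


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    A = -0.5 * D2
    row = A.mean(axis=0)
    return A - row[None, :] - row[:, None] + A.mean()


def _projector(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    out = np.zeros((len(labels), len(levels)))
    out[np.arange(len(labels)), inv] = 1.0
    return out


@dataclass
class PermanovaTable:
    """Distance-based SS partition for a crossed two-way (or one-way) design."""

    sources: list[str]
    ss: np.ndarray
    df: np.ndarray
    F: np.ndarray      # nan where df == 0 or for Residual/Total
    p: np.ndarray      # nan likewise
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        ms = np.where(self.df > 0, self.ss / np.where(self.df > 0, self.df, 1),
                      np.nan)
        return pd.DataFrame({
            "Source": self.sources,
            "Sum of sqrs": self.ss,
            "df": self.df,
            "Mean square": ms,
            "F": self.F,
            "p": self.p,
        })

    def __getitem__(self, source: str) -> dict:
        i = self.sources.index(source)
        return {"SS": self.ss[i], "df": int(self.df[i]), "F": self.F[i],
                "p": self.p[i]}


def permanova_two_way(values: np.ndarray, factor_a, factor_b,
                      n_perm: int = 9999,
                      seed: int | np.random.SeedSequence | None = None,
                      factor_names: tuple[str, str] = ("sampling site", "measurer"),
                      ) -> PermanovaTable:
    """Two-way crossed PERMANOVA on Euclidean distances.

    SS are partitioned from the Gower-centred squared-distance matrix
    (SS_total = (1/n) * sum_{i<j} d_ij^2); the interaction SS is obtained by
    subtracting both main effects from the cell-means SS.  Pseudo-F uses the
    residual mean square; p-values come from unrestricted permutation of
    specimen rows, recomputing every F.  The design must be balanced.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    n = values.shape[0]
    if len(a) != n or len(b) != n:
        raise ValueError("factor length does not match number of rows")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is very low for permutation p-values",
                      stacklevel=2)
    cells = pd.Series(range(n)).groupby([pd.Series(a), pd.Series(b)]).size()
    if cells.nunique() != 1:
        raise UnbalancedDesignError(
            f"unbalanced crossed design; cell sizes {sorted(set(cells))}")
    n_a = len(np.unique(a))
    n_b = len(np.unique(b))

    D2 = squareform(pdist(values, metric="sqeuclidean"))
    G = _gower_center(D2)

    one = np.full((n, 1), 1.0)
    H1 = _projector(one)
    Ha = _projector(np.hstack([one, _dummies(a)])) - H1
    Hb = _projector(np.hstack([one, _dummies(b)])) - H1
    cell_labels = np.array([f"{x}||{y}" for x, y in zip(a, b)])
    Hc = _projector(np.hstack([one, _dummies(cell_labels)])) - H1

    df_a = n_a - 1
    df_b = n_b - 1
    df_ab = df_a * df_b
    df_res = n - n_a * n_b
    if df_res < 1:
        raise ValueError("no residual degrees of freedom (one row per cell)")

    def _partition(Gm: np.ndarray) -> tuple[float, float, float, float]:
        ss_t = float(np.trace(Gm))
        ss_a = float((Ha * Gm).sum())
        ss_b = float((Hb * Gm).sum())
        ss_c = float((Hc * Gm).sum())
        return ss_a, ss_b, ss_c - ss_a - ss_b, ss_t - ss_c

    ss_a, ss_b, ss_ab, ss_res = _partition(G)
    ss_total = float(np.trace(G))
    ms_res = ss_res / df_res

    def _fstats(parts) -> np.ndarray:
        sa, sb, sab, sres = parts
        mres = sres / df_res
        out = np.full(3, np.nan)
        if df_a > 0:
            out[0] = (sa / df_a) / mres
        if df_b > 0:
            out[1] = (sb / df_b) / mres
        if df_ab > 0:
            out[2] = (sab / df_ab) / mres
        return out

    F_obs = _fstats((ss_a, ss_b, ss_ab, ss_res))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        Fp = _fstats(_partition(Gp))
        exceed += (Fp >= F_obs - 1e-12)
    p = np.where(np.isnan(F_obs), np.nan, (1 + exceed) / (1 + n_perm))

    sources = [factor_names[0], factor_names[1], "Interaction",
               "Residual", "Total"]
    ss = np.array([ss_a, ss_b, ss_ab, ss_res, ss_total])
    df = np.array([df_a, df_b, df_ab, df_res, n - 1])
    F = np.array([F_obs[0], F_obs[1], F_obs[2], np.nan, np.nan])
    pv = np.array([p[0], p[1], p[2], np.nan, np.nan])
    tab = PermanovaTable(sources, ss, df, F, pv, n_perm)
    # SS partition identity is structural; assert it cheaply on every run
    assert abs(ss_a + ss_b + ss_ab + ss_res - ss_total) <= 1e-8 * max(1.0, ss_total)
    _ = ms_res
    return tab


def permanova_one_way(values: np.ndarray, groups,
                      n_perm: int = 9999,
                      seed: int | np.random.SeedSequence | None = None,
                      ) -> PermanovaTable:
    """One-way PERMANOVA on Euclidean distances (unrestricted permutation)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    g = np.asarray(groups)
    n = values.shape[0]
    n_g = len(np.unique(g))
    if n_g < 2:
        raise ValueError("need at least two groups")
    D2 = squareform(pdist(values, metric="sqeuclidean"))
    G = _gower_center(D2)
    one = np.full((n, 1), 1.0)
    H1 = _projector(one)
    Hg = _projector(np.hstack([one, _dummies(g)])) - H1
    df_g = n_g - 1
    df_res = n - n_g
    ss_t = float(np.trace(G))

    def _F(Gm: np.ndarray) -> float:
        sg = float((Hg * Gm).sum())
        return (sg / df_g) / ((np.trace(Gm) - sg) / df_res)

    F_obs = _F(G)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _F(G[np.ix_(perm, perm)]) >= F_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    ss_g = float((Hg * G).sum())
    return PermanovaTable(
        ["group", "Residual", "Total"],
        np.array([ss_g, ss_t - ss_g, ss_t]),
        np.array([df_g, df_res, n - 1]),
        np.array([F_obs, np.nan, np.nan]),
        np.array([p, np.nan, np.nan]),
        n_perm)


# ---------------------------------------------------------------------------
# CVA


DETACHMENT_CLASSES = {3: "all-three", 2: "two-of-three", 1: "one", 0: "none"}


@dataclass
class CvaResult:
    scores: np.ndarray           # n x n_axes canonical scores
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    axes: np.ndarray             # variables x n_axes
    groups: np.ndarray
    group_centroids: pd.DataFrame
    pairwise_p: dict[tuple, float] = field(default_factory=dict)
    detachment_class: str = ""
    n_significant_pairs: int = 0


def cva(values: np.ndarray, groups, n_perm: int = 9999,
        seed: int | np.random.SeedSequence | None = None,
        alpha: float = 0.05) -> CvaResult:
    """Canonical variate analysis with pairwise permutation detachment tests.

    Rank deficiency (shape variables span at most 2K-4 dimensions) is
    handled by first projecting onto principal components with eigenvalue
    > 1e-10 of the largest (capped at n - g), then solving the generalized
    eigenproblem between/within on the reduced space.  Axis signs are fixed
    by making the largest-magnitude loading positive.  Pairwise group
    detachment is a two-group one-way PERMANOVA on Euclidean distances at
    ``alpha``, uncorrected.
    """
    X = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)
    n, _ = X.shape
    n_g = len(levels)
    if n_g < 2:
        raise ValueError("CVA needs at least two groups")
    counts = np.array([(g == lv).sum() for lv in levels])
    if (counts < 2).any():
        small = levels[counts < 2]
        raise ValueError(f"groups with fewer than 2 specimens: {list(small)}")

    grand = X.mean(axis=0)
    Xc = X - grand
    # PCA reduction
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s ** 2 > 1e-10 * s[0] ** 2 if s[0] > 0 else np.zeros(len(s), bool)
    keep &= np.arange(len(s)) < max(1, n - n_g)
    V = Vt[keep].T
    Z = Xc @ V

    # between / within covariance on the reduced space
    W = np.zeros((Z.shape[1], Z.shape[1]))
    B = np.zeros_like(W)
    for lv, cnt in zip(levels, counts):
        Zg = Z[g == lv]
        mg = Zg.mean(axis=0)
        W += (Zg - mg).T @ (Zg - mg)
        B += cnt * np.outer(mg, mg)
    W /= (n - n_g)
    B /= max(n_g - 1, 1)

    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(n_g - 1, Z.shape[1])
    evals = np.clip(evals[order][:n_axes], 0, None)
    evecs = evecs[:, order][:, :n_axes]
    axes = V @ evecs
    # reproducible axis sign: largest-magnitude loading positive
    for j in range(axes.shape[1]):
        i_max = np.argmax(np.abs(axes[:, j]))
        if axes[i_max, j] < 0:
            axes[:, j] = -axes[:, j]
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ axes
    total = evals.sum()
    pct = 100 * evals / total if total > 0 else np.zeros_like(evals)

    centroids = pd.DataFrame(
        [dict(group=lv, **{f"cv{j + 1}": scores[g == lv, j].mean()
                           for j in range(n_axes)}) for lv in levels])

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(list(itertools.combinations(levels, 2))))
    pairwise_p = {}
    for (la, lb), ss_child in zip(itertools.combinations(levels, 2), children):
        mask = (g == la) | (g == lb)
        tab = permanova_one_way(X[mask], g[mask], n_perm=n_perm, seed=ss_child)
        pairwise_p[(la, lb)] = tab["group"]["p"]
    n_sig = sum(p < alpha for p in pairwise_p.values())
    if n_g == 3:
        detachment = DETACHMENT_CLASSES[n_sig]
    else:
        detachment = f"{n_sig}/{len(pairwise_p)}"

    return CvaResult(scores=scores, eigenvalues=evals, percent_variance=pct,
                     axes=axes, groups=g, group_centroids=centroids,
                     pairwise_p=pairwise_p, detachment_class=detachment,
                     n_significant_pairs=n_sig)
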