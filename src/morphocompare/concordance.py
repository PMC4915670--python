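"""Repeatability and reproducibility via pairwise Mantel tests.

Each dataset (one measurer's one repeat of one population, after size
correction) is converted to a Euclidean distance matrix over its
individuals.  Repeatability compares the repeats of one measurer
(intra-measurer similarity), reproducibility the datasets of different
measurers (inter-measurer similarity, all repeat pairings).  The Mantel
correlation R of two matrices scores the agreement; its permutation p-value
tests positive association.  R values are then grouped at consecutive levels
(measurer, species, method) and compared with Kruskal-Wallis tests,
summarized by a compact letter display.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class IncompleteDesignError(ValueError):
    """The collection of datasets does not cover the full crossed design."""


class ZeroVarianceError(ValueError):
    """A distance matrix has no variation among its entries."""


@dataclass
class SpecimenMatrix:
    """One dataset: the individuals of one population measured once.

    Rows are sorted by individual id so that matched datasets align
    row-for-row.
    """

    species: str
    site: str
    measurer: str
    repeat: int
    individual_ids: list[str]
    values: np.ndarray  # individuals x variables

    @property
    def key(self) -> tuple:
        return (self.species, self.site, self.measurer, self.repeat)


def build_specimen_matrices(labels: pd.DataFrame, values: np.ndarray,
                            ) -> dict[tuple, SpecimenMatrix]:
    """Split a long table into one SpecimenMatrix per (species, site,
    measurer, repeat), rows sorted canonically by individual id."""
    values = np.asarray(values, dtype=float)
    out: dict[tuple, SpecimenMatrix] = {}
    for key, idx in labels.groupby(
            ["species", "site", "measurer", "repeat"], sort=True).indices.items():
        idx = np.asarray(idx)
        ids = labels["individual"].values[idx]
        order = np.argsort(ids)
        out[key] = SpecimenMatrix(
            species=key[0], site=key[1], measurer=key[2], repeat=int(key[3]),
            individual_ids=list(ids[order]), values=values[idx[order]])
    return out


def euclidean_distance_matrix(m: SpecimenMatrix | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix over individuals."""
    values = m.values if isinstance(m, SpecimenMatrix) else np.asarray(m, float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if np.isnan(values).any():
        if isinstance(m, SpecimenMatrix):
            bad = [i for i, row in zip(m.individual_ids, values)
                   if np.isnan(row).any()]
            raise ValueError(f"missing values for individuals: {bad}")
        raise ValueError("missing values in input table")
    return squareform(pdist(values, metric="euclidean"))


@dataclass
class MantelResult:
    R: float
    p: float
    n_perm: int
    n_specimens: int
    exact: bool = False


def _triangle(A: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], 1)
    return A[iu]


def mantel_test(A: np.ndarray, B: np.ndarray, n_perm: int = 9999,
                seed: int | np.random.SeedSequence | None = None,
                method: str = "auto") -> MantelResult:
    """Mantel test of association between two distance matrices.

    R is the Pearson correlation of the off-diagonal upper triangles; p is
    one-sided for positive association, (1 + exceedances) / (1 + n_perm)
    under joint row/column permutation of B.  With ``method="exact"`` (the
    default for n <= 8) all n! permutations are enumerated and p is the
    exact fraction of permutations with R at least as large as observed.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"matrices must be square and equal-shaped, "
                         f"got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    if method not in ("auto", "exact", "random"):
        raise ValueError(f"unknown method {method!r}")
    a = _triangle(A)
    b = _triangle(B)
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("distance matrix has zero variance; R undefined")
    ac = a - a.mean()
    ac /= np.sqrt((ac ** 2).sum())
    bc = b - b.mean()
    bc /= np.sqrt((bc ** 2).sum())
    r_obs = float(ac @ bc)

    exact = method == "exact" or (method == "auto" and n <= 8)
    ii, jj = np.triu_indices(n, 1)
    if not exact and n_perm == 0:
        # R only; no permutation null requested
        return MantelResult(R=r_obs, p=float("nan"), n_perm=0,
                            n_specimens=n, exact=False)
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        total = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        total = n_perm
    r_perm = np.empty(total)
    chunk = 20000
    for start in range(0, total, chunk):
        P = perms[start:start + chunk]
        bp = B[P[:, ii], P[:, jj]]
        bp = bp - bp.mean(axis=1, keepdims=True)
        norms = np.sqrt((bp ** 2).sum(axis=1))
        r_perm[start:start + P.shape[0]] = (bp @ ac) / norms
    exceed = int((r_perm >= r_obs - 1e-12).sum())
    if exact:
        p = exceed / total
    else:
        p = (1 + exceed) / (1 + total)
    return MantelResult(R=r_obs, p=float(p), n_perm=total,
                        n_specimens=n, exact=exact)


def enumerate_pairs(keys, mode: str) -> list[tuple[tuple, tuple]]:
    """Dataset pairs to compare for one method.

    ``keys`` are (species, site, measurer, repeat) tuples covering a complete
    crossed design.  Repeatability pairs the repeats of each measurer
    (repeat_a < repeat_b); reproducibility pairs different measurers'
    datasets in all repeat pairings (measurer_a < measurer_b).
    """
    if mode not in ("repeatability", "reproducibility"):
        raise ValueError(f"unknown mode {mode!r}")
    keys = sorted(keys)
    species = sorted({k[0] for k in keys})
    sites = sorted({k[1] for k in keys})
    measurers = sorted({k[2] for k in keys})
    repeats = sorted({k[3] for k in keys})
    expected = set(itertools.product(species, sites, measurers, repeats))
    missing = sorted(expected - set(keys))
    if missing:
        raise IncompleteDesignError(
            f"design incomplete; missing cells: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    pairs = []
    for sp, site in itertools.product(species, sites):
        if mode == "repeatability":
            for m in measurers:
                for ra, rb in itertools.combinations(repeats, 2):
                    pairs.append(((sp, site, m, ra), (sp, site, m, rb)))
        else:
            for ma, mb in itertools.combinations(measurers, 2):
                for ra, rb in itertools.product(repeats, repeats):
                    pairs.append(((sp, site, ma, ra), (sp, site, mb, rb)))
    return pairs


def concordance_table(matrices: dict[tuple, SpecimenMatrix], mode: str,
                      n_perm: int = 9999, seed: int | None = None,
                      method: str = "random", mantel_method: str = "auto",
                      ) -> pd.DataFrame:
    """All pairwise Mantel comparisons for one method's datasets.

    Returns one row per comparison with the pair labels, R, p, and a
    significance flag at p < 0.05 (the S5/S6 reporting layout).
    """
    pairs = enumerate_pairs(matrices.keys(), mode)
    dmats = {key: euclidean_distance_matrix(m) for key, m in matrices.items()}
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    rows = []
    for (ka, kb), ss in zip(pairs, children):
        ma, mb = matrices[ka], matrices[kb]
        if ma.individual_ids != mb.individual_ids:
            raise ValueError(
                f"individual sets differ between datasets {ka} and {kb}")
        res = mantel_test(dmats[ka], dmats[kb], n_perm=n_perm, seed=ss,
                          method=mantel_method)
        rows.append({
            "species": ka[0], "site": ka[1],
            "measurer_a": ka[2], "repeat_a": ka[3],
            "measurer_b": kb[2], "repeat_b": kb[3],
            "R": res.R, "p": res.p, "n_perm": res.n_perm,
            "n_specimens": res.n_specimens,
            "significant": res.p < 0.05,
        })
    out = pd.DataFrame(rows)
    if mode == "repeatability":
        # intra-measurer rows: expose the (single) measurer for level-I grouping
        out.insert(2, "measurer", out["measurer_a"])
    out.attrs["mode"] = mode
    return out


def compact_letter_display(groups: list, sig_pairs: set[frozenset]) -> dict:
    """Greedy insert-absorb compact letter display.

    Groups sharing a letter are not significantly different.  ``groups``
    should be ordered (e.g. by decreasing mean) for stable lettering.
    """
    sets: list[set] = [set(groups)]
    for pair in sig_pairs:
        g1, g2 = tuple(pair)
        new_sets = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb: drop duplicates and subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


LEVEL_FAMILIES = {
    "measurer": ["method", "species"],
    "species": ["method"],
    "method": [],
}


def group_and_compare(table: pd.DataFrame, level: str, alpha: float = 0.05,
                      value_col: str = "R", group_col: str | None = None,
                      ) -> dict:
    """Group Mantel R values at one level and test group differences.

    ``table`` must carry the grouping columns (a ``method`` column is added
    by the pipeline when tables of several methods are concatenated).
    Returns ``summaries`` (one row per group per family with mean, SD, n and
    letter), ``omnibus`` (Kruskal-Wallis H and p per family) and
    ``pairwise`` (two-group Kruskal-Wallis p per group pair per family).
    Groups with fewer than 2 values are excluded with a warning row in
    ``summaries`` (letter NA).
    """
    if level not in LEVEL_FAMILIES:
        raise ValueError(f"unknown level {level!r}")
    group_col = group_col or level
    family_cols = [c for c in LEVEL_FAMILIES[level] if c in table.columns]
    if family_cols:
        families = list(table.groupby(family_cols, sort=True))
    else:
        families = [((), table)]
    summaries = []
    omnibus = []
    pairwise = []
    for fam_key, fam in families:
        fam_key = fam_key if isinstance(fam_key, tuple) else (fam_key,)
        fam_id = dict(zip(family_cols, fam_key))
        groups = {g: sub[value_col].to_numpy(float)
                  for g, sub in fam.groupby(group_col, sort=True)}
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        ordered = sorted(usable, key=lambda g: -usable[g].mean())
        H = p_omni = np.nan
        if len(usable) >= 2:
            H, p_omni = stats.kruskal(*usable.values())
        sig_pairs = set()
        for ga, gb in itertools.combinations(sorted(usable), 2):
            _, p_pair = stats.kruskal(usable[ga], usable[gb])
            pairwise.append({**fam_id, "group_a": ga, "group_b": gb,
                             "p": p_pair, "significant": p_pair < alpha})
            if p_pair < alpha:
                sig_pairs.add(frozenset((ga, gb)))
        letters = compact_letter_display(ordered, sig_pairs) if ordered else {}
        for g, v in groups.items():
            summaries.append({
                **fam_id, "group": g, "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "n": len(v), "letter": letters.get(g, "NA"),
            })
        omnibus.append({**fam_id, "H": H, "p": p_omni,
                        "n_groups": len(usable)})
    return {
        "summaries": pd.DataFrame(summaries),
        "omnibus": pd.DataFrame(omnibus),
        "pairwise": pd.DataFrame(pairwise),
        "level": level,
    }


def expected_pair_count(n_species: int, n_sites: int, n_measurers: int,
                        n_repeats: int, mode: str) -> int:
    """Closed-form comparison count per method for a complete design."""
    cells = n_species * n_sites
    if mode == "repeatability":
        return cells * n_measurers * math.comb(n_repeats, 2)
    if mode == "reproducibility":
        return cells * math.comb(n_measurers, 2) * n_repeats ** 2
    raise ValueError(f"unknown mode {mode!r}")
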