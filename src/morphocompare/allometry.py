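"""Allometric size standardization of linear measurements.

Distance-based morphometric data confound body size with shape: larger fish
have larger measurements.  The standard remedy scales each measurement M to
the value it would take at the common mean standard length Ls,

    M_adj = M * (Ls / L0) ** b,

where L0 is the specimen's standard length and b the allometric exponent of
that variable, estimated as the slope of log10(M) on log10(L0).  After
standardization no variable should retain a significant correlation with SL;
:func:`recheck_decorrelation` performs that check.

Note on the formula: the ratio form above is the classical allometric
correction.  A frequently seen typographical variant writes the subtraction
(Ls - L0) in place of the ratio; it is dimensionally inconsistent and not
idempotent, but can be selected with ``literal_subtraction=True`` for
forensic comparison against outputs produced with it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DistanceDataset


@dataclass
class AllometricModel:
    """Per-variable allometric exponents and the reference mean SL."""

    Ls: float
    b: pd.Series  # indexed by variable name
    group_key: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.Ls > 0:
            raise ValueError("Ls must be positive")
        if not np.isfinite(self.b.to_numpy(float)).all():
            raise ValueError("non-finite allometric exponent")


def fit_allometry(data: DistanceDataset,
                  pooling: tuple[str, ...] | str = ("site",),
                  ) -> AllometricModel:
    """Estimate b per variable as a pooled within-group log-log OLS slope.

    Within-group slopes are averaged weighted by group degrees of freedom
    (n_g - 2).  Records with a zero measurement are excluded from that
    variable's slope fit with a warning.  Ls is the arithmetic mean SL over
    the whole analysis set.
    """
    if isinstance(pooling, str):
        pooling = (pooling,)
    pooling = tuple(pooling)
    if data.n_records < 3:
        raise ValueError("need at least 3 specimens to fit allometry")
    sl = data.sl
    V = data.values.to_numpy(float)
    names = data.variable_names
    if pooling:
        groups = list(data.labels.groupby(list(pooling), sort=True).indices.values())
    else:
        groups = [np.arange(data.n_records)]
    log_sl = np.log10(sl)

    b = np.zeros(len(names))
    for j, name in enumerate(names):
        num = 0.0
        den = 0.0
        for idx in groups:
            idx = np.asarray(idx)
            m = V[idx, j]
            keep = m > 0
            if keep.sum() < len(idx):
                warnings.warn(
                    f"excluding {len(idx) - int(keep.sum())} zero measurements "
                    f"of {name} from the slope fit", stacklevel=2)
            x = log_sl[idx][keep]
            if len(x) < 3 or np.ptp(x) < 1e-12:
                continue
            slope = stats.linregress(x, np.log10(m[keep])).slope
            w = len(x) - 2
            num += w * slope
            den += w
        if den == 0:
            raise ValueError(
                f"cannot estimate allometric exponent for {name}: "
                "SL constant (or too few positive values) in every group")
        b[j] = num / den
    return AllometricModel(Ls=float(sl.mean()),
                           b=pd.Series(b, index=names), group_key=pooling)


def standardize(data: DistanceDataset, model: AllometricModel,
                literal_subtraction: bool = False,
                suffix: str = "_adj") -> DistanceDataset:
    """Size-adjust every measurement to the common mean SL.

    Default is the ratio form M * (Ls/L0)**b; ``literal_subtraction``
    switches to M * (Ls - L0)**b (see the module docstring).
    """
    missing = [v for v in data.variable_names if v not in model.b.index]
    if missing:
        raise ValueError(f"model has no exponent for variables: {missing}")
    if (data.sl <= 0).any():
        raise ValueError("standard length must be positive")
    b = model.b.loc[data.variable_names].to_numpy(float)
    M = data.values.to_numpy(float)
    if literal_subtraction:
        base = model.Ls - data.sl
        adj = M * np.power(base[:, None], b[None, :])
    else:
        adj = M * np.power((model.Ls / data.sl)[:, None], b[None, :])
    out = pd.DataFrame(adj, columns=[f"{v}{suffix}" for v in data.variable_names])
    return DistanceDataset(data.labels.copy(), data.sl.copy(), out, data.method)


def recheck_decorrelation(data: DistanceDataset,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each (standardized) variable against SL.

    Returns one row per variable with columns ``r``, ``p``, ``passed`` and
    ``status``; variables with zero variance are reported as not-applicable.
    """
    if data.n_records < 3:
        raise ValueError("need at least 3 specimens")
    rows = []
    for name in data.variable_names:
        v = data.values[name].to_numpy(float)
        if np.var(v) < 1e-24 * max(1.0, float(np.mean(v)) ** 2):
            rows.append((name, np.nan, np.nan, True, "not-applicable"))
            continue
        r, p = stats.pearsonr(v, data.sl)
        rows.append((name, r, p, p > alpha, "ok"))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "passed", "status"])
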