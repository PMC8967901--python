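"""Cross-cell-type and cross-quantity comparisons on a log10 scale.

All correlations over abundances, concentrations, and perturbation
distances are Pearson R on log10-transformed values, so unit changes
(copies vs uM) never move R.  SBR values are already log10 ratios and are
correlated directly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .metrics import StoichResult
from .network import ValidationError

logger = logging.getLogger("stoichbalance")


@dataclass
class CorrelationResult:
    r: float
    n: int
    excluded: dict[str, str] = field(default_factory=dict)


def correlate_log10(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson R between two labelled positive series, on log10 values.

    Labels missing from either series, or carrying non-positive or NaN
    values (zero or unknown copies), are dropped and logged.  Fewer than
    three surviving pairs is an error.
    """
    excluded: dict[str, str] = {}
    shared = x.index.intersection(y.index)
    for label in x.index.union(y.index):
        if label not in shared:
            excluded[label] = "missing in one series"
    keep = []
    for label in shared:
        xv, yv = x[label], y[label]
        if pd.isna(xv) or pd.isna(yv):
            excluded[label] = "undefined value"
        elif xv <= 0 or yv <= 0:
            excluded[label] = "non-positive value"
            warnings.warn(f"{label}: non-positive value dropped from correlation", stacklevel=2)
        else:
            keep.append(label)
    if len(keep) < 3:
        raise ValidationError(f"need >= 3 positive shared pairs, got {len(keep)}")
    lx = np.log10(x[keep].astype(float).to_numpy())
    ly = np.log10(y[keep].astype(float).to_numpy())
    r, _ = scipy.stats.pearsonr(lx, ly)
    return CorrelationResult(r=float(r), n=len(keep), excluded=excluded)


def correlate(x: pd.Series, y: pd.Series, *, min_n: int = 3) -> CorrelationResult:
    """Plain Pearson R on already-log-scale quantities (e.g. SBR vectors)."""
    shared = x.index.intersection(y.index)
    excluded = {str(l): "missing in one series" for l in x.index.union(y.index) if l not in shared}
    mask = x[shared].notna() & y[shared].notna()
    for label in shared[~mask]:
        excluded[str(label)] = "undefined value"
    keep = shared[mask]
    if len(keep) < min_n:
        raise ValidationError(f"need >= {min_n} shared pairs, got {len(keep)}")
    r, _ = scipy.stats.pearsonr(x[keep].to_numpy(), y[keep].to_numpy())
    return CorrelationResult(r=float(r), n=len(keep), excluded=excluded)


@dataclass
class CellComparison:
    """Pairwise cross-cell-type comparison of SBR and concentration."""

    pair_tables: dict[tuple[str, str], pd.DataFrame]
    sbr_correlations: dict[tuple[str, str], CorrelationResult]
    concentration_correlations: dict[tuple[str, str], CorrelationResult]


def compare_cells(results: dict[str, StoichResult]) -> CellComparison:
    """Per-molecule deltas and pairwise R across cell types.

    For each cell-type pair the table holds ``delta_SBR = SBR_1 - SBR_2``
    and ``delta_log10_C = log10 C_1 - log10 C_2`` per shared molecule, plus
    Pearson R between the SBR vectors and between log10 concentrations.
    Swapping the pair order negates every delta.
    """
    pair_tables: dict[tuple[str, str], pd.DataFrame] = {}
    sbr_corr: dict[tuple[str, str], CorrelationResult] = {}
    conc_corr: dict[tuple[str, str], CorrelationResult] = {}
    for c1, c2 in itertools.combinations(sorted(results), 2):
        t1, t2 = results[c1].per_molecule, results[c2].per_molecule
        shared = t1.index.intersection(t2.index)
        df = pd.DataFrame(index=shared)
        df["delta_SBR"] = t1.loc[shared, "SBR"] - t2.loc[shared, "SBR"]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["delta_log10_C"] = np.log10(
                t1.loc[shared, "C_obs"].astype(float)
            ) - np.log10(t2.loc[shared, "C_obs"].astype(float))
        df["outlier"] = (df["delta_SBR"].abs() > 1.0) | (df["delta_log10_C"].abs() > 1.0)
        pair_tables[(c1, c2)] = df
        sbr_corr[(c1, c2)] = correlate(t1["SBR"], t2["SBR"])
        conc_corr[(c1, c2)] = correlate_log10(t1["C_obs"], t2["C_obs"])
    return CellComparison(
        pair_tables=pair_tables,
        sbr_correlations=sbr_corr,
        concentration_correlations=conc_corr,
    )
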