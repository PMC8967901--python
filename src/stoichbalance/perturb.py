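"""In-silico knockdowns and the disruption/sensitivity indices.

A knockdown removes one molecule and its incident edges, re-solves the
balance optimization with identical settings, and recomputes SBR for every
remaining molecule.  Two squared-distance scores summarize a full scan:

* disruption of a removed molecule k: sum over molecules p (present and
  scored in both networks) of ``(SBR_p^k - SBR_p)^2`` — how much removing k
  reshuffles everyone else's stoichiometry;
* sensitivity of a molecule a: sum over knockdowns k != a of
  ``(SBR_a^k - SBR_a)^2`` — how much a's own stoichiometry moves as others
  are removed.

The removed-molecule index is called ``removed`` throughout, never alpha:
the optimizer weight alpha is an unrelated quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .balance import balance_network
from .metrics import interface_cv, sbr
from .network import CopyNumberTable, InteractionNetwork, ValidationError, filter_network

logger = logging.getLogger("stoichbalance")


@dataclass
class KnockdownMatrix:
    """Baseline SBR plus one row of SBR values per single-molecule removal."""

    baseline: pd.Series
    matrix: pd.DataFrame  # index: removed molecule; columns: molecule; (k, k) is NaN
    baseline_interface: pd.Series | None = None
    interface_matrix: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        out = pd.concat([self.baseline.to_frame("baseline").T, self.matrix])
        out.to_csv(path, index_label="removed")


@dataclass
class PerturbationScores:
    disruption: pd.Series
    sensitivity: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"disruption": self.disruption, "sensitivity": self.sensitivity})


def _prepare(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    **balance_opts,
) -> tuple[pd.Series, pd.Series]:
    """Filter, balance, and return (per-molecule SBR, per-interface SBR)."""
    reduced = filter_network(
        net, table, cell_type, drop_lipids=True, drop_zero_copy=True
    )
    solution = balance_network(reduced, table, cell_type, **balance_opts)
    return sbr(table, solution, cell_type, net=reduced)


def knockdown(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    molecule: str,
    **balance_opts,
) -> pd.Series:
    """SBR of every remaining molecule after removing one node.

    The molecule and all incident edges are removed; interfaces left with no
    partner drop out of their protein's balanced-copy average (logged).
    """
    if molecule not in net.molecules:
        raise ValidationError(f"{molecule!r} not in network")
    reduced = net.without_molecules([molecule])
    lost = {
        r
        for r in net.connected_interfaces()
        if r[0] != molecule and r not in reduced.connected_interfaces()
    }
    if lost:
        logger.info("knockdown of %s disconnects interfaces: %s", molecule, sorted(lost))
    series, _ = _prepare(reduced, table, cell_type, **balance_opts)
    return series


def knockdown_scan(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    targets: Sequence[str] | None = None,
    *,
    include_cargo: bool = False,
    per_interface: bool = False,
    **balance_opts,
) -> KnockdownMatrix:
    """One independent re-optimization per removed molecule.

    ``targets`` defaults to every protein in the (filtered) network; cargo
    classes are included only on request.  Rows are independent, so scanning
    a subset reproduces the corresponding rows of a full scan exactly.
    """
    base_net = filter_network(net, table, cell_type, drop_lipids=True, drop_zero_copy=True)
    baseline, baseline_iface = _prepare(net, table, cell_type, **balance_opts)
    if targets is None:
        targets = [
            n
            for n in sorted(base_net.molecules)
            if base_net.molecules[n].kind == "protein"
            or (include_cargo and base_net.molecules[n].kind == "cargo_class")
        ]
    rows: dict[str, pd.Series] = {}
    iface_rows: dict[str, pd.Series] = {}
    for target in targets:
        if target not in base_net.molecules:
            raise ValidationError(f"scan target {target!r} not in filtered network")
        reduced = base_net.without_molecules([target])
        row, iface_row = _prepare(reduced, table, cell_type, **balance_opts)
        rows[target] = row
        if per_interface:
            iface_rows[target] = iface_row
    matrix = pd.DataFrame(rows).T.reindex(columns=baseline.index)
    for t in matrix.index:
        if t in matrix.columns:
            matrix.loc[t, t] = np.nan
    result = KnockdownMatrix(baseline=baseline, matrix=matrix)
    if per_interface:
        result.baseline_interface = baseline_iface
        imat = pd.DataFrame(iface_rows).T.reindex(columns=baseline_iface.index)
        for t in imat.index:
            own = [c for c in imat.columns if c[0] == t]
            imat.loc[t, own] = np.nan
        result.interface_matrix = imat
    return result


def _distance_scores(baseline: pd.Series, matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    delta = matrix.sub(baseline, axis=1)
    sq = delta**2
    disruption = sq.sum(axis=1, skipna=True)
    col_sums = sq.sum(axis=0, skipna=True)
    sensitivity = col_sums.reindex(baseline.index, fill_value=0.0)
    return disruption.astype(float), sensitivity.astype(float)


def disruption(matrix: KnockdownMatrix) -> pd.Series:
    """Squared SBR distance caused by each removal (molecules scored in both)."""
    d, _ = _distance_scores(matrix.baseline, matrix.matrix)
    d.name = "disruption"
    return d


def sensitivity(matrix: KnockdownMatrix) -> pd.Series:
    """Squared SBR distance of each molecule across all removals of others."""
    _, s = _distance_scores(matrix.baseline, matrix.matrix)
    s.name = "sensitivity"
    return s


def perturbation_scores(matrix: KnockdownMatrix, *, use_interfaces: bool = False) -> PerturbationScores:
    """Disruption and sensitivity in one object.

    With ``use_interfaces=True`` the distances are computed on per-interface
    SBR values before any per-protein averaging; on dense natural networks
    the two routes correlate at R close to 1.
    """
    if use_interfaces:
        if matrix.interface_matrix is None or matrix.baseline_interface is None:
            raise ValidationError("scan was not run with per_interface=True")
        d, s_if = _distance_scores(matrix.baseline_interface, matrix.interface_matrix)
        # fold interface-level sensitivity back onto molecules
        s = s_if.groupby(level=0).sum()
        d.name, s.name = "disruption", "sensitivity"
        return PerturbationScores(disruption=d, sensitivity=s)
    d, s = _distance_scores(matrix.baseline, matrix.matrix)
    d.name, s.name = "disruption", "sensitivity"
    return PerturbationScores(disruption=d, sensitivity=s)
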