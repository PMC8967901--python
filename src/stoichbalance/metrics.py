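"""Stoichiometry statistics: partner stoichiometry, SBR, and interface CV.

Two log10 ratios summarize supply vs demand for each molecule:

* **SP** (partner stoichiometry) compares a protein's observed copies to the
  interface-averaged summed copies of its direct partners — a nearest-
  neighbor measure that ignores competition beyond the first shell.
* **SBR** (stoichiometric balance ratio) = log10(C_obs / C_balanced), where
  C_balanced comes from the whole-network balance optimization; SBR > 0
  means excess supply (super-stoichiometric), SBR < 0 insufficient supply.

The per-protein coefficient of variation (CV) of balanced interface copies
flags proteins whose interfaces are pushed to very different copy numbers,
typically one interface competing at a hub plus one exclusive partner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalanceSolution
from .network import CopyNumberTable, InteractionNetwork

logger = logging.getLogger("stoichbalance")

#: Floor applied to balanced copies inside log ratios.
C_BALANCED_FLOOR = 1e-6


@dataclass
class StoichResult:
    """Per-molecule and per-interface stoichiometry table."""

    per_molecule: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_interface: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded: dict[str, str] = field(default_factory=dict)

    def to_csv(self, molecule_path, interface_path=None) -> None:
        self.per_molecule.to_csv(molecule_path, index_label="name")
        if interface_path is not None and not self.per_interface.empty:
            self.per_interface.to_csv(interface_path, index_label=["molecule", "interface"])


def _scored_molecules(
    net: InteractionNetwork, table: CopyNumberTable, cell_type: str
) -> tuple[InteractionNetwork, dict[str, str]]:
    """Apply the standard exclusions (lipids, zero-copy) and log them."""
    excluded: dict[str, str] = {}
    for name, mol in net.molecules.items():
        if mol.kind == "lipid":
            excluded[name] = "lipid"
        elif table.status(name, cell_type) == "zero" and table.effective_copies(net, name, cell_type) is None:
            excluded[name] = "zero copies"
    reduced = net.without_molecules(excluded)
    return reduced, excluded


def partner_stoichiometry(
    net: InteractionNetwork, table: CopyNumberTable, cell_type: str
) -> pd.Series:
    """SP per molecule: log10 of own copies over interface-averaged partner copies.

    For each connected interface i of p, partner copies are summed over the
    partner interfaces of i (a partner binding through two distinct
    interfaces counts twice; a self-interaction adds p's own copies once).
    The denominator averages these sums over interfaces that have at least
    one scoreable partner.  Partners with unknown copies contribute zero;
    lipids and zero-copy molecules are excluded before scoring.  Molecules
    whose own copies are unknown, or whose partner sum is zero, get NaN.
    """
    reduced, excluded = _scored_molecules(net, table, cell_type)
    connected = reduced.connected_interfaces()
    out: dict[str, float] = {}
    for name in sorted(reduced.molecules):
        own = table.effective_copies(reduced, name, cell_type)
        if own is None:
            out[name] = np.nan
            continue
        iface_sums: list[float] = []
        for iface in reduced.molecules[name].interfaces:
            ref = (name, iface)
            if ref not in connected:
                continue
            partners = reduced.partners_of_interface(ref)
            if not partners:
                continue
            total = 0.0
            for pmol, _ in partners:
                pc = table.effective_copies(reduced, pmol, cell_type)
                total += pc if pc is not None else 0.0
            iface_sums.append(total)
        if not iface_sums:
            out[name] = np.nan
            continue
        denom = float(np.mean(iface_sums))
        out[name] = np.log10(own / denom) if denom > 0 else np.nan
    series = pd.Series(out, dtype=float).sort_index()
    series.name = "SP"
    return series


def sbr(
    table: CopyNumberTable,
    solution: BalanceSolution,
    cell_type: str,
    net: InteractionNetwork | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-molecule and per-interface SBR from a balance solution.

    ``SBR_p = log10(C_obs(p) / C_balanced(p))`` with C_balanced(p) the mean
    of the protein's balanced interface copies; the per-interface variant
    uses the interface's own balanced copies.  Molecules with unknown
    observed copies get NaN.  Balanced copies below the numeric floor are
    floored with a warning.
    """
    per_mol: dict[str, float] = {}
    for name, cb in solution.balanced_protein_copies.items():
        obs = (
            table.effective_copies(net, name, cell_type)
            if net is not None
            else table.copies(name, cell_type)
        )
        if obs is None:
            per_mol[name] = np.nan
            continue
        if cb < C_BALANCED_FLOOR:
            warnings.warn(
                f"balanced copies for {name} below floor ({cb:.3g}); floored",
                stacklevel=2,
            )
            cb = C_BALANCED_FLOOR
        per_mol[name] = float(np.log10(obs / cb))
    per_iface: dict[tuple[str, str], float] = {}
    for (mol, iface), x in solution.interface_copies.items():
        obs = (
            table.effective_copies(net, mol, cell_type)
            if net is not None
            else table.copies(mol, cell_type)
        )
        if obs is None:
            per_iface[(mol, iface)] = np.nan
            continue
        x = max(x, C_BALANCED_FLOOR)
        per_iface[(mol, iface)] = float(np.log10(obs / x))
    mol_series = pd.Series(per_mol, dtype=float).sort_index()
    mol_series.name = "SBR"
    idx = pd.MultiIndex.from_tuples(sorted(per_iface), names=["molecule", "interface"])
    iface_series = pd.Series([per_iface[k] for k in idx], index=idx, dtype=float)
    iface_series.name = "SBR_interface"
    return mol_series, iface_series


def interface_cv(solution: BalanceSolution) -> pd.Series:
    """Coefficient of variation of balanced copies across a protein's interfaces.

    Population (n) standard deviation over mean; single-interface molecules
    get CV = 0, as do all-zero interface copies.
    """
    by_mol: dict[str, list[float]] = {}
    for (mol, _), x in solution.interface_copies.items():
        by_mol.setdefault(mol, []).append(x)
    out: dict[str, float] = {}
    for mol, xs in by_mol.items():
        arr = np.asarray(xs, dtype=float)
        mean = arr.mean()
        out[mol] = float(arr.std() / mean) if arr.size > 1 and mean > 0 else 0.0
    series = pd.Series(out, dtype=float).sort_index()
    series.name = "CV"
    return series


def stoichiometry_table(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    solution: BalanceSolution,
) -> StoichResult:
    """Assemble the full per-molecule stoichiometry report.

    Columns: functional class, observed and balanced copies, SP, SBR, CV,
    number of connected interfaces, and degree in the (unfiltered) network.
    """
    reduced, excluded = _scored_molecules(net, table, cell_type)
    sp = partner_stoichiometry(net, table, cell_type)
    sbr_mol, sbr_iface = sbr(table, solution, cell_type, net=reduced)
    cv = interface_cv(solution)
    connected = reduced.connected_interfaces()
    rows = []
    for name in sorted(solution.balanced_protein_copies):
        mol = reduced.molecules.get(name)
        rows.append(
            {
                "name": name,
                "class": (mol.functional_class if mol is not None else None) or "",
                "C_obs": table.effective_copies(reduced, name, cell_type),
                "C_balanced": solution.balanced_protein_copies[name],
                "SP": sp.get(name, np.nan),
                "SBR": sbr_mol.get(name, np.nan),
                "CV": cv.get(name, 0.0),
                "n_interfaces": sum(1 for r in connected if r[0] == name),
                "degree": net.degree(name) if name in net.molecules else 0,
            }
        )
    per_molecule = pd.DataFrame(rows).set_index("name") if rows else pd.DataFrame()
    per_interface = pd.DataFrame(
        {
            "C_balanced": solution.interface_series(),
            "SBR_interface": sbr_iface,
        }
    )
    return StoichResult(per_molecule=per_molecule, per_interface=per_interface, excluded=excluded)
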