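"""Interface-resolved interaction networks and per-cell-type copy numbers.

The central object is the :class:`InteractionNetwork`: molecules (proteins,
membrane lipids, or cargo classes — groups of transmembrane receptors treated
as one node) carry named binding *interfaces* (structured domains, residue
patches, or short linear motifs), and undirected edges connect interface to
interface.  This resolution is what lets the balance optimizer partition a
protein's copies between competing and cooperative interactions.

Copy numbers are kept per (molecule, cell type) with an explicit three-way
status: *observed* (a positive count), *zero* (the protein is known to be
absent, so it is removed from the network before any balance analysis), and
*unknown* (the protein stays in the network but its copies are unconstrained).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("stoichbalance")

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23

#: Cell volumes in litres.  Only reported concentrations (uM) depend on these;
#: every stoichiometry statistic is scale invariant.  The synaptosome is a
#: compartment ~6000x smaller than a HeLa cell.
DEFAULT_CELL_VOLUMES: dict[str, float] = {
    "HeLa": 2.2e-12,
    "fibroblast": 2.0e-12,
    "synaptosome": 2.2e-12 / 6000.0,
}

MOLECULE_KINDS = ("protein", "lipid", "cargo_class")

FUNCTIONAL_CLASSES = (
    "AP2",
    "adaptor",
    "kinase",
    "phosphatase",
    "dynamin",
    "cofactor",
    "BAR",
    "cytoskeletal",
    "abundant",
    "other",
)


class NetworkFormatError(ValueError):
    """Malformed network/copy-number file (carries the offending line)."""


class ValidationError(ValueError):
    """Inconsistent in-memory model (dangling reference, bad status, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """A network node: a protein, a lipid, or a cargo class.

    ``interfaces`` is the ordered list of binding-site labels, unique within
    the molecule.  ``functional_class`` applies to proteins only; cargo
    classes may list their member gene symbols in ``cargo_members``.
    """

    name: str
    kind: str = "protein"
    functional_class: str | None = None
    interfaces: list[str] = field(default_factory=list)
    cargo_members: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.kind not in MOLECULE_KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if len(set(self.interfaces)) != len(self.interfaces):
            raise ValidationError(f"{self.name}: duplicate interface labels")
        if self.kind == "lipid" and self.functional_class is not None:
            raise ValidationError(f"{self.name}: lipids carry no functional class")
        if self.kind == "cargo_class" and not self.cargo_members:
            raise ValidationError(f"{self.name}: cargo class with no members")
        if self.kind != "cargo_class" and self.cargo_members:
            raise ValidationError(f"{self.name}: cargo_members on non-cargo node")
        if self.functional_class is not None and self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValidationError(
                f"{self.name}: unknown functional class {self.functional_class!r}"
            )


#: An interface reference is simply a (molecule name, interface label) pair.
InterfaceRef = tuple[str, str]


@dataclass(frozen=True)
class Interaction:
    """An undirected interface-interface edge.

    Endpoints are stored in canonical (lexicographic) order so ``(a, b)`` and
    ``(b, a)`` compare equal; self-edges (``a == b``, an interface binding
    itself, e.g. a homodimerization site) are allowed.
    """

    a: InterfaceRef
    b: InterfaceRef
    interaction_class: str = "unspecified"
    enzymatic: bool = False
    conditional: bool = False
    isoform_specific: bool = False
    provenance: str = "matched"

    def __post_init__(self) -> None:
        if self.b < self.a:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def is_self(self) -> bool:
        return self.a == self.b

    @property
    def key(self) -> tuple[InterfaceRef, InterfaceRef]:
        return (self.a, self.b)

    def touches(self, molecule: str) -> bool:
        return self.a[0] == molecule or self.b[0] == molecule


@dataclass
class InteractionNetwork:
    """Molecules plus interface-resolved interactions."""

    molecules: dict[str, Molecule] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    def add_molecule(self, mol: Molecule) -> None:
        if mol.name in self.molecules:
            raise ValidationError(f"duplicate molecule {mol.name!r}")
        mol.validate()
        self.molecules[mol.name] = mol

    def add_interaction(self, inter: Interaction, *, strict: bool = False) -> None:
        """Add an edge, auto-registering molecules/interfaces unless strict."""
        for mol_name, iface in (inter.a, inter.b):
            if mol_name not in self.molecules:
                if strict:
                    raise ValidationError(
                        f"edge references undeclared molecule {mol_name!r}"
                    )
                self.molecules[mol_name] = Molecule(name=mol_name)
            mol = self.molecules[mol_name]
            if iface not in mol.interfaces:
                mol.interfaces.append(iface)
        if inter.key in {e.key for e in self.interactions}:
            logger.warning("duplicate edge %s collapsed", inter.key)
            return
        self.interactions.append(inter)

    # -- basic queries ----------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_edges(self) -> int:
        return len(self.interactions)

    @property
    def n_interfaces(self) -> int:
        return sum(len(m.interfaces) for m in self.molecules.values())

    def connected_interfaces(self) -> set[InterfaceRef]:
        """Interfaces that appear in at least one edge.

        Interfaces listed on a molecule but absent from every edge stay in
        the data model but are excluded from all balance computations.
        """
        out: set[InterfaceRef] = set()
        for e in self.interactions:
            out.add(e.a)
            out.add(e.b)
        return out

    def partners_of_interface(self, ref: InterfaceRef) -> list[InterfaceRef]:
        """Partner interfaces of ``ref`` (one entry per incident edge)."""
        out: list[InterfaceRef] = []
        for e in self.interactions:
            if e.is_self:
                if e.a == ref:
                    out.append(e.a)
            elif e.a == ref:
                out.append(e.b)
            elif e.b == ref:
                out.append(e.a)
        return out

    def degree(self, molecule: str) -> int:
        """Number of interactions with >= 1 endpoint on the molecule.

        Self-interactions count once.
        """
        return sum(1 for e in self.interactions if e.touches(molecule))

    def validate(self) -> None:
        for mol in self.molecules.values():
            mol.validate()
        seen: set[tuple[InterfaceRef, InterfaceRef]] = set()
        for e in self.interactions:
            for mol_name, iface in (e.a, e.b):
                if mol_name not in self.molecules:
                    raise ValidationError(f"edge references unknown molecule {mol_name!r}")
                if iface not in self.molecules[mol_name].interfaces:
                    raise ValidationError(
                        f"edge references unknown interface {mol_name}:{iface}"
                    )
            if e.key in seen:
                raise ValidationError(f"duplicate edge {e.key}")
            seen.add(e.key)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(
            molecules={n: replace(m, interfaces=list(m.interfaces)) for n, m in self.molecules.items()},
            interactions=list(self.interactions),
        )

    def without_molecules(self, names: Iterable[str]) -> "InteractionNetwork":
        """New network with the named molecules and incident edges removed."""
        drop = set(names)
        net = InteractionNetwork(
            molecules={
                n: replace(m, interfaces=list(m.interfaces))
                for n, m in self.molecules.items()
                if n not in drop
            },
            interactions=[e for e in self.interactions if e.a[0] not in drop and e.b[0] not in drop],
        )
        return net


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

COPY_STATUSES = ("observed", "zero", "unknown")


@dataclass(frozen=True)
class CopyEntry:
    status: str
    copies_per_cell: float | None = None

    def validate(self, name: str = "?") -> None:
        if self.status not in COPY_STATUSES:
            raise ValidationError(f"{name}: bad status {self.status!r}")
        if self.status == "observed":
            if self.copies_per_cell is None or not self.copies_per_cell > 0:
                raise ValidationError(
                    f"{name}: observed entries need copies_per_cell > 0 "
                    f"(got {self.copies_per_cell!r})"
                )
        elif self.copies_per_cell is not None:
            raise ValidationError(f"{name}: status {self.status} carries no copies")


@dataclass
class CopyNumberTable:
    """Per-(molecule, cell type) observed copies with explicit status."""

    entries: dict[tuple[str, str], CopyEntry] = field(default_factory=dict)
    cell_volumes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CELL_VOLUMES))

    def set(self, name: str, cell_type: str, status: str, copies: float | None = None) -> None:
        entry = CopyEntry(status=status, copies_per_cell=copies)
        entry.validate(name)
        self.entries[(name, cell_type)] = entry

    def cell_types(self) -> list[str]:
        return sorted({ct for (_, ct) in self.entries})

    def get(self, name: str, cell_type: str) -> CopyEntry | None:
        return self.entries.get((name, cell_type))

    def status(self, name: str, cell_type: str) -> str:
        """Status for a molecule; missing rows count as unknown."""
        e = self.entries.get((name, cell_type))
        return e.status if e is not None else "unknown"

    def copies(self, name: str, cell_type: str) -> float | None:
        e = self.entries.get((name, cell_type))
        if e is None or e.status != "observed":
            return None
        return e.copies_per_cell

    def concentration(self, name: str, cell_type: str) -> float | None:
        """Concentration in uM: copies / (N_A * volume) * 1e6."""
        c = self.copies(name, cell_type)
        vol = self.cell_volumes.get(cell_type)
        if c is None or vol is None:
            return None
        return c / (AVOGADRO * vol) * 1e6

    def observed_series(self, cell_type: str) -> pd.Series:
        data = {
            name: e.copies_per_cell
            for (name, ct), e in self.entries.items()
            if ct == cell_type and e.status == "observed"
        }
        return pd.Series(data, dtype=float).sort_index()

    def zero_molecules(self, cell_type: str) -> set[str]:
        return {
            name
            for (name, ct), e in self.entries.items()
            if ct == cell_type and e.status == "zero"
        }

    def scaled(self, factor: float) -> "CopyNumberTable":
        """All observed copies multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValidationError("scale factor must be positive")
        out = CopyNumberTable(cell_volumes=dict(self.cell_volumes))
        for (name, ct), e in self.entries.items():
            out.entries[(name, ct)] = (
                CopyEntry("observed", e.copies_per_cell * factor)
                if e.status == "observed"
                else e
            )
        return out

    def effective_copies(self, net: InteractionNetwork, name: str, cell_type: str) -> float | None:
        """Observed copies, with the cargo-class fallback.

        A cargo class with no table row of its own falls back to the sum of
        its members' observed abundances.
        """
        e = self.entries.get((name, cell_type))
        if e is not None:
            return e.copies_per_cell if e.status == "observed" else None
        mol = net.molecules.get(name)
        if mol is not None and mol.kind == "cargo_class":
            member_copies = [
                self.copies(m, cell_type)
                for m in mol.cargo_members
                if self.copies(m, cell_type) is not None
            ]
            if member_copies:
                return float(sum(member_copies))
        return None


# ---------------------------------------------------------------------------
# I/O — tab-separated edge table + molecule table, CSV copy numbers
# ---------------------------------------------------------------------------

NETWORK_COLUMNS = [
    "protein_a",
    "interface_a",
    "protein_b",
    "interface_b",
    "interaction_class",
    "enzymatic",
    "conditional",
    "isoform_specific",
    "provenance",
]

MOLECULE_COLUMNS = ["name", "kind", "functional_class", "cargo_members"]


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in {"1", "true", "yes", "y"}


def _read_table(path: Path, expected_header: Sequence[str], sep: str) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(sep)
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in expected_header if c not in header]
                if missing:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: header missing columns {missing}"
                    )
                continue
            if len(fields) < len(header):
                fields = fields + [""] * (len(header) - len(fields))
            rows.append((lineno, [f.strip() for f in fields[: len(header)]]))
    if header is None:
        raise NetworkFormatError(f"{path}: empty file (no header)")
    # re-order fields to the expected column order
    idx = [header.index(c) for c in expected_header]
    return [(ln, [f[i] for i in idx]) for ln, f in rows]


def read_network(
    path: str | Path,
    molecule_path: str | Path | None = None,
    *,
    strict: bool = False,
) -> InteractionNetwork:
    """Read an interface-resolved network from a tab-separated edge table.

    ``molecule_path`` optionally supplies molecule metadata (kind, functional
    class, cargo members); molecules and interfaces appearing only in edges
    are auto-registered.  Duplicate undirected edge rows collapse to one edge
    with a warning.
    """
    path = Path(path)
    net = InteractionNetwork()
    if molecule_path is not None:
        for lineno, f in _read_table(Path(molecule_path), MOLECULE_COLUMNS, "\t"):
            try:
                name, kind, fclass, members = f
                net.add_molecule(
                    Molecule(
                        name=name,
                        kind=kind or "protein",
                        functional_class=fclass or None,
                        cargo_members=tuple(m for m in members.split(";") if m),
                    )
                )
            except ValidationError as exc:
                raise NetworkFormatError(f"{molecule_path}:{lineno}: {exc}") from exc
    for lineno, f in _read_table(path, NETWORK_COLUMNS, "\t"):
        try:
            pa, ia, pb, ib, klass, enz, cond, iso, prov = f
            if not pa or not ia or not pb or not ib:
                raise NetworkFormatError("empty endpoint field")
            inter = Interaction(
                a=(pa, ia),
                b=(pb, ib),
                interaction_class=klass or "unspecified",
                enzymatic=_parse_bool(enz),
                conditional=_parse_bool(cond),
                isoform_specific=_parse_bool(iso),
                provenance=prov or "matched",
            )
            net.add_interaction(inter, strict=strict)
        except NetworkFormatError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
        except ValidationError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
    net.validate()
    return net


def write_network(net: InteractionNetwork, path: str | Path, molecule_path: str | Path | None = None) -> None:
    """Write the edge table (and optionally the molecule table).

    Edges are written in canonical lexicographic order on the endpoint
    pairs, so output is deterministic for a given network.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NETWORK_COLUMNS) + "\n")
        for e in sorted(net.interactions, key=lambda e: e.key):
            fh.write(
                "\t".join(
                    [
                        e.a[0],
                        e.a[1],
                        e.b[0],
                        e.b[1],
                        e.interaction_class,
                        str(e.enzymatic).lower(),
                        str(e.conditional).lower(),
                        str(e.isoform_specific).lower(),
                        e.provenance,
                    ]
                )
                + "\n"
            )
    if molecule_path is not None:
        with open(molecule_path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(MOLECULE_COLUMNS) + "\n")
            for name in sorted(net.molecules):
                m = net.molecules[name]
                fh.write(
                    "\t".join(
                        [
                            m.name,
                            m.kind,
                            m.functional_class or "",
                            ";".join(m.cargo_members),
                        ]
                    )
                    + "\n"
                )


def write_sif(net: InteractionNetwork, path: str | Path) -> None:
    """SIF export for graph viewers: one ``nodeA relation nodeB`` per edge."""
    with open(Path(path), "w", encoding="utf-8") as fh:
        for e in sorted(net.interactions, key=lambda e: e.key):
            fh.write(f"{e.a[0]} {e.interaction_class} {e.b[0]}\n")


COPY_COLUMNS = ["name", "cell_type", "copies_per_cell", "status"]


def read_copy_numbers(
    path: str | Path,
    cell_type: str | None = None,
    *,
    cell_volumes: Mapping[str, float] | None = None,
) -> CopyNumberTable:
    """Read a copy-number CSV (columns name, cell_type, copies_per_cell, status).

    If ``cell_type`` is given, only that cell type's rows are kept; an
    unknown label raises listing the available types.
    """
    path = Path(path)
    table = CopyNumberTable()
    if cell_volumes is not None:
        table.cell_volumes.update(cell_volumes)
    for lineno, f in _read_table(path, COPY_COLUMNS, ","):
        name, ct, copies_s, status = f
        status = status or "observed"
        copies: float | None
        if copies_s in ("", "-", "NA", "nan"):
            copies = None
        else:
            try:
                copies = float(copies_s)
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: bad copies {copies_s!r}") from exc
            if copies < 0:
                raise NetworkFormatError(f"{path}:{lineno}: negative copies")
        if status != "observed" and copies is not None:
            # tolerate explicit 0 for status=zero rows
            if status == "zero" and copies == 0:
                copies = None
            else:
                raise NetworkFormatError(
                    f"{path}:{lineno}: status {status} cannot carry copies"
                )
        if status == "observed" and (copies is None or copies == 0):
            raise NetworkFormatError(
                f"{path}:{lineno}: observed row needs positive copies"
            )
        try:
            table.set(name, ct, status, copies)
        except ValidationError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
    if cell_type is not None:
        available = table.cell_types()
        if cell_type not in available:
            raise ValidationError(
                f"cell type {cell_type!r} not in file; available: {available}"
            )
        table.entries = {
            key: e for key, e in table.entries.items() if key[1] == cell_type
        }
    return table


def write_copy_numbers(table: CopyNumberTable, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(",".join(COPY_COLUMNS) + "\n")
        for (name, ct) in sorted(table.entries):
            e = table.entries[(name, ct)]
            copies = "" if e.copies_per_cell is None else repr(e.copies_per_cell)
            fh.write(f"{name},{ct},{copies},{e.status}\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_network(
    net: InteractionNetwork,
    table: CopyNumberTable | None = None,
    cell_type: str | None = None,
    *,
    drop_lipids: bool = False,
    drop_zero_copy: bool = False,
    drop_classes: Iterable[str] = (),
    drop_molecules: Iterable[str] = (),
) -> InteractionNetwork:
    """Remove molecules (and incident edges) ahead of balance analysis.

    Lipids are dropped because their relative abundances are orders of
    magnitude above the proteins and they bind with non-1:1 stoichiometry;
    zero-copy molecules are dropped because they are known absent in the
    cell type.  The input network is left unmodified.
    """
    drop: set[str] = set()
    classes = set(drop_classes)
    for name, mol in net.molecules.items():
        if drop_lipids and mol.kind == "lipid":
            drop.add(name)
        if mol.functional_class in classes:
            drop.add(name)
    for name in drop_molecules:
        if name not in net.molecules:
            warnings.warn(f"cannot drop {name!r}: not in network", stacklevel=2)
        else:
            drop.add(name)
    if drop_zero_copy:
        if table is None or cell_type is None:
            raise ValidationError("drop_zero_copy requires a copy table and cell type")
        drop |= {n for n in table.zero_molecules(cell_type) if n in net.molecules}
    return net.without_molecules(drop)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class NetworkStats:
    n_molecules: int
    n_edges: int
    n_interfaces: int
    degrees: dict[str, int]
    interaction_class_counts: dict[str, int]
    class_profile: dict[str, dict[str, int]]  # molecule -> class -> edge count


def network_stats(net: InteractionNetwork) -> NetworkStats:
    """Node/edge/interface counts, degrees, and interaction-class composition.

    A molecule's degree is the number of interactions with at least one
    endpoint on it; self-interactions are counted once.  The per-class
    composition sums to the total edge count.
    """
    degrees = {name: net.degree(name) for name in net.molecules}
    class_counts: dict[str, int] = {}
    profile: dict[str, dict[str, int]] = {name: {} for name in net.molecules}
    for e in net.interactions:
        class_counts[e.interaction_class] = class_counts.get(e.interaction_class, 0) + 1
        mols = {e.a[0], e.b[0]}
        for m in mols:
            prof = profile[m]
            prof[e.interaction_class] = prof.get(e.interaction_class, 0) + 1
    return NetworkStats(
        n_molecules=net.n_molecules,
        n_edges=net.n_edges,
        n_interfaces=net.n_interfaces,
        degrees=degrees,
        interaction_class_counts=class_counts,
        class_profile=profile,
    )
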