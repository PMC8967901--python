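"""Seeded generators for synthetic interface-resolved networks.

Real interface-interaction networks decompose into small, highly
disconnected modules — selective pairs, hubs (one central interface with
many spokes of one domain type), and squares (pairs-of-pairs) — with very
few triangles unless interfaces self-bind.  Protein abundances span about
six orders of magnitude and are roughly log-normal in log10 space, and a
fraction of molecules have unknown or zero copies.  The generator emulates
exactly that structure, plus a *balanced* mode that constructs instances
whose observed copies equal an achievable balance, with the ground-truth
complex counts retained for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .network import (
    FUNCTIONAL_CLASSES,
    CopyNumberTable,
    Interaction,
    InteractionNetwork,
    Molecule,
    ValidationError,
)

logger = logging.getLogger("stoichbalance")

SYNTH_CELL_TYPE = "synthetic"


@dataclass
class SynthesisParams:
    """Knobs of the generator; the seed fully determines the output.

    Defaults mirror the statistical structure of the curated endocytosis
    network: ~80 proteins, a few interfaces per protein, a motif mix
    dominated by pairs and hubs with some squares, abundances log-normal in
    log10 with a six-decade span, and small unknown/zero fractions.
    """

    n_proteins: int = 80
    mean_interfaces: float = 3.0
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"pair": 0.45, "hub": 0.35, "square": 0.20}
    )
    hub_spoke_range: tuple[int, int] = (3, 8)
    selfbind_fraction: float = 0.05
    abundance_log10_mean: float = 4.0
    abundance_log10_sd: float = 1.25
    fraction_unknown: float = 0.05
    fraction_zero: float = 0.03
    seed: int = 0
    mode: str = "random"

    def validate(self) -> None:
        if self.mode not in ("random", "balanced"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_proteins < 2:
            raise ValidationError("need at least 2 proteins")
        if abs(sum(self.motif_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("motif proportions must sum to 1")
        if set(self.motif_mix) - {"pair", "hub", "square"}:
            raise ValidationError(f"unknown motif in mix: {sorted(self.motif_mix)}")
        if self.abundance_log10_sd < 0:
            raise ValidationError("abundance sd must be >= 0")
        lo, hi = self.hub_spoke_range
        if not (1 <= lo <= hi):
            raise ValidationError("bad hub_spoke_range")
        if hi + 1 > self.n_proteins:
            raise ValidationError("hub spokes exceed available proteins")
        if not (0 <= self.fraction_unknown + self.fraction_zero <= 1):
            raise ValidationError("unknown+zero fractions must lie in [0, 1]")
        if self.mean_interfaces < 1:
            raise ValidationError("mean_interfaces must be >= 1")


@dataclass
class SyntheticInstance:
    network: InteractionNetwork
    copies: CopyNumberTable
    cell_type: str = SYNTH_CELL_TYPE
    motifs: list[str] = field(default_factory=list)
    truth: dict | None = None  # balanced mode: complex counts + copies


def _new_interface(net: InteractionNetwork, protein: str) -> tuple[str, str]:
    mol = net.molecules[protein]
    label = f"i{len(mol.interfaces) + 1}"
    mol.interfaces.append(label)
    return (protein, label)


def _module_proteins(rng: np.random.Generator, names: list[str], k: int) -> list[str]:
    """k distinct proteins for one motif module."""
    idx = rng.choice(len(names), size=k, replace=False)
    return [names[i] for i in idx]


def generate(params: SynthesisParams) -> SyntheticInstance:
    """Build one synthetic instance; identical seeds give identical output.

    Modules are disconnected in the interface graph; proteins may host
    interfaces from several modules, which is what couples the balance
    problem across motifs.  In balanced mode every protein carries exactly
    one interface, complex counts are drawn first, interface copies follow
    by summation (self-edges x2), and observed copies are set to each
    protein's mean interface copies — so the constructed allocation attains
    the optimization objective's minimum and is recoverable.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    net = InteractionNetwork()
    names = [f"P{i:04d}" for i in range(params.n_proteins)]
    for i, name in enumerate(names):
        net.add_molecule(
            Molecule(
                name=name,
                kind="protein",
                functional_class=FUNCTIONAL_CLASSES[i % len(FUNCTIONAL_CLASSES)],
            )
        )

    motif_names = sorted(params.motif_mix)
    motif_p = np.array([params.motif_mix[m] for m in motif_names])
    motifs: list[str] = []
    edges: list[Interaction] = []

    if params.mode == "balanced":
        # one interface per protein: modules consume proteins without reuse
        pool = list(names)
        rng.shuffle(pool)
        while len(pool) >= 2:
            motif = rng.choice(motif_names, p=motif_p)
            if motif == "pair":
                need = 2
            elif motif == "square":
                need = 4
            else:
                lo, hi = params.hub_spoke_range
                need = int(rng.integers(lo, hi + 1)) + 1
            if need > len(pool):
                continue_possible = len(pool) >= 2
                if not continue_possible:
                    break
                motif, need = "pair", 2
            members = [pool.pop() for _ in range(need)]
            refs = [_new_interface(net, m) for m in members]
            edges.extend(_motif_edges(motif, refs, rng, selfbind=0.0))
            motifs.append(motif)
    else:
        target_slots = int(round(params.n_proteins * params.mean_interfaces))
        slots = 0
        while slots < target_slots:
            motif = rng.choice(motif_names, p=motif_p)
            if motif == "pair":
                need = 2
            elif motif == "square":
                need = 4
            else:
                lo, hi = params.hub_spoke_range
                need = int(rng.integers(lo, hi + 1)) + 1
            members = _module_proteins(rng, names, need)
            refs = [_new_interface(net, m) for m in members]
            edges.extend(_motif_edges(motif, refs, rng, selfbind=params.selfbind_fraction))
            motifs.append(motif)
            slots += need

    for e in edges:
        net.add_interaction(e)
    net.validate()

    copies = CopyNumberTable()
    truth: dict | None = None
    if params.mode == "balanced":
        counts = 10.0 ** rng.normal(
            params.abundance_log10_mean, params.abundance_log10_sd, size=len(edges)
        )
        iface_copies: dict[tuple[str, str], float] = {}
        for e, c in zip(edges, counts):
            if e.is_self:
                iface_copies[e.a] = iface_copies.get(e.a, 0.0) + 2.0 * c
            else:
                iface_copies[e.a] = iface_copies.get(e.a, 0.0) + c
                iface_copies[e.b] = iface_copies.get(e.b, 0.0) + c
        protein_copies: dict[str, float] = {}
        for name in names:
            xs = [x for (m, _), x in iface_copies.items() if m == name]
            if xs:
                protein_copies[name] = float(np.mean(xs))
        for name, c in protein_copies.items():
            copies.set(name, SYNTH_CELL_TYPE, "observed", c)
        truth = {
            "complex_counts": {e.key: float(c) for e, c in zip(edges, counts)},
            "interface_copies": dict(iface_copies),
            "protein_copies": dict(protein_copies),
        }
    else:
        abund = 10.0 ** rng.normal(
            params.abundance_log10_mean, params.abundance_log10_sd, size=len(names)
        )
        u = rng.random(len(names))
        for name, a, uu in zip(names, abund, u):
            if uu < params.fraction_zero:
                copies.set(name, SYNTH_CELL_TYPE, "zero")
            elif uu < params.fraction_zero + params.fraction_unknown:
                copies.set(name, SYNTH_CELL_TYPE, "unknown")
            else:
                copies.set(name, SYNTH_CELL_TYPE, "observed", float(a))

    return SyntheticInstance(network=net, copies=copies, motifs=motifs, truth=truth)


def _motif_edges(
    motif: str,
    refs: list[tuple[str, str]],
    rng: np.random.Generator,
    *,
    selfbind: float,
) -> list[Interaction]:
    edges: list[Interaction] = []
    if motif == "pair":
        a, b = refs
        if selfbind > 0 and rng.random() < selfbind:
            # a self-binding interface: homodimerization-style edge plus the pair,
            # which licenses a triangle-like closure in the interface graph
            edges.append(Interaction(a=a, b=a, interaction_class="self"))
        edges.append(Interaction(a=a, b=b, interaction_class="pair"))
    elif motif == "square":
        a, b, c, d = refs
        edges += [
            Interaction(a=a, b=b, interaction_class="square"),
            Interaction(a=b, b=c, interaction_class="square"),
            Interaction(a=c, b=d, interaction_class="square"),
            Interaction(a=d, b=a, interaction_class="square"),
        ]
    elif motif == "hub":
        hub, *spokes = refs
        for s in spokes:
            edges.append(Interaction(a=hub, b=s, interaction_class="hub"))
    else:  # pragma: no cover
        raise ValidationError(f"unknown motif {motif!r}")
    return edges


def perturb_abundance(
    inst: SyntheticInstance, molecule: str, factor: float
) -> SyntheticInstance:
    """New instance with one molecule's observed copies multiplied by ``factor``."""
    if not factor > 0:
        raise ValidationError("factor must be positive")
    if molecule not in inst.network.molecules:
        raise ValidationError(f"{molecule!r} not in network")
    copies = CopyNumberTable(cell_volumes=dict(inst.copies.cell_volumes))
    copies.entries = dict(inst.copies.entries)
    entry = copies.entries.get((molecule, inst.cell_type))
    if entry is not None and entry.status == "observed":
        copies.set(molecule, inst.cell_type, "observed", entry.copies_per_cell * factor)
    return SyntheticInstance(
        network=inst.network.copy(),
        copies=copies,
        cell_type=inst.cell_type,
        motifs=list(inst.motifs),
        truth=None if factor != 1 else (dict(inst.truth) if inst.truth else None),
    )
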