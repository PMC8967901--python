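"""Shared fixtures: tiny hand-built networks with known closed-form balances."""

from __future__ import annotations

import numpy as np
import pytest

from stoichbalance import (
    CopyNumberTable,
    Interaction,
    InteractionNetwork,
    Molecule,
)

CELL = "testcell"


def make_pair(copies_a: float = 100.0, copies_b: float = 1.0):
    """A-B single-interface pair; one edge, one decision variable."""
    net = InteractionNetwork()
    net.add_interaction(Interaction(a=("A", "i1"), b=("B", "i1"), interaction_class="pair"))
    table = CopyNumberTable()
    table.set("A", CELL, "observed", copies_a)
    table.set("B", CELL, "observed", copies_b)
    return net, table


def make_hub(copies: float = 10.0):
    """Hub A bound by spokes B and C, all single-interface, equal copies."""
    net = InteractionNetwork()
    net.add_interaction(Interaction(a=("A", "i1"), b=("B", "i1"), interaction_class="hub"))
    net.add_interaction(Interaction(a=("A", "i1"), b=("C", "i1"), interaction_class="hub"))
    table = CopyNumberTable()
    for name in "ABC":
        table.set(name, CELL, "observed", copies)
    return net, table


def make_chain(copies=(100.0, 10.0, 1.0)):
    """B-A(i1), A(i2)-C chain: A has two interfaces with distinct partners."""
    net = InteractionNetwork()
    net.add_interaction(Interaction(a=("B", "i1"), b=("A", "i1")))
    net.add_interaction(Interaction(a=("A", "i2"), b=("C", "i1")))
    table = CopyNumberTable()
    for name, c in zip("BAC", copies):
        table.set(name, CELL, "observed", c)
    return net, table


def make_two_pairs(copies=(10.0, 10.0, 500.0, 500.0)):
    """Two disconnected balanced pairs A-B and C-D."""
    net = InteractionNetwork()
    net.add_interaction(Interaction(a=("A", "i1"), b=("B", "i1")))
    net.add_interaction(Interaction(a=("C", "i1"), b=("D", "i1")))
    table = CopyNumberTable()
    for name, c in zip("ABCD", copies):
        table.set(name, CELL, "observed", c)
    return net, table


def random_tiny_instance(rng: np.random.Generator, max_edges: int = 4):
    """Random connected-ish instance with <= ``max_edges`` edges.

    Molecules are single- or double-interface proteins; abundances span a
    few decades; suitable for the brute-force oracle.
    """
    n_edges = int(rng.integers(1, max_edges + 1))
    n_proteins = int(rng.integers(2, 2 * n_edges + 2))
    names = [f"M{i}" for i in range(n_proteins)]
    net = InteractionNetwork()
    for name in names:
        net.add_molecule(Molecule(name=name))
    refs = []
    for name in names:
        n_if = int(rng.integers(1, 3))
        for k in range(n_if):
            label = f"i{k + 1}"
            net.molecules[name].interfaces.append(label)
            refs.append((name, label))
    edges = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 200:
        attempts += 1
        i, j = rng.integers(0, len(refs), size=2)
        a, b = refs[i], refs[j]
        if a[0] == b[0] and a != b:
            continue  # avoid intra-protein edges between distinct interfaces
        key = tuple(sorted((a, b)))
        edges.add(key)
    net2 = InteractionNetwork()
    for name in names:
        net2.add_molecule(Molecule(name=name, interfaces=[]))
    for a, b in sorted(edges):
        net2.add_interaction(Interaction(a=a, b=b))
    table = CopyNumberTable()
    for name in names:
        table.set(name, CELL, "observed", float(10.0 ** rng.uniform(0, 3)))
    return net2, table


@pytest.fixture
def pair():
    return make_pair()


@pytest.fixture
def hub():
    return make_hub()


@pytest.fixture
def chain():
    return make_chain()
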