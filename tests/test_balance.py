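"""Balance optimizer: closed forms, oracle agreement, and convexity properties."""

from __future__ import annotations

import numpy as np
import pytest

import stoichbalance as sb

from conftest import CELL, make_chain, make_hub, make_pair, random_tiny_instance

ABS = dict(objective_mode="absolute")


# ---------------------------------------------------------------------------
# Closed-form instances
# ---------------------------------------------------------------------------


def test_pair_unequal_copies_splits_the_difference(pair):
    # minimize (c-100)^2 + (c-1)^2  ->  c = 50.5
    net, table = pair
    sol = sb.balance_network(net, table, CELL, **ABS)
    c = sol.complex_count[(("A", "i1"), ("B", "i1"))]
    assert c == pytest.approx(50.5, rel=1e-3)
    assert sol.balanced_protein_copies["A"] == pytest.approx(50.5, rel=1e-3)
    assert sol.balanced_protein_copies["B"] == pytest.approx(50.5, rel=1e-3)


def test_pair_equal_copies_balances_exactly():
    net, table = make_pair(42.0, 42.0)
    sol = sb.balance_network(net, table, CELL, **ABS)
    c = sol.complex_count[(("A", "i1"), ("B", "i1"))]
    assert c == pytest.approx(42.0, rel=1e-6)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-3)


def test_hub_symmetric_closed_form(hub):
    # minimize (c1+c2-10)^2 + (c1-10)^2 + (c2-10)^2 -> c1 = c2 = 20/3
    net, table = hub
    sol = sb.balance_network(net, table, CELL, **ABS)
    for key in sol.complex_count:
        assert sol.complex_count[key] == pytest.approx(20 / 3, rel=1e-3)
    assert sol.balanced_protein_copies["A"] == pytest.approx(40 / 3, rel=1e-3)


def test_hub_sbr_values(hub):
    net, table = hub
    sol = sb.balance_network(net, table, CELL, **ABS)
    per_mol, _ = sb.sbr(table, sol, CELL)
    assert per_mol["A"] == pytest.approx(np.log10(0.75), abs=1e-3)
    assert per_mol["B"] == pytest.approx(np.log10(1.5), abs=1e-3)
    assert per_mol["C"] == pytest.approx(np.log10(1.5), abs=1e-3)


def test_self_edge_consumes_two_copies():
    net = sb.InteractionNetwork()
    net.add_interaction(sb.Interaction(a=("A", "i1"), b=("A", "i1")))
    table = sb.CopyNumberTable()
    table.set("A", CELL, "observed", 10.0)
    sol = sb.balance_network(net, table, CELL, **ABS)
    c = sol.complex_count[(("A", "i1"), ("A", "i1"))]
    assert c == pytest.approx(5.0, rel=1e-6)
    assert sol.interface_copies[("A", "i1")] == pytest.approx(10.0, rel=1e-6)


def test_precondition_rejects_lipids_and_zero_copy():
    net = sb.InteractionNetwork()
    net.add_molecule(sb.Molecule(name="L", kind="lipid", interfaces=["h"]))
    net.add_interaction(sb.Interaction(a=("L", "h"), b=("B", "i1")))
    table = sb.CopyNumberTable()
    table.set("B", CELL, "observed", 1.0)
    with pytest.raises(sb.ValidationError, match="lipid"):
        sb.build_qp(net, table, CELL)
    net2, table2 = make_pair()
    table2.entries[("B", CELL)] = sb.CopyEntry("zero")
    with pytest.raises(sb.ValidationError, match="zero"):
        sb.build_qp(net2, table2, CELL)


def test_unknown_component_warns():
    net = sb.InteractionNetwork()
    net.add_interaction(sb.Interaction(a=("U1", "i1"), b=("U2", "i1")))
    table = sb.CopyNumberTable()  # no rows: both unknown
    with pytest.warns(UserWarning, match="no observed copies"):
        sb.build_qp(net, table, CELL)


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------


def _compare_solutions(a: sb.BalanceSolution, b: sb.BalanceSolution, rtol: float):
    for ref, xa in a.interface_copies.items():
        xb = b.interface_copies[ref]
        scale = max(abs(xa), abs(xb), 1e-9)
        assert abs(xa - xb) / scale < rtol, (ref, xa, xb)


@pytest.mark.parametrize("mode", ["absolute", "relative"])
def test_oracle_agreement_on_named_instances(mode):
    for net, table in (make_pair(), make_hub()):
        fast = sb.balance_network(net, table, CELL, objective_mode=mode)
        slow = sb.brute_force_balance(net, table, CELL, objective_mode=mode)
        _compare_solutions(fast, slow, 1e-4)


def test_oracle_agreement_random_instances_hundred_seeds():
    """NNLS optimum matches the dense numeric minimizer on tiny instances."""
    worst = 0.0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        net, table = random_tiny_instance(rng)
        fast = sb.balance_network(net, table, CELL, **ABS)
        slow = sb.brute_force_balance(net, table, CELL, seed=seed, **ABS)
        for ref, xa in fast.interface_copies.items():
            xb = slow.interface_copies[ref]
            scale = max(abs(xa), abs(xb), 1e-6)
            worst = max(worst, abs(xa - xb) / scale)
    assert worst < 1e-3, worst


def test_brute_force_refuses_large_instances():
    inst = sb.generate(sb.SynthesisParams(seed=0, n_proteins=20))
    with pytest.raises(sb.ValidationError, match="4 edges"):
        sb.brute_force_balance(inst.network, inst.copies, inst.cell_type)


# ---------------------------------------------------------------------------
# Convexity / solution properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["absolute", "relative"])
def test_conservation_interface_copies_match_incidence(mode):
    """x_i equals the sum of incident complex counts, self-edges doubled."""
    inst = sb.generate(sb.SynthesisParams(seed=9, n_proteins=40, selfbind_fraction=0.3))
    net = sb.filter_network(
        inst.network, inst.copies, inst.cell_type, drop_lipids=True, drop_zero_copy=True
    )
    sol = sb.balance_network(net, inst.copies, inst.cell_type, objective_mode=mode)
    totals: dict = {}
    for (a, b), c in sol.complex_count.items():
        assert c >= 0
        if a == b:
            totals[a] = totals.get(a, 0.0) + 2 * c
        else:
            totals[a] = totals.get(a, 0.0) + c
            totals[b] = totals.get(b, 0.0) + c
    for ref, x in sol.interface_copies.items():
        scale = max(abs(x), 1.0)
        assert abs(totals.get(ref, 0.0) - x) / scale < 1e-8


@pytest.mark.parametrize("factor", [1e-3, 1e3])
@pytest.mark.parametrize("mode", ["absolute", "relative"])
def test_scale_equivariance(mode, factor):
    """Scaling all observed copies by k scales balanced copies by k exactly."""
    inst = sb.generate(sb.SynthesisParams(seed=2, n_proteins=40))
    net = sb.filter_network(
        inst.network, inst.copies, inst.cell_type, drop_lipids=True, drop_zero_copy=True
    )
    base = sb.balance_network(net, inst.copies, inst.cell_type, objective_mode=mode)
    scaled = sb.balance_network(
        net, inst.copies.scaled(factor), inst.cell_type, objective_mode=mode
    )
    for ref, x in base.interface_copies.items():
        y = scaled.interface_copies[ref]
        scale = max(abs(x * factor), abs(y), 1e-12)
        assert abs(y - x * factor) / scale < 1e-6, ref


def test_optimality_against_random_perturbations(hub):
    """The returned optimum beats 1000 random feasible perturbations."""
    net, table = make_hub()
    spec = sb.build_qp(net, table, CELL, objective_mode="absolute")
    sol = sb.solve_balance(spec)
    c_opt = np.array([sol.complex_count[e.key] for e in spec.edges])
    f_opt = sb.qp_objective(spec, c_opt)
    rng = np.random.default_rng(123)
    for _ in range(1000):
        step = rng.normal(scale=rng.uniform(1e-3, 5.0), size=c_opt.shape)
        candidate = np.clip(c_opt + step, 0.0, None)
        assert sb.qp_objective(spec, candidate) >= f_opt - 1e-9 * max(f_opt, 1.0)


@pytest.mark.parametrize("mode", ["absolute", "relative"])
def test_alpha_limit_drives_interface_spread_to_zero(mode):
    """Decreasing alpha shrinks within-protein interface spread monotonically.

    The spread is measured as std of balanced interface copies over the
    protein's observed copies; the raw CV is checked on a non-degenerate
    chain fixture where no interface is pinned at zero.
    """
    inst = sb.generate(sb.SynthesisParams(seed=3, n_proteins=40))
    net = sb.filter_network(
        inst.network, inst.copies, inst.cell_type, drop_lipids=True, drop_zero_copy=True
    )
    alphas = (10.0, 1.0, 0.1, 0.01, 0.001)
    spreads = []
    for alpha in alphas:
        sol = sb.balance_network(
            net, inst.copies, inst.cell_type, alpha=alpha, objective_mode=mode
        )
        by_mol: dict = {}
        for (mol, _), x in sol.interface_copies.items():
            by_mol.setdefault(mol, []).append(x)
        worst = 0.0
        for mol, xs in by_mol.items():
            obs = inst.copies.copies(mol, inst.cell_type)
            if len(xs) < 2 or obs is None:
                continue
            worst = max(worst, float(np.std(xs)) / obs)
        spreads.append(worst)
    assert all(b <= a * (1 + 1e-9) for a, b in zip(spreads, spreads[1:])), spreads
    assert spreads[-1] < 0.05 * spreads[0]


def test_alpha_limit_cv_monotone_on_chain(chain):
    net, table = chain
    cvs = []
    for alpha in (10.0, 1.0, 0.1, 0.01, 0.001):
        sol = sb.balance_network(net, table, CELL, alpha=alpha, objective_mode="absolute")
        cvs.append(float(sb.interface_cv(sol)["A"]))
    assert all(b <= a * (1 + 1e-9) for a, b in zip(cvs, cvs[1:])), cvs
    assert cvs[-1] < 1e-2


@pytest.mark.parametrize("mode", ["absolute", "relative"])
def test_balanced_instance_recovery(mode):
    """Balanced-by-construction instances come back with max |SBR| < 1e-3."""
    inst = sb.generate(sb.SynthesisParams(seed=5, mode="balanced"))
    sol = sb.balance_network(inst.network, inst.copies, inst.cell_type, objective_mode=mode)
    per_mol, _ = sb.sbr(inst.copies, sol, inst.cell_type)
    assert float(per_mol.abs().max()) < 1e-3
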