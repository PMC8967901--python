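"""Stoichiometric balance optimization (SBOPN).

Balanced copy numbers answer: how many copies of each interface would the
network need so that every interface copy pairs with a partner under
equal-strength competition?  The decision variables are non-negative complex
counts ``c_e``, one per interface-interface edge.  The copy number of an
interface is the sum over complexes it takes part in (a self-edge consumes
two copies per complex).  Two soft constraints shape the solution:

* *consistency* — interfaces of one protein should carry similar copies;
  its weight is ``1/alpha``, so a small alpha forces all interfaces of a
  protein toward equality;
* *target* — a protein's mean interface copies should match its observed
  copies (proteins with unknown copies are not penalized at all).

With a small ridge term to pin down flat directions (cycles in the
interface graph leave complex allocations underdetermined), the objective
is a sum of squared linear forms in ``c >= 0`` — a non-negative linear
least-squares problem, solved exactly by active-set NNLS.

Objective, per protein p with connected interfaces i and mean x̄_p::

    (1/alpha) * w_p * sum_i (x_i - x̄_p)^2        consistency
    + w_p * (x̄_p - C_obs(p))^2                    target (observed p only)
    + r * sum_e c_e^2                              ridge

``w_p = 1`` in absolute mode; ``w_p = 1/C_obs(p)^2`` in relative mode,
where proteins with unknown copies use the geometric-mean abundance of
their connected component as a surrogate weight.  Both modes are exactly
scale equivariant: scaling all observed copies by k scales every balanced
copy by k and leaves every SBR unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.optimize

from .network import CopyNumberTable, Interaction, InteractionNetwork, InterfaceRef, ValidationError

logger = logging.getLogger("stoichbalance")

DEFAULT_ALPHA = 1.0
DEFAULT_RIDGE_EPS = 1e-10
KKT_RTOL = 1e-9


class SolverError(RuntimeError):
    """The NNLS solve failed or violated its optimality conditions."""


@dataclass
class QPSpec:
    """Assembled least-squares system for one balance problem."""

    edges: list[Interaction]
    interfaces: list[InterfaceRef]  # connected interfaces, fixed order
    incidence: np.ndarray  # (n_interfaces, n_edges); self-edges count 2
    A: np.ndarray
    b: np.ndarray
    alpha: float
    ridge_eps: float
    objective_mode: str
    protein_interfaces: dict[str, list[int]]  # molecule -> row indices into interfaces
    observed: dict[str, float]  # molecules with an observed target
    weights: dict[str, float]  # per-protein w_p
    ridge_weights: np.ndarray  # per-edge ridge coefficient

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class BalanceSolution:
    """Optimal complex counts and the copy numbers they imply."""

    complex_count: dict[tuple[InterfaceRef, InterfaceRef], float]
    interface_copies: dict[InterfaceRef, float]
    balanced_protein_copies: dict[str, float]  # mean over connected interfaces
    objective_value: float
    diagnostics: dict = field(default_factory=dict)

    def interface_series(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples(sorted(self.interface_copies), names=["molecule", "interface"])
        return pd.Series([self.interface_copies[k] for k in idx], index=idx, dtype=float)

    def protein_series(self):
        import pandas as pd

        return pd.Series(self.balanced_protein_copies, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# Problem assembly
# ---------------------------------------------------------------------------


def _molecule_components(net: InteractionNetwork) -> list[set[str]]:
    """Connected components of the molecule graph induced by the edges.

    Molecules with no interactions carry no decision variables, so they are
    left out entirely.
    """
    g = nx.Graph()
    for e in net.interactions:
        g.add_edge(e.a[0], e.b[0])
    return [set(c) for c in nx.connected_components(g)]


def build_qp(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
    objective_mode: str = "relative",
) -> QPSpec:
    """Assemble the balance QP for a pre-filtered network.

    The network must already have lipids and zero-copy molecules removed
    (see :func:`stoichbalance.network.filter_network`); violating either
    precondition raises, since both would silently distort the balance.
    """
    if alpha <= 0 or ridge_eps <= 0:
        raise ValidationError("alpha and ridge_eps must be positive")
    if objective_mode not in ("absolute", "relative"):
        raise ValidationError(f"unknown objective mode {objective_mode!r}")
    lipids = [n for n, m in net.molecules.items() if m.kind == "lipid"]
    if lipids:
        raise ValidationError(f"network still contains lipids: {lipids}")
    zeros = [n for n in net.molecules if table.status(n, cell_type) == "zero"]
    if zeros:
        raise ValidationError(f"network still contains zero-copy molecules: {zeros}")

    edges = sorted(net.interactions, key=lambda e: e.key)
    interfaces = sorted(net.connected_interfaces())
    iface_index = {ref: i for i, ref in enumerate(interfaces)}

    incidence = np.zeros((len(interfaces), len(edges)))
    for j, e in enumerate(edges):
        if e.is_self:
            incidence[iface_index[e.a], j] = 2.0
        else:
            incidence[iface_index[e.a], j] += 1.0
            incidence[iface_index[e.b], j] += 1.0

    protein_interfaces: dict[str, list[int]] = {}
    for i, (mol, _) in enumerate(interfaces):
        protein_interfaces.setdefault(mol, []).append(i)

    observed: dict[str, float] = {}
    for name in protein_interfaces:
        c = table.effective_copies(net, name, cell_type)
        if c is not None:
            observed[name] = c

    # per-protein weights and per-edge ridge coefficients.  The ridge is
    # scaled to each connected component's abundance so its (tiny) pull is
    # uniform across components that live decades apart in copy number.
    obs_vals = np.array(sorted(observed.values()), dtype=float)
    global_scale = float(np.exp(np.mean(np.log(obs_vals)))) if obs_vals.size else 1.0
    comp_scale: dict[str, float] = {}
    for comp in _molecule_components(net):
        vals = [observed[n] for n in comp if n in observed]
        if vals:
            scale = float(np.exp(np.mean(np.log(vals))))
        else:
            warnings.warn(
                f"component {sorted(comp)} has no observed copies; "
                "its solution is determined only by the ridge term",
                stacklevel=2,
            )
            scale = global_scale
        for n in comp:
            comp_scale[n] = scale
    weights: dict[str, float] = {}
    if objective_mode == "absolute":
        for name in protein_interfaces:
            weights[name] = 1.0
        ridge_weights = np.full(len(edges), ridge_eps)
    else:
        for name in protein_interfaces:
            base = observed.get(name, comp_scale.get(name, global_scale))
            weights[name] = 1.0 / base**2
        ridge_weights = np.array(
            [ridge_eps / comp_scale.get(e.a[0], global_scale) ** 2 for e in edges]
        )

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for name, idxs in sorted(protein_interfaces.items()):
        n_i = len(idxs)
        w = weights[name]
        mean_row = incidence[idxs].mean(axis=0)
        if n_i > 1:
            coeff = np.sqrt(w / alpha)
            for i in idxs:
                rows.append(coeff * (incidence[i] - mean_row))
                rhs.append(0.0)
        if name in observed:
            coeff = np.sqrt(w)
            rows.append(coeff * mean_row)
            rhs.append(coeff * observed[name])
    # ridge block
    for j in range(len(edges)):
        row = np.zeros(len(edges))
        row[j] = np.sqrt(ridge_weights[j])
        rows.append(row)
        rhs.append(0.0)

    A = np.vstack(rows) if rows else np.zeros((0, len(edges)))
    b = np.asarray(rhs, dtype=float)
    return QPSpec(
        edges=edges,
        interfaces=interfaces,
        incidence=incidence,
        A=A,
        b=b,
        alpha=alpha,
        ridge_eps=ridge_eps,
        objective_mode=objective_mode,
        protein_interfaces=protein_interfaces,
        observed=observed,
        weights=weights,
        ridge_weights=ridge_weights,
    )


def qp_objective(spec: QPSpec, c: np.ndarray) -> float:
    """Objective value at complex counts ``c`` (via the assembled system)."""
    r = spec.A @ c - spec.b
    return float(r @ r)


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


def _solution_from_counts(spec: QPSpec, c: np.ndarray, diagnostics: dict) -> BalanceSolution:
    x = spec.incidence @ c
    interface_copies = {ref: float(x[i]) for i, ref in enumerate(spec.interfaces)}
    protein_copies = {
        name: float(np.mean(x[idxs])) for name, idxs in spec.protein_interfaces.items()
    }
    return BalanceSolution(
        complex_count={e.key: float(c[j]) for j, e in enumerate(spec.edges)},
        interface_copies=interface_copies,
        balanced_protein_copies=protein_copies,
        objective_value=qp_objective(spec, c),
        diagnostics=diagnostics,
    )


def solve_balance(spec: QPSpec) -> BalanceSolution:
    """Solve the balance problem exactly with active-set NNLS.

    The problem is convex, so the optimum is unique in the interface copies
    (the ridge additionally pins down the complex allocation) and no
    randomized initialization is involved.  KKT optimality is verified to a
    relative tolerance of 1e-9; violation raises :class:`SolverError` with
    diagnostics, never a partial solution.
    """
    if spec.n_edges == 0:
        return _solution_from_counts(spec, np.zeros(0), {"iterations": 0, "kkt_violation": 0.0})
    try:
        c, rnorm = scipy.optimize.nnls(spec.A, spec.b)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise SolverError(f"NNLS failed: {exc}") from exc
    grad = spec.A.T @ (spec.A @ c - spec.b)
    scale = max(float(np.abs(spec.A.T @ spec.b).max()), 1.0)
    free = c > 0
    viol = 0.0
    if free.any():
        viol = max(viol, float(np.abs(grad[free]).max()))
    if (~free).any():
        viol = max(viol, float(max(0.0, -grad[~free].min())))
    rel_viol = viol / scale
    diagnostics = {"residual_norm": float(rnorm), "kkt_violation": rel_viol}
    if rel_viol > KKT_RTOL:
        raise SolverError(f"KKT violation {rel_viol:.3e} exceeds {KKT_RTOL}; diagnostics={diagnostics}")
    logger.info(
        "balance solved: %d edges, %d interfaces, objective %.6g, KKT %.2e",
        spec.n_edges,
        len(spec.interfaces),
        qp_objective(spec, c),
        rel_viol,
    )
    return _solution_from_counts(spec, c, diagnostics)


def balance_network(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
    objective_mode: str = "relative",
) -> BalanceSolution:
    """Convenience wrapper: assemble and solve in one call."""
    spec = build_qp(
        net, table, cell_type, alpha=alpha, ridge_eps=ridge_eps, objective_mode=objective_mode
    )
    return solve_balance(spec)


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)
# ---------------------------------------------------------------------------


def _direct_objective(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    edges: list[Interaction],
    c: np.ndarray,
    alpha: float,
    ridge_weights: np.ndarray,
    weights: dict[str, float],
) -> float:
    """Objective evaluated by naive loops, independently of the matrix route."""
    iface_copies: dict[InterfaceRef, float] = {}
    for e, ce in zip(edges, c):
        if e.is_self:
            iface_copies[e.a] = iface_copies.get(e.a, 0.0) + 2.0 * ce
        else:
            iface_copies[e.a] = iface_copies.get(e.a, 0.0) + ce
            iface_copies[e.b] = iface_copies.get(e.b, 0.0) + ce
    by_mol: dict[str, list[float]] = {}
    for (mol, _), x in iface_copies.items():
        by_mol.setdefault(mol, []).append(x)
    total = 0.0
    for mol, xs in by_mol.items():
        w = weights[mol]
        mean = sum(xs) / len(xs)
        total += (w / alpha) * sum((x - mean) ** 2 for x in xs)
        obs = table.effective_copies(net, mol, cell_type)
        if obs is not None:
            total += w * (mean - obs) ** 2
    total += float(np.sum(ridge_weights * np.asarray(c) ** 2))
    return total


def brute_force_balance(
    net: InteractionNetwork,
    table: CopyNumberTable,
    cell_type: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
    objective_mode: str = "relative",
    n_starts: int = 8,
    seed: int = 0,
) -> BalanceSolution:
    """Dense numeric minimization of the same objective — a test oracle.

    Restricted to tiny instances (<= 4 edges); uses multi-start L-BFGS-B on
    the loop-evaluated objective, sharing no linear algebra with
    :func:`solve_balance`.
    """
    if net.n_edges > 4:
        raise ValidationError("brute_force_balance is restricted to <= 4 edges")
    spec = build_qp(
        net, table, cell_type, alpha=alpha, ridge_eps=ridge_eps, objective_mode=objective_mode
    )
    edges = spec.edges
    n = len(edges)
    if n == 0:
        return _solution_from_counts(spec, np.zeros(0), {"oracle": True})
    obs_vals = list(spec.observed.values()) or [1.0]
    hi = max(obs_vals) * 4.0

    def f(c: np.ndarray) -> float:
        return _direct_objective(
            net, table, cell_type, edges, c, spec.alpha, spec.ridge_weights, spec.weights
        )

    rng = np.random.default_rng(seed)
    best_c, best_f = None, np.inf
    starts = [np.full(n, v) for v in (0.0, np.mean(obs_vals))]
    starts += [rng.uniform(0.0, hi, size=n) for _ in range(n_starts)]
    for x0 in starts:
        res = scipy.optimize.minimize(
            f,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 2000},
        )
        if res.fun < best_f:
            best_f, best_c = res.fun, res.x
    return _solution_from_counts(spec, np.asarray(best_c), {"oracle": True, "objective": best_f})
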