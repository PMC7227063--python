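"""Exact solving of the k-arrangement problem by integer linear programming.

Per arrangement i the model carries binary variables
``y[u,i]`` (orientation of segment u), ``z[{u,v},i]`` (u precedes v; the
reverse order is ``1 - z``, so antisymmetry holds structurally), and
``x[e,i]`` (edge e concordant in arrangement i); one ``q[e]`` per edge
records satisfaction by at least one arrangement.  The objective maximizes
``sum_e w(e) * q[e]`` subject to ``q[e] <= sum_i x[e,i]``.

Concordance is linked to order/orientation by four cap constraints per
edge per arrangement, one pattern per connection type (u is the
genomically earlier segment of the pair):

* tail-head:  x=1 requires z = y_u = y_v
* tail-tail:  x=1 requires z = y_u = 1 - y_v
* head-tail:  x=1 requires z = 1 - y_u = 1 - y_v
* head-head:  x=1 requires z = 1 - y_u = y_v

The caps are one-sided (``x <= ...``); maximization supplies the reverse
implication.  A transitivity band ``0 <= z_uv + z_vw - z_uw <= 1`` per
segment triple makes each z assignment a total order.  The backend is
``scipy.optimize.milp`` (HiGHS); solves honor a wall-clock time limit and
report whether the incumbent is optimal.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .arrangement import (
    Arrangement,
    ArrangementSet,
    DEFAULT_MAX_DISTANCE,
    TSVCall,
    call_tsvs,
    is_concordant,
    reference_arrangement,
)
from .gsg import GSG, TAIL, connected_components

__all__ = [
    "ILPModel",
    "SolveStatus",
    "OPTIMAL",
    "FEASIBLE_TIME_LIMIT",
    "INFEASIBLE_ERROR",
    "build_ilp",
    "solve_ilp",
    "solve_per_component",
]

log = logging.getLogger(__name__)

OPTIMAL = "OPTIMAL"
FEASIBLE_TIME_LIMIT = "FEASIBLE_TIME_LIMIT"
INFEASIBLE_ERROR = "INFEASIBLE_ERROR"


@dataclass(frozen=True)
class SolveStatus:
    state: str
    objective: float
    wall_time: float
    label: str = ""


@dataclass
class ILPModel:
    """Backend-agnostic binary program for a GSG and arrangement count k.

    Rows are triples (coefficient row as {var_index: coef}, lower, upper);
    all variables are binary.  ``objective`` holds maximization
    coefficients (non-zero only on the q variables).
    """

    gsg: GSG
    k: int
    n_vars: int = 0
    x: dict[tuple[int, int], int] = field(default_factory=dict)  # (edge, arr) -> var
    y: dict[tuple[str, int], int] = field(default_factory=dict)  # (segment, arr) -> var
    z: dict[tuple[str, str, int], int] = field(default_factory=dict)  # (u, v, arr), u<v
    q: dict[int, int] = field(default_factory=dict)  # edge -> var
    rows: list[tuple[dict[int, float], float, float]] = field(default_factory=list)
    objective: np.ndarray | None = None
    last_solution: np.ndarray | None = None  # incumbent from the latest solve

    def _new_var(self) -> int:
        v = self.n_vars
        self.n_vars += 1
        return v

    @property
    def n_constraints(self) -> int:
        return len(self.rows)


def _z_term(model: ILPModel, u: str, v: str, i: int) -> tuple[dict[int, float], float]:
    """Affine form of z_uv (u precedes v) as ({var: coef}, constant)."""
    if (u, v, i) in model.z:
        return {model.z[(u, v, i)]: 1.0}, 0.0
    return {model.z[(v, u, i)]: -1.0}, 1.0


def _cap(model: ILPModel, xvar: int, lin_a: dict[int, float], const_a: float,
         lin_b: dict[int, float], const_b: float) -> None:
    """Add the pair of caps x <= A - B + 1 and x <= B - A + 1 enforcing
    x = 1 -> A == B for affine binary forms A, B."""
    for (la, ca), (lb, cb) in (((lin_a, const_a), (lin_b, const_b)),
                               ((lin_b, const_b), (lin_a, const_a))):
        row = {xvar: 1.0}
        for var, coef in la.items():
            row[var] = row.get(var, 0.0) - coef
        for var, coef in lb.items():
            row[var] = row.get(var, 0.0) + coef
        # x <= A - B + 1  <=>  x - lin_a + lin_b <= 1 + const_a - const_b
        model.rows.append((row, -np.inf, 1.0 + ca - cb))


def build_ilp(gsg: GSG, k: int) -> ILPModel:
    """Construct the k-arrangement model for a GSG.

    Per arrangement: 4 caps per edge, one transitivity band per segment
    triple; plus one q-link row per edge (``q <= 1`` lives in the variable
    bounds).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = ILPModel(gsg=gsg, k=k)
    sids = gsg.genomic_order()
    pos = {s: j for j, s in enumerate(sids)}
    for i in range(k):
        for s in sids:
            model.y[(s, i)] = model._new_var()
        for a, b in itertools.combinations(sids, 2):
            model.z[(a, b, i)] = model._new_var()
        for ei in range(gsg.n_edges):
            model.x[(ei, i)] = model._new_var()
    for ei in range(gsg.n_edges):
        model.q[ei] = model._new_var()

    one = ({}, 1.0)

    for ei, e in enumerate(gsg.edges):
        u, v = e.a, e.b
        if pos[u.segment_id] > pos[v.segment_id]:
            u, v = v, u
        us, vs = u.segment_id, v.segment_id
        # target values as affine forms: x=1 -> z = target_z-form etc.
        for i in range(k):
            xv = model.x[(ei, i)]
            zlin, zconst = _z_term(model, us, vs, i)
            yu = ({model.y[(us, i)]: 1.0}, 0.0)
            not_yu = ({model.y[(us, i)]: -1.0}, 1.0)
            yv = ({model.y[(vs, i)]: 1.0}, 0.0)
            not_yv = ({model.y[(vs, i)]: -1.0}, 1.0)
            if u.end == TAIL and v.end != TAIL:      # tail-head: z = y_u = y_v
                t1, t2 = yu, yv
            elif u.end == TAIL and v.end == TAIL:    # tail-tail: z = y_u = 1-y_v
                t1, t2 = yu, not_yv
            elif u.end != TAIL and v.end == TAIL:    # head-tail: z = 1-y_u = 1-y_v
                t1, t2 = not_yu, not_yv
            else:                                     # head-head: z = 1-y_u = y_v
                t1, t2 = not_yu, yv
            _cap(model, xv, zlin, zconst, t1[0], t1[1])
            _cap(model, xv, zlin, zconst, t2[0], t2[1])
        # q_e <= sum_i x_e^i
        row = {model.q[ei]: 1.0}
        for i in range(k):
            row[model.x[(ei, i)]] = -1.0
        model.rows.append((row, -np.inf, 0.0))

    # transitivity: 0 <= z_uv + z_vw - z_uw <= 1 for canonical u < v < w
    for i in range(k):
        for a, b, c in itertools.combinations(sids, 3):
            row: dict[int, float] = {}
            const = 0.0
            for (p, qq), sign in (((a, b), 1.0), ((b, c), 1.0), ((a, c), -1.0)):
                lin, cst = _z_term(model, p, qq, i)
                for var, coef in lin.items():
                    row[var] = row.get(var, 0.0) + sign * coef
                const += sign * cst
            model.rows.append((row, 0.0 - const, 1.0 - const))

    obj = np.zeros(model.n_vars)
    for ei, e in enumerate(gsg.edges):
        obj[model.q[ei]] = e.weight
    model.objective = obj
    return model


def _decode(model: ILPModel, sol: np.ndarray) -> ArrangementSet:
    gsg = model.gsg
    sids = gsg.genomic_order()
    tie = {s: j for j, s in enumerate(sids)}
    arrs = []
    for i in range(model.k):
        # rank of u = number of v placed before u according to z
        before = {s: 0 for s in sids}
        for a, b in itertools.combinations(sids, 2):
            z = sol[model.z[(a, b, i)]] > 0.5
            if z:
                before[b] += 1
            else:
                before[a] += 1
        order = tuple(sorted(sids, key=lambda s: (before[s], tie[s])))
        orient = {s: int(sol[model.y[(s, i)]] > 0.5) for s in sids}
        arrs.append(Arrangement(order, orient))
    return ArrangementSet(arrs)


def solve_ilp(
    model: ILPModel, time_limit: float | None = None
) -> tuple[ArrangementSet, SolveStatus]:
    """Solve a built model and decode the incumbent into arrangements.

    The decoded set always achieves at least the solver's objective: the
    caps let x stay 0 on an edge that the decoded order/orientations in
    fact satisfy, so decoding can only reveal extra concordant weight.
    """
    gsg = model.gsg
    t0 = time.monotonic()
    if gsg.n_segments == 0 or gsg.n_edges == 0:
        ref = reference_arrangement(gsg)
        status = SolveStatus(OPTIMAL, 0.0, time.monotonic() - t0)
        return ArrangementSet([ref] * model.k), status

    n = model.n_vars
    rows_idx, cols, vals, lbs, ubs = [], [], [], [], []
    for r, (row, lb, ub) in enumerate(model.rows):
        for var, coef in row.items():
            rows_idx.append(r)
            cols.append(var)
            vals.append(coef)
        lbs.append(lb)
        ubs.append(ub)
    A = sparse.csr_matrix((vals, (rows_idx, cols)), shape=(len(model.rows), n))
    constraints = LinearConstraint(A, lbs, ubs)
    options: dict = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=-model.objective,
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
        constraints=constraints,
        options=options,
    )
    wall = time.monotonic() - t0
    if res.x is None:
        status = SolveStatus(INFEASIBLE_ERROR, float("nan"), wall)
        log.warning("ILP produced no incumbent (status %s)", res.status)
        return ArrangementSet([reference_arrangement(gsg)] * model.k), status
    state = OPTIMAL if res.status == 0 else FEASIBLE_TIME_LIMIT
    model.last_solution = res.x  # raw incumbent, kept for diagnostics
    decoded = _decode(model, res.x)
    status = SolveStatus(state, float(-res.fun), wall)
    return decoded, status


def solve_per_component(
    gsg: GSG,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    time_limit_per_component: float = 3600.0,
    k: int = 2,
) -> tuple[ArrangementSet, list[TSVCall], list[SolveStatus]]:
    """Exact per-component solving under the k-allele (default diploid)
    assumption, then TSV calling.

    Each connected component is an independent subproblem; the ILP runs on
    every component with its own time limit, incumbents are accepted when
    the limit is hit, and a component with no incumbent falls back to its
    reference arrangement (with a warning).  Component arrangements are
    composed into k global arrangements in genomic order, and TSVs are
    called on the composed set.
    """
    comps = connected_components(gsg)
    orders: list[list[str]] = [[] for _ in range(k)]
    orients: list[dict[str, int]] = [{} for _ in range(k)]
    statuses: list[SolveStatus] = []
    for ci, comp in enumerate(comps):
        label = f"component{ci}({comp.n_segments} segments)"
        if comp.n_edges == 0:
            ref = reference_arrangement(comp)
            arrs = ArrangementSet([ref] * k)
            status = SolveStatus(OPTIMAL, 0.0, 0.0, label)
        else:
            model = build_ilp(comp, k)
            arrs, status = solve_ilp(model, time_limit=time_limit_per_component)
            status = SolveStatus(status.state, status.objective, status.wall_time, label)
            if status.state == INFEASIBLE_ERROR:
                log.warning("%s: no incumbent, falling back to reference", label)
                arrs = ArrangementSet([reference_arrangement(comp)] * k)
        statuses.append(status)
        for i in range(k):
            orders[i].extend(arrs[i].order)
            orients[i].update(arrs[i].orient)
    A = ArrangementSet(
        [Arrangement(tuple(orders[i]), orients[i]) for i in range(k)]
    )
    calls = call_tsvs(gsg, A, max_distance=max_distance)
    return A, calls, statuses
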