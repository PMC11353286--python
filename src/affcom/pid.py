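"""Partial information decomposition: union information and synergy.

Synergy is defined as the information a set of sources carries about a
target jointly, over and above their union information,

    I_syn({X1..Xn}; Y) = I(X1..n; Y) - I_union({X1..Xn}; Y),

where the union information is the minimum of I*(X1..n; Y) over all joint
distributions Pr* that preserve every pairwise (Xi, Y) marginal of the
original distribution.  The minimization is a convex program over a
polytope; it is solved here by eliminating the equality constraints
(null-space parameterization, so feasibility is exact) and running a
trust-region constrained minimizer from the maximum-entropy feasible start
Pr*(x1..xn, y) = p(y) Π_i p(xi|y).

A brute-force grid oracle over the same polytope certifies the solver on
small problems; it is deliberately independent of the solver path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .distributions import (
    ProbabilityTable,
    entropy,
    marginalize,
    mutual_information,
)

__all__ = [
    "PIDProblem",
    "PIDSummary",
    "SolverError",
    "union_information",
    "synergy",
    "wms_synergy",
    "smax_synergy",
    "union_information_oracle",
]

_LN2 = np.log(2.0)
_EPS = 1e-12


class SolverError(RuntimeError):
    """Union-information solver failed to converge; carries diagnostics."""

    def __init__(self, message, best_value=None, residual=None):
        super().__init__(message)
        self.best_value = best_value
        self.residual = residual


@dataclass(frozen=True)
class PIDProblem:
    """Sources → target decomposition problem on a discrete joint.

    ``sources`` are disjoint groups of variable names (each group is treated
    as one composite source); ``target`` is a further disjoint group.
    """

    joint: ProbabilityTable
    sources: tuple
    target: tuple

    def __post_init__(self):
        sources = tuple(tuple(g) for g in self.sources)
        target = tuple(self.target)
        object.__setattr__(self, "sources", sources)
        object.__setattr__(self, "target", target)
        if len(sources) < 2:
            raise ValueError("need at least two source groups")
        groups = [set(g) for g in sources] + [set(target)]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise ValueError("source/target groups must be pairwise disjoint")
        for g in groups:
            for name in g:
                self.joint.space.index(name)

    # -- dense composite view -----------------------------------------

    def dense(self) -> np.ndarray:
        """Joint over composite sources and target as an (K1,..,Kn,KY) array.

        Composite alphabets are the sorted distinct outcome tuples observed
        per group; the polytope of the union-information program lives on the
        full product grid of these alphabets.
        """
        keep = tuple(n for g in self.sources for n in g) + self.target
        reduced = marginalize(self.joint, keep)
        sizes = [len(g) for g in self.sources] + [len(self.target)]
        # split each outcome tuple into per-group composite states
        splits = np.cumsum(sizes)[:-1]
        groups_states: list = [set() for _ in sizes]
        rows = []
        for outcome, p in reduced.mass.items():
            parts = []
            prev = 0
            for s in np.append(splits, len(outcome)):
                parts.append(tuple(outcome[prev:s]))
                prev = s
            for gs, part in zip(groups_states, parts):
                gs.add(part)
            rows.append((parts, p))
        alphabets = [sorted(gs) for gs in groups_states]
        index = [{s: i for i, s in enumerate(a)} for a in alphabets]
        arr = np.zeros(tuple(len(a) for a in alphabets))
        for parts, p in rows:
            arr[tuple(ix[s] for ix, s in zip(index, parts))] += p
        return arr


@dataclass(frozen=True)
class PIDSummary:
    joint_mi: float
    source_mi: tuple
    union: float
    synergy: float
    wms: float
    smax_synergy: float
    iterations: int
    residual: float


# -- internal geometry of the marginal-preserving polytope --------------


def _marginal_constraints(shape: tuple):
    """Rows of the linear map q ↦ all pairwise (Xi, Y) marginals."""
    nvars = np.prod(shape)
    n_src = len(shape) - 1
    rows = []
    grid = np.indices(shape).reshape(n_src + 1, -1)
    for i in range(n_src):
        for xi in range(shape[i]):
            for y in range(shape[-1]):
                rows.append(((grid[i] == xi) & (grid[-1] == y)).astype(float))
    return np.array(rows).reshape(-1, nvars)


def _polytope_geometry(p: np.ndarray):
    """Reduced coordinates of {q >= 0 : pairwise (Xi,Y) marginals match p}.

    Any outcome whose (xi, y) pairwise marginal is zero for some source is
    forced to zero by nonnegativity; eliminating those coordinates first
    keeps the polytope full-dimensional inside the null space of the
    remaining equality constraints, which both the solver's parameterization
    and the oracle's grid rely on.

    Returns ``(free, q0_free, C_free, b, N)``: indices of free coordinates,
    the max-entropy feasible start restricted to them, the constraint matrix
    and right-hand side on the free coordinates, and a null-space basis.
    """
    n_src = p.ndim - 1
    shape = p.shape
    grid = np.indices(shape).reshape(n_src + 1, -1)
    allowed = np.ones(p.size, dtype=bool)
    for i in range(n_src):
        axes = tuple(k for k in range(n_src) if k != i)
        pair = p.sum(axis=axes)  # (Ki, KY)
        allowed &= pair[grid[i], grid[-1]] > 0
    free = np.flatnonzero(allowed)
    C_full = _marginal_constraints(shape)
    b_full = C_full @ p.ravel()
    keep_rows = b_full > 0
    C = C_full[np.ix_(keep_rows, free)]
    b = b_full[keep_rows]
    N = scipy.linalg.null_space(C)
    q0 = _feasible_start(p).ravel()[free]
    return free, q0, C, b, N


def _scatter(q_free: np.ndarray, free: np.ndarray, shape: tuple) -> np.ndarray:
    q = np.zeros(int(np.prod(shape)))
    q[free] = q_free
    return q.reshape(shape)


def _feasible_start(p: np.ndarray) -> np.ndarray:
    """Max-entropy feasible point: sources conditionally independent given Y."""
    n_src = p.ndim - 1
    py = p.sum(axis=tuple(range(n_src)))
    q = np.ones_like(p)
    for i in range(n_src):
        axes = tuple(k for k in range(n_src) if k != i)
        p_xi_y = p.sum(axis=axes)  # shape (Ki, KY)
        cond = np.divide(p_xi_y, py, out=np.zeros_like(p_xi_y), where=py > 0)
        shape = [1] * (n_src + 1)
        shape[i] = p.shape[i]
        shape[-1] = p.shape[-1]
        q = q * cond.reshape(shape)
    q = q * py.reshape([1] * n_src + [-1])
    return q


def _mi_joint_target(q: np.ndarray) -> float:
    """I(X1..n; Y) of a dense joint, in bits."""
    n_src = q.ndim - 1
    qx = q.sum(axis=-1, keepdims=True)
    qy = q.sum(axis=tuple(range(n_src)), keepdims=True)
    nz = q > _EPS
    ratio = np.ones_like(q)
    denom = (qx * qy)[nz]
    ratio[nz] = q[nz] / np.maximum(denom, _EPS)
    return float((q[nz] * np.log2(ratio[nz])).sum())


def _mi_grad_nats(q: np.ndarray) -> np.ndarray:
    n_src = q.ndim - 1
    qx = q.sum(axis=-1, keepdims=True)
    qy = q.sum(axis=tuple(range(n_src)), keepdims=True)
    qc = np.maximum(q, _EPS)
    return np.log(qc) - np.log(np.maximum(qx, _EPS)) - np.log(np.maximum(qy, _EPS))


def union_information(prob: PIDProblem, tolerance: float = 1e-8):
    """Minimize I*(X1..n;Y) over joints with the original (Xi,Y) marginals.

    On the marginal-preserving polytope p(y) is fixed, so the objective is
    const − H(Y | X1..n), which is convex; the program is solved by a
    log-barrier interior-point Newton method in the null-space
    parameterization q = q0 + N t (feasibility of the equality constraints
    is thus exact by construction), started from the maximum-entropy
    feasible point q0 = p(y) Π p(xi|y), which is strictly positive on the
    reduced coordinates.

    Returns ``(value_bits, diagnostics)`` where diagnostics reports total
    Newton iterations and the final max marginal-constraint residual.
    Raises :class:`SolverError` (carrying the best value found) on
    non-convergence.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    p = prob.dense()
    shape = p.shape
    n_src = p.ndim - 1
    free, q0, C, b, N = _polytope_geometry(p)
    value0 = _mi_joint_target(_scatter(q0, free, shape))
    if N.shape[1] == 0:
        return value0, {"iterations": 0, "residual": 0.0}

    # composite-source index of each free coordinate (Hessian block structure)
    grid = np.indices(shape).reshape(n_src + 1, -1)[:, free]
    xid = np.ravel_multi_index(grid[:n_src], shape[:n_src])
    n_x = int(np.prod(shape[:n_src]))
    same_x = xid[:, None] == xid[None, :]

    def objective_nats(qf):
        # Σ q ln q − Σ_x qX ln qX  ==  −H(Y|X); differs from I by a constant
        qx = np.bincount(xid, weights=qf, minlength=n_x)
        nz = qf > 0
        nzx = qx > 0
        return float(
            (qf[nz] * np.log(qf[nz])).sum() - (qx[nzx] * np.log(qx[nzx])).sum()
        )

    t = np.zeros(N.shape[1])
    total_iters = 0
    mu = 1e-2
    while mu > 1e-11 and total_iters < 10_000:
        for _ in range(60):
            qf = q0 + N @ t
            qx = np.bincount(xid, weights=qf, minlength=n_x)
            grad_full = np.log(qf) - np.log(qx[xid]) - mu / qf
            grad = N.T @ grad_full
            H_full = np.diag(1.0 / qf + mu / qf**2) - same_x / qx[xid][:, None]
            H = N.T @ H_full @ N
            try:
                dt = np.linalg.solve(H + 1e-13 * np.eye(H.shape[0]), -grad)
            except np.linalg.LinAlgError:
                dt = -grad
            decrement = float(-grad @ dt)
            if decrement < 1e-12:
                break
            # step to the boundary, then Armijo backtracking
            nd = N @ dt
            neg = nd < 0
            step = 1.0 if not neg.any() else min(1.0, 0.99 * float((-qf[neg] / nd[neg]).min()))
            f0 = objective_nats(qf) - mu * float(np.log(qf).sum())
            while step > 1e-14:
                q_new = qf + step * nd
                if (q_new > 0).all():
                    f_new = objective_nats(q_new) - mu * float(np.log(q_new).sum())
                    if f_new <= f0 - 1e-4 * step * decrement:
                        break
                step *= 0.5
            if step <= 1e-14:
                break
            t = t + step * dt
            total_iters += 1
        mu *= 0.1

    qf = q0 + N @ t
    q = _scatter(qf, free, shape)
    residual = float(np.abs(C @ qf - b).max())
    value = min(_mi_joint_target(q), value0)
    diagnostics = {"iterations": total_iters, "residual": residual}
    if residual > max(tolerance, 1e-7) or total_iters >= 10_000:
        raise SolverError(
            "union-information solver did not converge",
            best_value=value,
            residual=residual,
        )
    return value, diagnostics


def wms_synergy(prob: PIDProblem) -> float:
    """WholeMinusSum synergy I(X1..n;Y) − Σ_i I(Xi;Y); may be negative."""
    p = prob.dense()
    joint_mi = _mi_joint_target(p)
    return joint_mi - sum(_source_mis(p))


def _source_mis(p: np.ndarray) -> list:
    n_src = p.ndim - 1
    out = []
    for i in range(n_src):
        axes = tuple(k for k in range(n_src) if k != i)
        pair = p.sum(axis=axes)  # (Ki, KY)
        out.append(_mi_joint_target(pair))
    return out


def smax_synergy(prob: PIDProblem) -> float:
    """Smax synergy: joint MI minus the expected best specific information.

    Specific information of source Xi at target state y is
    Σ_x p(x|y) log2[p(x|y)/p(x)]; Smax takes the max over sources per y.
    """
    p = prob.dense()
    n_src = p.ndim - 1
    py = p.sum(axis=tuple(range(n_src)))
    spec = np.zeros((n_src, p.shape[-1]))
    for i in range(n_src):
        axes = tuple(k for k in range(n_src) if k != i)
        pair = p.sum(axis=axes)  # (Ki, KY)
        px = pair.sum(axis=1)
        for y in range(p.shape[-1]):
            if py[y] <= 0:
                continue
            cond = pair[:, y] / py[y]
            nz = cond > 0
            spec[i, y] = float(
                (cond[nz] * np.log2(cond[nz] / np.maximum(px[nz], _EPS))).sum()
            )
    best = spec.max(axis=0)
    return _mi_joint_target(p) - float((py * best).sum())


def synergy(prob: PIDProblem, tolerance: float = 1e-8) -> PIDSummary:
    """Full decomposition summary: joint/source MIs, union, synergy, bounds."""
    p = prob.dense()
    joint_mi = _mi_joint_target(p)
    source_mi = tuple(_source_mis(p))
    union, diag = union_information(prob, tolerance)
    syn = joint_mi - union
    if syn < -1e-6 or syn > joint_mi + 1e-6:
        raise SolverError(
            f"synergy {syn:.3g} outside [0, joint MI] beyond tolerance",
            best_value=syn,
        )
    syn = float(np.clip(syn, 0.0, joint_mi))
    return PIDSummary(
        joint_mi=joint_mi,
        source_mi=source_mi,
        union=joint_mi - syn,
        synergy=syn,
        wms=wms_synergy(prob),
        smax_synergy=smax_synergy(prob),
        iterations=diag["iterations"],
        residual=diag["residual"],
    )


def union_information_oracle(prob: PIDProblem, grid_resolution: int = 25) -> float:
    """Brute-force minimum of I*(X1..n;Y) over the marginal polytope.

    Parameterizes the polytope by its free coordinates (null space of the
    marginal constraints), bounds each coordinate by linear programming, and
    evaluates the objective on a regular grid plus the feasible start.  Only
    intended for tests on small supports.
    """
    p = prob.dense()
    if p.size > 64:
        raise ValueError(f"support of {p.size} outcomes too large for the oracle")
    shape = p.shape
    free, q0, C, b, N = _polytope_geometry(p)
    k = N.shape[1]
    best = _mi_joint_target(_scatter(q0, free, shape))
    if k == 0:
        return best
    bounds = []
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        lo = scipy.optimize.linprog(c, A_ub=-N, b_ub=q0, bounds=[(None, None)] * k)
        hi = scipy.optimize.linprog(-c, A_ub=-N, b_ub=q0, bounds=[(None, None)] * k)
        if not (lo.success and hi.success):
            raise RuntimeError("failed to bound the feasible polytope")
        bounds.append((lo.fun, -hi.fun))
    if grid_resolution**k > 2_000_000:
        raise ValueError("free-coordinate grid too large for the oracle")
    axes = [np.linspace(lo, hi, grid_resolution) for lo, hi in bounds]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    qs = q0[None, :] + mesh @ N.T
    feasible = (qs >= -1e-9).all(axis=1)
    for q in qs[feasible]:
        val = _mi_joint_target(_scatter(np.maximum(q, 0.0), free, shape))
        if val < best:
            best = val
    return best
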