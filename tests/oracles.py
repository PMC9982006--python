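"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP path: FBA/FVA values are checked
against exhaustive vertex enumeration of the flux polytope
{v : S v = 0, lb <= v <= ub}, and GPR evaluation against an exhaustive
truth table.
"""

from __future__ import annotations

import itertools

import numpy as np

from gsmm.core import MetabolicModel, build_stoichiometric_matrix


def enumerate_vertices(model: MetabolicModel, tol: float = 1e-9) -> np.ndarray:
    """All vertices of the flux polytope, by active-set enumeration.

    A vertex has n - rank(S) linearly independent active bound constraints;
    we try every choice of free-variable complement and bound assignment.
    Only practical for <= ~10 reactions.
    """
    S = build_stoichiometric_matrix(model).toarray()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    k = n - rank  # number of bounds to pin
    lbs = np.array([r.lower_bound for r in model.reactions.values()])
    ubs = np.array([r.upper_bound for r in model.reactions.values()])
    vertices = []
    for pinned in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in pinned]
        A = S[:, free]
        for choice in itertools.product((0, 1), repeat=k):
            fixed = np.array(
                [lbs[j] if c == 0 else ubs[j] for j, c in zip(pinned, choice)]
            )
            b = -S[:, pinned] @ fixed
            sol, residuals, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            if rk < len(free):
                continue  # underdetermined: not a vertex basis
            if np.linalg.norm(A @ sol - b) > 1e-7:
                continue  # inconsistent
            v = np.empty(n)
            v[list(pinned)] = fixed
            v[free] = sol
            if np.all(v >= lbs - 1e-7) and np.all(v <= ubs + 1e-7):
                vertices.append(np.clip(v, lbs, ubs))
    assert vertices, "polytope has no vertices (model unexpectedly empty)"
    uniq = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-6) for u in uniq):
            uniq.append(v)
    return np.array(uniq)


def brute_force_optimum(model: MetabolicModel, objective_id: str,
                        direction: str = "max") -> float:
    verts = enumerate_vertices(model)
    j = list(model.reactions).index(objective_id)
    vals = verts[:, j]
    return float(vals.max() if direction == "max" else vals.min())


def brute_force_fva(model: MetabolicModel, fraction: float = 1.0,
                    objective_id: str | None = None) -> dict[str, tuple[float, float]]:
    """Flux ranges over the vertices meeting the objective constraint.

    Valid because the extreme points of the face {obj >= f * opt} that the
    LP explores at fraction 1 (equality face) or fraction 0 (whole polytope,
    for non-negative objectives) are extreme points of the polytope itself.
    """
    verts = enumerate_vertices(model)
    rids = list(model.reactions)
    obj = objective_id or model.objective_reaction_id
    j = rids.index(obj)
    opt = verts[:, j].max()
    keep = verts[verts[:, j] >= fraction * opt - 1e-7]
    return {
        rid: (float(keep[:, i].min()), float(keep[:, i].max()))
        for i, rid in enumerate(rids)
    }


def truth_table_gpr(tree, genes: list[str], deleted: set[str]) -> bool:
    """Recursive evaluation written independently of the package's walker."""
    if isinstance(tree, str):
        return tree not in deleted
    op, children = tree
    results = [truth_table_gpr(c, genes, deleted) for c in children]
    return all(results) if op == "and" else any(results)


def floyd_warshall_stats(adjacency: np.ndarray) -> tuple[int, int, float]:
    """(diameter, radius, characteristic path length) of a connected graph."""
    n = adjacency.shape[0]
    dist = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
    assert np.isfinite(dist).all(), "graph not connected"
    ecc = dist.max(axis=1)
    off_diag = dist[~np.eye(n, dtype=bool)]
    return int(ecc.max()), int(ecc.min()), float(off_diag.mean())
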