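"""Variational mechanical inference of relative junctional tensions.

At mechanical equilibrium a planar cell network with three-fold vertices
admits a dual *tension triangulation*: one node Q per cell, one dual edge
per interior junction, with each dual edge perpendicular to its junction
and its length equal to the junctional tension. Force balance at every
vertex is then equivalent to the closure of the dual triangles.

The inference fits such a triangulation to an observed (generally noisy)
network by minimising

    Omega = 1/2 sum_<a,b> [(Q_a - Q_b) . r_ij]^2
            - Lambda/2 sum_<a,b> |Q_a - Q_b|^2,

where r_ij is the chord vector of the junction shared by cells a and b and
Lambda is the Lagrange multiplier fixing the overall tension scale.
Stationarity is the generalised eigenproblem A q = Lambda B q over the
stacked Q coordinates; the minimiser is the eigenvector of the smallest
eigenvalue after deflating the two global-translation null modes.
Tensions T_ab = |Q_a - Q_b| are reported rescaled to mean 1. Pressure is
assumed uniform (junction curvature negligible) and does not enter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .network import TissueNetwork

__all__ = [
    "DualTopology",
    "InferredTensions",
    "InferenceError",
    "build_dual_topology",
    "infer_tensions",
    "force_balance_residual",
]

EIGEN_GAP_WARN = 1e-6


class InferenceError(ValueError):
    pass


@dataclass
class DualTopology:
    """Topology of the tension triangulation dual to a cell network."""

    cell_index: dict[int, int]  # cell id -> Q-node index
    dual_edges: list[tuple[int, int, int]]  # (junction id, cell a, cell b)
    triangles: list[tuple[int, int, int, int]]  # (vertex id, cell a, b, c)

    @property
    def n_nodes(self) -> int:
        return len(self.cell_index)


@dataclass
class InferredTensions:
    """Per-junction relative tensions with normalisation metadata."""

    tensions: dict[int, float]  # junction id -> T >= 0, mean 1
    lambda_: float  # Lagrange-multiplier eigenvalue
    q_positions: dict[int, np.ndarray]  # cell id -> Q (2,)
    normalization: float  # factor applied to raw |dQ| values
    excluded: dict[int, str] = field(default_factory=dict)
    n_components: int = 1
    eigen_gap: float = np.inf

    def __getitem__(self, junction_id: int) -> float:
        return self.tensions[junction_id]

    def __contains__(self, junction_id: int) -> bool:
        return junction_id in self.tensions


def _inference_cells(network: TissueNetwork) -> set[int]:
    """Cells usable for inference: interior (not touching the frame)."""
    return {c.id for c in network.cells.values() if not c.is_boundary}


def build_dual_topology(network: TissueNetwork) -> DualTopology:
    """Enumerate Q-nodes, dual edges and dual triangles of a restricted network.

    One Q-node per retained interior cell; one dual edge per junction whose
    two cells are both retained; one triangle per three-fold vertex whose
    three incident cells are all retained.
    """
    cells = sorted(_inference_cells(network))
    cell_index = {cid: k for k, cid in enumerate(cells)}
    dual_edges = []
    for j in sorted(network.junctions.values(), key=lambda j: j.id):
        if len(j.cells) == 2 and all(c in cell_index for c in j.cells):
            a, b = j.cells
            dual_edges.append((j.id, a, b))
    if not dual_edges:
        raise InferenceError("no interior junction between retained cells")

    # triangles: vertices where exactly three retained junctions meet
    vertex_cells: dict[int, set[int]] = {}
    for jid, a, b in dual_edges:
        for vid in network.junctions[jid].vertices:
            if vid is not None:
                vertex_cells.setdefault(vid, set()).update((a, b))
    triangles = [
        (vid, *sorted(cs))
        for vid, cs in sorted(vertex_cells.items())
        if len(cs) == 3
    ]
    return DualTopology(cell_index=cell_index, dual_edges=dual_edges, triangles=triangles)


def infer_tensions(network: TissueNetwork) -> InferredTensions:
    """Infer relative junctional tensions on a three-fold-restricted network.

    The triangulation is fitted over *all* cells and every two-cell
    junction (boundary ones included): peripheral Q-nodes with too few
    constraints would otherwise host spurious near-null modes of the
    energy that swamp the physical solution on noisy networks. Tensions
    are *reported* only for interior junctions (two non-boundary cells),
    rescaled so that their mean is exactly 1; all other junctions are
    listed in ``excluded`` with a reason. If the dual graph is
    disconnected each component is solved and normalised independently
    (with a warning), since relative tensions do not compare across
    components.
    """
    fit_edges = [
        (j.id, *j.cells)
        for j in sorted(network.junctions.values(), key=lambda j: j.id)
        if len(j.cells) == 2 and np.linalg.norm(j.chord) > 0
    ]
    if not fit_edges:
        raise InferenceError("no two-cell junction to fit")
    reportable = set(_reportable_junctions(network))

    # connected components of the dual graph
    import networkx as nx

    g = nx.Graph()
    for jid, a, b in fit_edges:
        g.add_edge(a, b, junction=jid)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps = [c for c in comps if len(c) >= 2]
    if not comps:
        raise InferenceError("dual graph has no edges")
    if len(comps) > 1:
        warnings.warn(
            f"dual graph disconnected into {len(comps)} components; "
            "tensions normalised per component"
        )

    tensions: dict[int, float] = {}
    q_positions: dict[int, np.ndarray] = {}
    lambdas = []
    gaps = []
    norm_applied = 1.0
    for comp in comps:
        comp_set = set(comp)
        edges = [e for e in fit_edges if e[1] in comp_set]
        report = reportable & {e[0] for e in edges}
        if not report:
            continue
        lam, gap, qs, ts, scale = _solve_component(network, comp, edges, report)
        lambdas.append(lam)
        gaps.append(gap)
        norm_applied = scale
        q_positions.update(qs)
        tensions.update(ts)
    if not tensions:
        raise InferenceError("no interior junction to report a tension for")

    excluded = dict(network.excluded)
    for j in network.junctions.values():
        if j.id in tensions:
            continue
        if j.id in excluded:
            continue
        if len(j.cells) < 2 or j.is_boundary:
            excluded[j.id] = "boundary-junction"
        elif any(network.cells[c].is_boundary for c in j.cells):
            excluded[j.id] = "adjacent-to-boundary-cell"
        else:
            excluded[j.id] = "outside-connected-dual-component"

    return InferredTensions(
        tensions=tensions,
        lambda_=float(lambdas[0]),
        q_positions=q_positions,
        normalization=norm_applied,
        excluded=excluded,
        n_components=len(comps),
        eigen_gap=float(min(gaps)),
    )


def _reportable_junctions(network):
    return [
        j.id
        for j in network.junctions.values()
        if len(j.cells) == 2
        and not j.is_boundary
        and None not in j.vertices
        and not any(network.cells[c].is_boundary for c in j.cells)
    ]


def _solve_component(network, comp, edges, report):
    idx = {cid: k for k, cid in enumerate(comp)}
    n = len(comp)
    A = np.zeros((2 * n, 2 * n))
    B = np.zeros((2 * n, 2 * n))
    I2 = np.eye(2)
    # normalise the chord scale: pure conditioning, the eigenvectors (and
    # hence normalised tensions) are scale-free
    chord_scale = np.mean(
        [np.linalg.norm(network.junctions[jid].chord) for jid, _, _ in edges]
    )
    for jid, a, b in edges:
        r = network.junctions[jid].chord / chord_scale
        K = np.outer(r, r)
        ia, ib = idx[a], idx[b]
        for M, k in ((A, K), (B, I2)):
            M[2 * ia : 2 * ia + 2, 2 * ia : 2 * ia + 2] += k
            M[2 * ib : 2 * ib + 2, 2 * ib : 2 * ib + 2] += k
            M[2 * ia : 2 * ia + 2, 2 * ib : 2 * ib + 2] -= k
            M[2 * ib : 2 * ib + 2, 2 * ia : 2 * ia + 2] -= k

    # deflate the two rigid-translation null modes of both forms
    T = np.zeros((2 * n, 2))
    T[0::2, 0] = 1.0
    T[1::2, 1] = 1.0
    P = linalg.null_space(T.T)  # (2n, 2n-2), orthonormal
    Ap = P.T @ A @ P
    Bp = P.T @ B @ P
    w, V = linalg.eigh(Ap, Bp)
    v0 = V[:, 0]
    # polish with shifted inverse iteration: the eigen-gap is generically
    # large, so two steps reach the accuracy of the linear solver
    shift = max(w[0], 0.0) + 1e-12 * max(abs(w).max(), 1.0)
    try:
        M = Ap - (w[0] - shift) * Bp
        for _ in range(2):
            v0 = linalg.solve(M, Bp @ v0, assume_a="sym")
            v0 /= np.sqrt(v0 @ Bp @ v0)
    except linalg.LinAlgError:
        v0 = V[:, 0]
    V[:, 0] = v0
    w[0] = (v0 @ Ap @ v0) / (v0 @ Bp @ v0)
    lam = w[0] * chord_scale**2  # report in the network's own length units
    gap = (w[1] - w[0]) / max(abs(w[1]), np.finfo(float).eps) if len(w) > 1 else np.inf
    if gap < EIGEN_GAP_WARN:
        warnings.warn(
            f"near-degenerate tension spectrum (relative eigen-gap {gap:.2e})"
        )
    q = (P @ V[:, 0]).reshape(n, 2)

    raw = {}
    for jid, a, b in edges:
        if jid in report:
            raw[jid] = float(np.linalg.norm(q[idx[a]] - q[idx[b]]))
    mean_raw = np.mean(list(raw.values()))
    if mean_raw == 0:
        raise InferenceError("degenerate solution: all dual edges collapsed")
    scale = 1.0 / mean_raw
    tensions = {jid: t * scale for jid, t in raw.items()}
    qs = {cid: q[idx[cid]] * scale for cid in comp}
    return lam, gap, qs, tensions, scale


def force_balance_residual(
    network: TissueNetwork, tensions
) -> tuple[dict[int, float], float, int]:
    """Net force magnitude at each vertex under the given tensions.

    For every vertex whose incident junctions all carry a tension, computes
    ``| sum_j T_j u_jv |`` with ``u_jv`` the unit chord pointing away from
    the vertex. Returns (per-vertex residuals, median residual, number of
    vertices skipped because a tension was missing).

    ``tensions`` may be an :class:`InferredTensions` or a plain mapping
    junction id -> tension.
    """
    tmap = tensions.tensions if isinstance(tensions, InferredTensions) else tensions
    incident: dict[int, list[int]] = {}
    for j in network.junctions.values():
        for vid in j.vertices:
            if vid is not None:
                incident.setdefault(vid, []).append(j.id)

    residuals: dict[int, float] = {}
    skipped = 0
    for vid, jids in incident.items():
        if not all(jid in tmap for jid in jids):
            skipped += 1
            continue
        f = np.zeros(2)
        for jid in jids:
            j = network.junctions[jid]
            if j.vertices[0] == vid:
                away = j.path[-1] - j.path[0]
            else:
                away = j.path[0] - j.path[-1]
            nrm = np.linalg.norm(away)
            if nrm == 0:
                continue
            f += tmap[jid] * away / nrm
        residuals[vid] = float(np.linalg.norm(f))
    if not residuals:
        return residuals, float("nan"), skipped
    return residuals, float(np.median(list(residuals.values()))), skipped
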