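"""Junctional shear stress from the tensions of the four neighbour junctions.

A junction shared by cells *a* and *b* carries cortical tension on each
side, theta_a(x) + theta_b(x) = T with T constant along the junction.
Opposing gradients of the two cortical tensions transfer tension from one
side to the other and shear the adhesion complexes; the average shear
stress is the average gradient of cortical tension. Requiring cortical
tensions to be continuous at the two end vertices expresses it through the
four neighbour junction tensions:

    tau = |(T1 + T3) - (T2 + T4)| / (2 L),

where, with *d* the third cell at one end vertex and *c* at the other,
T1 = T(b,d), T2 = T(a,d), T3 = T(a,c), T4 = T(b,c); T1/T3 lie on opposite
cells at opposite ends (diagonal pairing), and L is the junction length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import TissueNetwork

__all__ = [
    "NeighborQuadruple",
    "ShearEstimate",
    "QuadrupleError",
    "vertex_incidence",
    "neighbor_quadruple",
    "compute_shear",
    "shear_table",
]


class QuadrupleError(ValueError):
    """Raised when a junction has no valid neighbour quadruple."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class NeighborQuadruple:
    """Ids of the four neighbour junctions of a central junction.

    Side labels: cells ``a``/``b`` flank the central junction; ``d`` is the
    third cell at the start vertex, ``c`` the third cell at the end vertex.
    """

    junction: int
    t1: int  # between cells (b, d)
    t2: int  # between cells (a, d)
    t3: int  # between cells (a, c)
    t4: int  # between cells (b, c)
    cell_a: int
    cell_b: int
    cell_c: int
    cell_d: int


@dataclass(frozen=True)
class ShearEstimate:
    junction: int
    tau: float  # |(T1+T3)-(T2+T4)| / (2L), tension units per length
    signed: float  # ((T1+T3)-(T2+T4)) / (2L); sign: a-side cortical tension
    # increases from the start to the end vertex when positive
    quadruple: NeighborQuadruple
    tensions: tuple[float, float, float, float]  # (T1, T2, T3, T4)
    length: float


def vertex_incidence(network: TissueNetwork) -> dict[int, list[int]]:
    """Map vertex id -> incident junction ids (precompute for bulk queries)."""
    inc: dict[int, list[int]] = {}
    for j in network.junctions.values():
        for vid in j.vertices:
            if vid is not None:
                inc.setdefault(vid, []).append(j.id)
    return inc


def neighbor_quadruple(
    network: TissueNetwork, junction_id: int, incidence=None
) -> NeighborQuadruple:
    """Identify the four neighbour junctions around a central junction.

    Both end vertices must be three-fold; the central junction must be an
    interior junction with two adjacent cells. Raises
    :class:`QuadrupleError` with a reason code otherwise.
    """
    j = network.junctions[junction_id]
    if len(j.cells) != 2 or j.is_boundary or None in j.vertices:
        raise QuadrupleError("central-junction-not-interior")
    a, b = j.cells
    v0, vL = j.vertices
    if incidence is None:
        incidence = vertex_incidence(network)

    def flank(vid):
        others = [k for k in incidence.get(vid, []) if k != junction_id]
        if len(others) != 2:
            raise QuadrupleError("end-vertex-not-threefold")
        pairs = [set(network.junctions[k].cells) for k in others]
        if any(len(p) != 2 for p in pairs):
            raise QuadrupleError("neighbor-junction-not-interior")
        third = (pairs[0] | pairs[1]) - {a, b}
        if len(third) != 1:
            raise QuadrupleError("no-unique-third-cell")
        (t,) = third
        b_side = a_side = None
        for k, p in zip(others, pairs):
            if p == {b, t}:
                b_side = k
            elif p == {a, t}:
                a_side = k
        if b_side is None or a_side is None:
            raise QuadrupleError("neighbor-cells-inconsistent")
        return t, b_side, a_side

    d, t1, t2 = flank(v0)  # T1 = (b,d), T2 = (a,d)
    c, t4_b, t3_a = flank(vL)  # T3 = (a,c), T4 = (b,c)
    return NeighborQuadruple(
        junction=junction_id,
        t1=t1,
        t2=t2,
        t3=t3_a,
        t4=t4_b,
        cell_a=a,
        cell_b=b,
        cell_c=c,
        cell_d=d,
    )


def compute_shear(
    network: TissueNetwork,
    tensions,
    junction_ids=None,
) -> tuple[dict[int, ShearEstimate], dict[int, str]]:
    """Average shear stress for every eligible junction.

    ``tensions`` maps junction id -> relative tension (an
    ``InferredTensions`` works directly). Junctions whose quadruple cannot
    be built, or with a neighbour lacking a tension, are returned in the
    exclusion map with a reason code — never as a silent zero.
    """
    tmap = getattr(tensions, "tensions", tensions)
    if junction_ids is None:
        junction_ids = sorted(tmap)
    estimates: dict[int, ShearEstimate] = {}
    excluded: dict[int, str] = {}
    incidence = vertex_incidence(network)
    for jid in junction_ids:
        try:
            quad = neighbor_quadruple(network, jid, incidence=incidence)
        except QuadrupleError as err:
            excluded[jid] = err.reason
            continue
        ids = (quad.t1, quad.t2, quad.t3, quad.t4)
        if any(k not in tmap for k in ids):
            excluded[jid] = "neighbor-tension-missing"
            continue
        L = network.junctions[jid].length
        if L <= 0:
            raise ValueError(f"junction {jid} has non-positive length")
        t1, t2, t3, t4 = (tmap[k] for k in ids)
        signed = ((t1 + t3) - (t2 + t4)) / (2.0 * L)
        estimates[jid] = ShearEstimate(
            junction=jid,
            tau=abs(signed),
            signed=signed,
            quadruple=quad,
            tensions=(t1, t2, t3, t4),
            length=L,
        )
    return estimates, excluded


def shear_table(estimates: dict[int, ShearEstimate], excluded: dict[int, str]) -> pd.DataFrame:
    """Flat table of shear estimates and exclusions for CSV export."""
    rows = []
    for jid, e in sorted(estimates.items()):
        rows.append(
            {
                "junction_id": jid,
                "tau": e.tau,
                "t1_id": e.quadruple.t1,
                "t2_id": e.quadruple.t2,
                "t3_id": e.quadruple.t3,
                "t4_id": e.quadruple.t4,
                "t1": e.tensions[0],
                "t2": e.tensions[1],
                "t3": e.tensions[2],
                "t4": e.tensions[3],
                "length": e.length,
                "eligible": True,
                "reason": "",
            }
        )
    for jid, reason in sorted(excluded.items()):
        rows.append(
            {
                "junction_id": jid,
                "tau": float("nan"),
                "t1_id": -1,
                "t2_id": -1,
                "t3_id": -1,
                "t4_id": -1,
                "t1": float("nan"),
                "t2": float("nan"),
                "t3": float("nan"),
                "t4": float("nan"),
                "length": float("nan"),
                "eligible": False,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
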