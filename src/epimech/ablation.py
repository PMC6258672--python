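"""Laser-ablation read-outs: recoil, normalized intensity, shear selection.

The initial recoil velocity of a cut junction's endpoints is the standard
proxy for the tension it carried. Intensities on and around the ablated
junction are normalized by the mean line density of 20+ neighbouring
junctions to suppress embryo-to-embryo variability. The shear-increase
selection identifies, from pre-ablation tensions alone, the junctions
adjacent to a cut whose shear stress must rise: those for which the
ablated junction sits on the weaker diagonal pair of their neighbour
quadruple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import TissueNetwork
from .shear import QuadrupleError, neighbor_quadruple, vertex_incidence
from .synth import AblationEvent

__all__ = [
    "AblationEvent",
    "recoil_velocity",
    "normalized_junction_intensity",
    "select_shear_increase",
    "relative_change",
]

FRAME_TOL_S = 0.5
MIN_NEIGHBORS = 20


def _value_at(times, values, t, tol=FRAME_TOL_S, what="series"):
    times = np.asarray(times, dtype=float)
    k = int(np.argmin(np.abs(times - t)))
    dt = abs(times[k] - t)
    if dt > tol:
        raise ValueError(
            f"no frame of {what} within {tol} s of t={t} (nearest {times[k]})"
        )
    return values[k], dt


def recoil_velocity(event: AblationEvent, window_s: float = 2.0) -> float:
    """Mean separation speed of the cut junction's endpoints after ablation.

    velocity = (d(t0 + window) - d(t0)) / window with d the inter-endpoint
    distance and t0 = 0 the ablation time. Frames are matched to the
    window boundaries within a 0.5 s tolerance.
    """
    va, vb = sorted(event.tracks)
    d = np.linalg.norm(event.tracks[va] - event.tracks[vb], axis=1)
    d0, _ = _value_at(event.times, d, 0.0, what="track")
    d1, _ = _value_at(event.times, d, window_s, what="track")
    return float((d1 - d0) / window_s)


def normalized_junction_intensity(
    event: AblationEvent,
    channel: str,
    time_s: float = 0.0,
    min_neighbors: int = MIN_NEIGHBORS,
) -> float:
    """Ablated-junction line density over the mean of its neighbours.

    "Neighbours" are all other junctions in the field of view; at least
    ``min_neighbors`` (20 by default) are required for a stable
    normalization.
    """
    df = event.densities
    frame = df[df["channel"] == channel]
    if frame.empty:
        raise ValueError(f"no densities recorded for channel {channel!r}")
    times = np.sort(frame["time"].unique())
    t, _ = _value_at(times, times, time_s, what="densities")
    frame = frame[frame["time"] == t]
    abl = frame[frame["junction_id"] == event.junction]["density"]
    if abl.empty:
        raise ValueError("no density recorded for the ablated junction")
    neighbors = frame[frame["junction_id"] != event.junction]["density"]
    if len(neighbors) < min_neighbors:
        raise ValueError(
            f"only {len(neighbors)} neighbouring junctions; need >= {min_neighbors}"
        )
    return float(abl.iloc[0] / neighbors.mean())


def select_shear_increase(
    network: TissueNetwork,
    tensions,
    ablated_junction: int,
) -> tuple[list[int], dict[int, str]]:
    """Junctions adjacent to an ablation whose shear stress must increase.

    For each junction sharing a vertex with the ablated one, the neighbour
    quadruple (T1..T4) is built from pre-ablation tensions. The junction
    is selected iff the ablated junction plays the role of a neighbour on
    the strictly weaker diagonal pair — i.e. (T1 + T3) > (T2 + T4) with
    the ablated junction as T2 or T4, or symmetrically. Removing tension
    from the weaker pair widens the imbalance, so tau rises.

    Returns (selected junction ids, skipped candidates with reasons).
    """
    tmap = getattr(tensions, "tensions", tensions)
    j0 = network.junctions[ablated_junction]
    incidence = vertex_incidence(network)
    candidates = sorted(
        {
            k
            for vid in j0.vertices
            if vid is not None
            for k in incidence.get(vid, [])
            if k != ablated_junction
        }
    )
    selected = []
    skipped: dict[int, str] = {}
    for jid in candidates:
        try:
            quad = neighbor_quadruple(network, jid, incidence=incidence)
        except QuadrupleError as err:
            skipped[jid] = err.reason
            continue
        ids = (quad.t1, quad.t2, quad.t3, quad.t4)
        if ablated_junction not in ids:
            skipped[jid] = "ablated-junction-not-in-quadruple"
            continue
        if any(k not in tmap for k in ids):
            skipped[jid] = "neighbor-tension-missing"
            continue
        s13 = tmap[quad.t1] + tmap[quad.t3]
        s24 = tmap[quad.t2] + tmap[quad.t4]
        on_24 = ablated_junction in (quad.t2, quad.t4)
        if (on_24 and s13 > s24) or (not on_24 and s24 > s13):
            selected.append(jid)
        else:
            skipped[jid] = "ablated-junction-on-dominant-side"
    return selected, skipped


def relative_change(times, values, t0: float, dt: float = 20.0) -> float:
    """(final - initial) / initial over a time window.

    ``relative change = (v(t0 + dt) - v(t0)) / v(t0)``, with both frames
    matched within the 0.5 s tolerance. Raises when the initial value is
    zero.
    """
    values = np.asarray(values, dtype=float)
    v0, _ = _value_at(times, values, t0)
    v1, _ = _value_at(times, values, t0 + dt)
    if v0 == 0:
        raise ValueError("relative change undefined: initial value is zero")
    return float((v1 - v0) / v0)
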