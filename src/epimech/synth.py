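"""Synthetic force-balanced tissues with known ground truth.

The generator inverts the tension-triangulation duality: it samples seed
points in a square pixel domain, takes their Voronoi diagram as the cell
network and their Delaunay triangulation as the tension network, and
assigns each junction the length of its dual Delaunay edge as its true
tension. Because every Voronoi edge is perpendicular to its Delaunay dual
and the three Delaunay edges of each triangle close exactly, the assigned
tensions satisfy force balance at every interior vertex to machine
precision — an exact equilibrium tissue with known relative tensions.

On top of the geometry the generator emulates the statistical structure of
junctional fluorescence in the germband:

* Myosin-II proportional to tension and planar-polarized towards
  DV-oriented ("vertical") junctions;
* E-cadherin planar-polarized the opposite way (AP-enriched) with an
  additive 1/length density confound;
* Vinculin recruited at a tension-independent baseline proportional to
  E-cadherin plus a load-dependent term proportional to tension.

It can render noisy multichannel z-stacks of those densities (junction
bands, Gaussian PSF, defocused flanking planes, Poisson + read noise) and
simulate quasi-static laser ablations by overdamped relaxation, with an
optional shear-sensitive E-cadherin turnover model. The turnover model is
synthetic: it encodes the hypothesis that shear increases dissociation so
that the analysis pipeline can be exercised against a known direction of
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from skimage.draw import line as draw_line
from skimage.filters import gaussian

from .network import Cell, Junction, TissueNetwork, fold_angle
from .shear import compute_shear

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_equilibrium_network",
    "assign_intensities",
    "render_images",
    "simulate_ablation",
    "modulation_from_pcp",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic tissue, channels, renderer and ablation.

    Lengths are in pixels (``pixel_size`` microns per pixel), intensities
    in arbitrary units, times in seconds.
    """

    n_cells: int = 200
    domain_px: float = 400.0
    seed: int = 0
    pixel_size: float = 0.1  # um/px
    anisotropy: float = 1.0  # >1 stretches the point process along DV
    lloyd_iterations: int = 2  # regularises the tessellation; raw Poisson
    # points produce sub-pixel junctions no real segmentation would carry

    # channel model
    pcp_myosin: float = 2.0  # target DV/AP polarity amplitude of Myosin-II
    pcp_ecad: float = 1.5  # target AP/DV polarity amplitude of E-cadherin
    myo_base: float = 1.0
    ecad_base: float = 1.0
    confound: float = 0.5  # 1/length term, units of ecad_base * mean length
    confound_floor_px: float = 5.0  # length floor for the 1/L term: line
    # densities are ROI means, so junctions shorter than the ROI width
    # cannot concentrate signal without bound
    vinc_alpha: float = 0.3  # constitutive recruitment per unit E-cadherin
    vinc_beta: float = 0.5  # load-dependent recruitment per unit tension
    noise_myo: float = 0.1  # multiplicative, relative
    noise_ecad: float = 0.1  # additive, units of ecad_base
    noise_vinc: float = 0.05  # additive

    # renderer
    image_px: int = 400
    n_planes: int = 8
    focus_plane: int = 2  # apical planes have lower index
    junction_halfwidth_px: int = 3
    psf_sigma_px: float = 1.0
    defocus_sigma_px: float = 2.0  # extra blur per plane away from focus
    defocus_decay: float = 0.45  # intensity decay per plane away from focus
    background_level: float = 0.05
    photon_gain: float = 200.0  # photons per intensity unit; 0 disables
    read_noise: float = 0.01

    # ablation simulator
    gamma: float = 1.0  # drag, tension units * s / px
    dt: float = 0.02
    frame_interval_s: float = 0.25
    k_on: float = 0.05  # E-cad turnover source, a.u./s
    k_off0: float = 0.05  # basal off-rate, 1/s
    shear_sensitivity: float = 20.0  # off-rate gain per unit shear


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed_points: np.ndarray  # (n_cells, 2), cell id = row index
    tensions: dict[int, float]  # junction id -> true tension, mean 1
    densities: dict[str, dict[int, float]] = field(default_factory=dict)
    labels: np.ndarray | None = None
    focus_plane: int | None = None
    released_tension: float | None = None  # set by simulate_ablation


def modulation_from_pcp(amplitude: float) -> float:
    """Convert a target extreme-bin ALD ratio into a sin^2 modulation depth.

    For a channel with density proportional to ``1 + p * sin^2(theta)`` and
    junction angles uniform in [0, 90] degrees, returns the ``p`` for which
    the ratio of bin-averaged densities between the 75--90 and 0--15 degree
    bins equals ``amplitude``.
    """
    if amplitude < 1.0:
        raise ValueError("amplitude must be >= 1 (ratio of larger over smaller)")

    def mean_sin2(a_deg, b_deg):
        a, b = np.radians(a_deg), np.radians(b_deg)
        return 0.5 - (np.sin(2 * b) - np.sin(2 * a)) / (4 * (b - a))

    s_hi = mean_sin2(75, 90)
    s_lo = mean_sin2(0, 15)
    denom = s_hi - amplitude * s_lo
    if denom <= 0:
        raise ValueError(f"amplitude {amplitude} not reachable with sin^2 modulation")
    return (amplitude - 1.0) / denom


def generate_equilibrium_network(
    config: SyntheticConfig,
    points: np.ndarray | None = None,
) -> tuple[TissueNetwork, GroundTruth]:
    """Build an exactly force-balanced Voronoi tissue with known tensions.

    Cells are Voronoi regions of seed points, junctions the Voronoi edges,
    and the true tension of each junction is the length of its dual
    Delaunay edge, normalised to mean 1 over interior junctions. Rays to
    infinity are clipped and flagged as boundary junctions so that every
    retained vertex keeps its three incident junctions.

    ``points`` overrides the random point process (e.g. a triangular
    lattice yields a regular hexagonal tissue with all tensions equal).
    """
    rng = np.random.default_rng(config.seed)
    S = config.domain_px
    if points is not None:
        pts = np.asarray(points, dtype=float)
        if len(pts) < 4:
            raise ValueError("need at least 4 cells for a Voronoi tissue")
    else:
        if config.n_cells < 4:
            raise ValueError("need at least 4 cells for a Voronoi tissue")
        pts = _sample_points(rng, config)
        for _ in range(config.lloyd_iterations):
            pts = _lloyd_step(pts, S)
    for _ in range(5):
        try:
            vor = Voronoi(pts)
            break
        except Exception:  # degenerate (e.g. cocircular) point set
            warnings.warn("degenerate point set; resampling with jitter")
            pts = pts + rng.normal(0, 1e-3 * S, pts.shape)
    else:
        raise ValueError("could not triangulate the sampled points")

    vertices = {i: vor.vertices[i].copy() for i in range(len(vor.vertices))}

    junctions: dict[int, Junction] = {}
    center = pts.mean(axis=0)
    finite = [
        np.linalg.norm(vor.vertices[v1] - vor.vertices[v2])
        for (v1, v2) in vor.ridge_vertices
        if v1 >= 0 and v2 >= 0
    ]
    # clip open rays at a typical edge length: long artificial chords would
    # dominate the inference quadratic form without adding information
    ray_len = 2.0 * float(np.median(finite)) if finite else 0.1 * S
    for k, ((p, q), rv) in enumerate(zip(vor.ridge_points, vor.ridge_vertices)):
        v1, v2 = rv
        if v1 >= 0 and v2 >= 0:
            a, b = vertices[v1], vertices[v2]
            path = np.vstack([a, b])
            length = float(np.linalg.norm(b - a))
            if length == 0:
                continue
            junctions[k] = Junction(
                id=k,
                vertices=(v1, v2),
                path=path,
                cells=(int(p), int(q)),
                length=length,
                angle=fold_angle(b - a, (1.0, 0.0)),
                is_boundary=False,
            )
        else:
            # ray to infinity: clip at a fixed length, keep the open end
            vfin = v2 if v1 < 0 else v1
            base = vertices[vfin]
            t = pts[q] - pts[p]
            n = np.array([-t[1], t[0]])
            n = n / np.linalg.norm(n)
            mid = 0.5 * (pts[p] + pts[q])
            if np.dot(mid - center, n) < 0:
                n = -n
            far = base + n * ray_len
            junctions[k] = Junction(
                id=k,
                vertices=(vfin, None),
                path=np.vstack([base, far]),
                cells=(int(p), int(q)),
                length=float(ray_len),
                angle=fold_angle(far - base, (1.0, 0.0)),
                is_boundary=True,
            )

    cells: dict[int, Cell] = {}
    in_box = lambda v: 0 <= v[0] <= S and 0 <= v[1] <= S
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        jids = sorted(j.id for j in junctions.values() if i in j.cells)
        vids = sorted(
            {v for jid in jids for v in junctions[jid].vertices if v is not None},
            key=lambda v: np.arctan2(*(vertices[v] - pts[i])[::-1]),
        )
        jids.sort(
            key=lambda jid: np.arctan2(
                *(junctions[jid].path.mean(axis=0) - pts[i])[::-1]
            )
        )
        open_cell = (-1 in region) or any(not in_box(vertices[v]) for v in vids)
        cells[i] = Cell(
            id=i,
            junctions=jids,
            vertices=list(vids),
            centroid=pts[i].copy(),
            is_boundary=open_cell,
        )

    # propagate the boundary flag: a junction flanked by a boundary cell is
    # itself boundary (its geometry may extend far outside the domain)
    for j in junctions.values():
        if any(cells[c].is_boundary for c in j.cells):
            j.is_boundary = True

    net = TissueNetwork(
        vertices=vertices,
        junctions=junctions,
        cells=cells,
        pixel_size=config.pixel_size,
    )
    net.validate()

    raw = {
        j.id: float(np.linalg.norm(pts[j.cells[0]] - pts[j.cells[1]]))
        for j in junctions.values()
        if len(j.cells) == 2
    }
    interior = [
        jid
        for jid in raw
        if not junctions[jid].is_boundary
        and not any(cells[c].is_boundary for c in junctions[jid].cells)
    ]
    scale = 1.0 / np.mean([raw[j] for j in interior]) if interior else 1.0
    tensions = {jid: t * scale for jid, t in raw.items()}
    truth = GroundTruth(seed_points=pts, tensions=tensions)
    return net, truth


def perturb_vertices(
    network: TissueNetwork, sigma_frac: float, seed: int
) -> TissueNetwork:
    """Gaussian-jitter every vertex by a fraction of the mean junction length.

    Returns a deep copy with paths, lengths and angles rebuilt from the
    displaced vertices; emulates segmentation noise on an otherwise exact
    tissue.
    """
    interior = [j for j in network.junctions.values() if not j.is_boundary]
    mean_len = float(np.mean([j.length for j in interior or network.junctions.values()]))
    rng = np.random.default_rng(seed)
    net2 = TissueNetwork.from_json(network.to_json())
    for vid in sorted(net2.vertices):
        net2.vertices[vid] = net2.vertices[vid] + rng.normal(
            0, sigma_frac * mean_len, 2
        )
    for j in net2.junctions.values():
        v0, vL = j.vertices
        if v0 is not None:
            j.path[0] = net2.vertices[v0]
        if vL is not None:
            j.path[-1] = net2.vertices[vL]
        j.length = float(np.linalg.norm(np.diff(j.path, axis=0), axis=1).sum())
        chord = j.path[-1] - j.path[0]
        if np.linalg.norm(chord) > 0:
            j.angle = fold_angle(chord, net2.ap_axis)
    return net2


def _lloyd_step(pts: np.ndarray, S: float) -> np.ndarray:
    """One Lloyd iteration: move each point to its clipped cell centroid."""
    from shapely.geometry import Polygon, box

    domain = box(0.0, 0.0, S, S)
    vor = Voronoi(pts)
    out = pts.copy()
    center = pts.mean(axis=0)
    radius = 4 * S
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:
            # close the open region far away before clipping
            verts = _closed_region(vor, i, center, radius)
        else:
            verts = [vor.vertices[v] for v in region]
        if len(verts) < 3:
            continue
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(domain)
        if not clipped.is_empty and clipped.area > 0:
            c = clipped.centroid
            out[i] = (c.x, c.y)
    return out


def _closed_region(vor, i, center, radius):
    """Vertices of an unbounded Voronoi region closed at a large radius."""
    ridges = []
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if i in (p, q):
            ridges.append(((p, q), rv))
    pts2 = []
    for (p, q), (v1, v2) in ridges:
        for v in (v1, v2):
            if v >= 0:
                pts2.append(vor.vertices[v])
            else:
                vfin = v2 if v1 < 0 else v1
                t = vor.points[q] - vor.points[p]
                n = np.array([-t[1], t[0]])
                n /= np.linalg.norm(n)
                mid = 0.5 * (vor.points[p] + vor.points[q])
                if np.dot(mid - center, n) < 0:
                    n = -n
                pts2.append(vor.vertices[vfin] + n * radius)
    pts2 = np.array(pts2)
    c = pts2.mean(axis=0)
    order = np.argsort(np.arctan2(pts2[:, 1] - c[1], pts2[:, 0] - c[0]))
    return [pts2[k] for k in order]


def _sample_points(rng, config):
    S = config.domain_px
    n = config.n_cells
    pts = rng.uniform(0.02 * S, 0.98 * S, size=(n, 2))
    if config.anisotropy != 1.0:
        # compress along x (AP) about the centre: an excess of short
        # AP-spacings creates more DV-oriented ("vertical") short junctions
        cx = pts[:, 0].mean()
        pts[:, 0] = cx + (pts[:, 0] - cx) / config.anisotropy
    return pts


# ---------------------------------------------------------------------------
# channel intensities


def assign_intensities(
    network: TissueNetwork,
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[int, float]]:
    """Per-junction line densities for Myosin-II, E-cadherin and Vinculin.

    myo  = m0 * T * (1 + p_myo sin^2 theta) * (1 + eps)
    ecad = e0 * (1 + p_ecad cos^2 theta) + c <L> / L + eps'
    vinc = alpha * ecad + beta * T + eps''

    All densities are clipped at 0; noise is seeded. The densities are
    stored on ``truth.densities`` and returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    p_myo = modulation_from_pcp(config.pcp_myosin)
    p_ecad = modulation_from_pcp(config.pcp_ecad)
    jids = [j.id for j in network.junctions.values() if j.id in truth.tensions]
    jids.sort()
    interior_lens = [
        network.junctions[j].length for j in jids if not network.junctions[j].is_boundary
    ]
    mean_len = float(np.mean(interior_lens or [network.junctions[j].length for j in jids]))
    myo, ecad, vinc = {}, {}, {}
    for jid in jids:
        j = network.junctions[jid]
        T = truth.tensions[jid]
        th = np.radians(j.angle)
        m = (
            config.myo_base
            * T
            * (1 + p_myo * np.sin(th) ** 2)
            * (1 + rng.normal(0, config.noise_myo))
        )
        e = (
            config.ecad_base * (1 + p_ecad * np.cos(th) ** 2)
            + config.confound
            * config.ecad_base
            * mean_len
            / max(j.length, config.confound_floor_px)
            + rng.normal(0, config.noise_ecad * config.ecad_base)
        )
        v = (
            config.vinc_alpha * e
            + config.vinc_beta * T
            + rng.normal(0, config.noise_vinc)
        )
        myo[jid] = max(m, 0.0)
        ecad[jid] = max(e, 1e-9)
        vinc[jid] = max(v, 0.0)
    truth.densities = {"myosin": myo, "ecadherin": ecad, "vinculin": vinc}
    return truth.densities


# ---------------------------------------------------------------------------
# rendering


def render_labels(network: TissueNetwork, truth: GroundTruth, config: SyntheticConfig):
    """Rasterise the Voronoi cells: label = cell id + 1, 0 on the skeleton."""
    n = config.image_px
    tree = cKDTree(truth.seed_points)
    yy, xx = np.mgrid[0:n, 0:n]
    scale = config.domain_px / n
    pix = np.column_stack([(xx.ravel() + 0.5) * scale, (yy.ravel() + 0.5) * scale])
    _, idx = tree.query(pix)
    labels = (idx + 1).reshape(n, n).astype(np.int32)
    from .network import _skeletonize_boundaries

    return _skeletonize_boundaries(labels)


def render_images(
    network: TissueNetwork,
    densities: dict[int, float],
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one channel as a (Z, H, W) float stack plus the label image.

    Junction paths are painted as bands of the given line density, blurred
    with a Gaussian PSF; planes away from the designated focus plane are
    further defocused and dimmed; basal planes carry a smooth background;
    Poisson shot noise and Gaussian read noise are added (seeded).
    """
    if seed is None:
        seed = config.seed + 2
    rng = np.random.default_rng(seed)
    n = config.image_px
    scale = n / config.domain_px
    base = np.zeros((n, n), dtype=float)
    for jid, d in densities.items():
        j = network.junctions[jid]
        pth = j.path * scale
        for k in range(len(pth) - 1):
            rr, cc = draw_line(
                int(round(pth[k][1])),
                int(round(pth[k][0])),
                int(round(pth[k + 1][1])),
                int(round(pth[k + 1][0])),
            )
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            base[rr[ok], cc[ok]] = np.maximum(base[rr[ok], cc[ok]], d)
    if config.junction_halfwidth_px > 0:
        from scipy.ndimage import grey_dilation

        w = 2 * config.junction_halfwidth_px + 1
        base = grey_dilation(base, size=(w, w))

    stack = np.zeros((config.n_planes, n, n), dtype=float)
    k0 = config.focus_plane
    for z in range(config.n_planes):
        dz = abs(z - k0)
        sigma = config.psf_sigma_px + dz * config.defocus_sigma_px
        img = gaussian(base, sigma=sigma, preserve_range=True) if sigma > 0 else base.copy()
        img *= config.defocus_decay**dz
        img += config.background_level
        stack[z] = img
    if config.photon_gain > 0:
        stack = rng.poisson(stack * config.photon_gain) / config.photon_gain
    if config.read_noise > 0:
        stack = stack + rng.normal(0, config.read_noise, stack.shape)
    stack = np.clip(stack, 0, None)

    labels = render_labels(network, _truth_from(network), config)
    return stack.astype(np.float32), labels


def _truth_from(network):
    # helper for render_images when called without the GroundTruth object:
    # seed points are the cell centroids (exact for Voronoi tissues)
    ids = sorted(network.cells)
    pts = np.array([network.cells[i].centroid for i in ids])
    return GroundTruth(seed_points=pts, tensions={})


def probability_map_from_labels(labels: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Junctional-pixel probability map emulating a pixel classifier.

    The boundary skeleton is thickened to ~3 px (junctional signal is
    wider than one pixel), blurred, and rescaled so ridge centres sit
    near probability 1.
    """
    from scipy.ndimage import binary_dilation

    ridge = binary_dilation(labels == 0, structure=np.ones((3, 3)))
    prob = ridge.astype(float)
    if sigma > 0:
        prob = gaussian(prob, sigma=sigma, preserve_range=True)
        m = prob.max()
        if m > 0:
            prob = prob / m
    return np.clip(prob, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ablation


@dataclass
class AblationEvent:
    """Bundle of tracks and densities produced by one (simulated) ablation."""

    junction: int
    times: np.ndarray  # (F,), seconds; 0 = ablation
    tracks: dict[int, np.ndarray]  # endpoint vertex id -> (F, 2) positions
    densities: "object"  # pandas DataFrame: time, junction_id, channel, density
    network: TissueNetwork  # pre-ablation
    tensions: dict[int, float]  # pre-ablation (ground truth or inferred)
    released_tension: float | None = None


def simulate_ablation(
    network: TissueNetwork,
    truth: GroundTruth,
    junction_id: int,
    config: SyntheticConfig,
    duration_s: float = 20.0,
    turnover: bool = True,
) -> AblationEvent:
    """Overdamped relaxation after setting one junction's tension to zero.

    Vertices move with velocity F / gamma, where F is the vector sum of the
    remaining junctional tensions pulling on the vertex along the current
    chords (quasi-static force balance holds before the cut, so the initial
    net force on each cut endpoint is the released tension). Optionally
    integrates a shear-sensitive E-cadherin turnover model
    ``dE/dt = k_on - k_off0 (1 + s * tau) E`` on every junction, with tau
    recomputed from the neighbour quadruples at each step.
    """
    import pandas as pd

    j0 = network.junctions[junction_id]
    if j0.is_boundary or None in j0.vertices:
        raise ValueError("can only ablate an interior junction")
    if config.gamma <= 0:
        raise ValueError("drag gamma must be positive")

    vids = sorted(network.vertices)
    vidx = {v: k for k, v in enumerate(vids)}
    pos = np.array([network.vertices[v] for v in vids], dtype=float)

    edges = []  # (i_idx, j_idx, tension) for junctions with both ends closed
    for j in network.junctions.values():
        if None in j.vertices or j.id not in truth.tensions:
            continue
        t = 0.0 if j.id == junction_id else truth.tensions[j.id]
        edges.append((vidx[j.vertices[0]], vidx[j.vertices[1]], t))
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    et = np.array([e[2] for e in edges])

    # E-cadherin turnover state. When the generator assigned densities, the
    # per-junction source term is chosen so that each junction is exactly
    # stationary at its pre-ablation shear: changes after the cut are then
    # driven only by changes in shear. Otherwise a uniform source k_on is
    # used and densities relax towards k_on / (k_off0 (1 + s tau)).
    pre_tensions = dict(truth.tensions)
    pre_taus = _current_shear(network, pre_tensions)
    if truth.densities.get("ecadherin"):
        E = dict(truth.densities["ecadherin"])
        k_on_j = {
            jid: config.k_off0
            * (1 + config.shear_sensitivity * pre_taus.get(jid, 0.0))
            * e0
            for jid, e0 in E.items()
        }
    else:
        E = {j.id: config.k_on / config.k_off0 for j in network.junctions.values()}
        k_on_j = {jid: config.k_on for jid in E}

    n_frames = int(round(duration_s / config.frame_interval_s)) + 1
    steps_per_frame = max(int(round(config.frame_interval_s / config.dt)), 1)
    dt = config.frame_interval_s / steps_per_frame

    v0, vL = j0.vertices
    times = np.zeros(n_frames)
    tracks = {v0: np.zeros((n_frames, 2)), vL: np.zeros((n_frames, 2))}
    rows = []
    post_tensions = {
        jid: (0.0 if jid == junction_id else t) for jid, t in truth.tensions.items()
    }

    geom = _GeometryView(network, vids, pos)
    for f in range(n_frames):
        times[f] = f * config.frame_interval_s
        tracks[v0][f] = pos[vidx[v0]]
        tracks[vL][f] = pos[vidx[vL]]
        for jid, e_val in E.items():
            rows.append(
                {
                    "time": times[f],
                    "junction_id": jid,
                    "channel": "ecadherin",
                    "density": e_val,
                }
            )
        if f == n_frames - 1:
            break
        for _ in range(steps_per_frame):
            d = pos[ej] - pos[ei]
            nrm = np.linalg.norm(d, axis=1)
            nrm[nrm == 0] = 1.0
            u = d / nrm[:, None]
            force = np.zeros_like(pos)
            np.add.at(force, ei, et[:, None] * u)
            np.add.at(force, ej, -et[:, None] * u)
            pos = pos + (dt / config.gamma) * force
        if turnover:
            geom.update(pos)
            taus = _current_shear(geom.network, post_tensions)
            for jid in E:
                tau = taus.get(jid, 0.0)
                koff = config.k_off0 * (1 + config.shear_sensitivity * tau)
                # exact update of the linear ODE over one frame: stable for
                # any off-rate (shear diverges when a junction collapses)
                decay = np.exp(-koff * config.frame_interval_s)
                E[jid] = E[jid] * decay + (k_on_j[jid] / koff) * (1 - decay)

    truth.released_tension = truth.tensions.get(junction_id)
    return AblationEvent(
        junction=junction_id,
        times=times,
        tracks=tracks,
        densities=pd.DataFrame(rows),
        network=network,
        tensions=dict(truth.tensions),
        released_tension=truth.released_tension,
    )


def _current_shear(network, tensions):
    estimates, _ = compute_shear(network, tensions)
    return {jid: e.tau for jid, e in estimates.items()}


class _GeometryView:
    """Mutable copy of a network whose vertex positions track a simulation."""

    def __init__(self, network: TissueNetwork, vids, pos):
        self.vids = vids
        self.vidx = {v: k for k, v in enumerate(vids)}
        self.network = TissueNetwork(
            vertices={v: pos[self.vidx[v]].copy() for v in vids},
            junctions={
                j.id: replace(j, path=j.path.copy()) for j in network.junctions.values()
            },
            cells=network.cells,
            pixel_size=network.pixel_size,
            ap_axis=network.ap_axis.copy(),
        )
        self.update(pos)

    def update(self, pos):
        net = self.network
        for v in self.vids:
            net.vertices[v][:] = pos[self.vidx[v]]
        for j in net.junctions.values():
            v0, vL = j.vertices
            if v0 is not None:
                j.path[0] = net.vertices[v0]
            if vL is not None:
                j.path[-1] = net.vertices[vL]
            j.length = max(
                float(np.linalg.norm(np.diff(j.path, axis=0), axis=1).sum()), 1e-9
            )
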