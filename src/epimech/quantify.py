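"""Fluorescence quantification: densities, planar polarity, pixel ratios.

Measurements follow the line-density convention: the signal of a junction
is the mean pixel intensity over a ~5-px-wide junctional ROI that excludes
the tri-cellular vertices, and the medial signal of a cell is the mean
over its interior kept clear of any junctional ROI. Planar polarity is
quantified by averaging junction line densities in six 15-degree angle
bins (0--15 ... 75--90 degrees from the AP axis); the ratio of the two
extreme bins is the planar-cell-polarity (PCP) amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.filters import sobel
from skimage.morphology import disk

from .network import TissueNetwork

__all__ = [
    "RoiMap",
    "ChannelDensities",
    "PolarityProfile",
    "PixelRatioProfile",
    "preprocess_stack",
    "extract_rois",
    "roi_density",
    "polarity_profile",
    "pixel_ratio_profile",
    "vinc_ecad_ratio",
]

ANGLE_BINS = [(0, 15), (15, 30), (30, 45), (45, 60), (60, 75), (75, 90)]


# ---------------------------------------------------------------------------
# z-stack preprocessing


def preprocess_stack(
    zstack: np.ndarray,
    tile_px: int = 64,
    background_radius: int = 50,
    basal_direction: int = +1,
    return_focus: bool = False,
):
    """Background-subtracted projection of a z-stack.

    The *signal image* is the maximum-intensity projection of the
    best-focus plane plus the two planes basal to it; the focus plane is
    the one maximising the median per-tile Sobel gradient energy. The
    *background image* is the maximum projection of the three basal-most
    planes passed through a median filter of the given radius. The result
    is ``clip(signal - background, 0)``.

    ``basal_direction`` is +1 when increasing plane index means more basal.
    """
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("z-stack must be 3-D (planes, rows, cols)")
    nz = stack.shape[0]
    if nz < 3:
        raise ValueError("need at least 3 z-planes")

    scores = np.array([_focus_score(stack[z], tile_px) for z in range(nz)])
    k = int(np.argmax(scores))
    sel = [z for z in (k, k + basal_direction, k + 2 * basal_direction) if 0 <= z < nz]
    signal = stack[sel].max(axis=0)

    basal = stack[-3:] if basal_direction > 0 else stack[:3]
    background = basal.max(axis=0)
    if background_radius > 0:
        background = ndimage.median_filter(
            background, footprint=disk(background_radius)
        )
    out = np.clip(signal - background, 0, None)
    if return_focus:
        return out, k
    return out


def _focus_score(img: np.ndarray, tile_px: int) -> float:
    """Median over tiles of the mean squared Sobel gradient."""
    g = sobel(img) ** 2
    H, W = g.shape
    tiles = []
    for r in range(0, H, tile_px):
        for c in range(0, W, tile_px):
            tiles.append(g[r : r + tile_px, c : c + tile_px].mean())
    return float(np.median(tiles))


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class RoiMap:
    """Junctional and medial ROI label images (pairwise disjoint)."""

    junction_labels: np.ndarray  # junction id + 1 per pixel, 0 elsewhere
    medial_labels: np.ndarray  # cell id + 1 per pixel, 0 elsewhere
    junction_ids: list[int]
    cell_ids: list[int]
    empty_junctions: list[int] = field(default_factory=list)
    empty_medials: list[int] = field(default_factory=list)


def extract_rois(
    network: TissueNetwork,
    shape: tuple[int, int],
    junction_width_px: int = 5,
    medial_margin_px: int = 2,
    vertex_radius_px: int = 3,
    labels: np.ndarray | None = None,
) -> RoiMap:
    """Build junctional and medial ROIs for a network registered to an image.

    Junctional ROIs dilate each junction path to the requested width and
    remove disks around the tri-cellular vertices; medial ROIs are the cell
    interiors (from ``labels`` if given, else the filled vertex polygon)
    kept at least ``medial_margin_px`` away from any junctional ROI or
    vertex disk. Junctions whose ROI is fully covered by the vertex
    exclusion, and cells too small to keep a medial ROI, are flagged.
    """
    H, W = shape
    jun_lab = np.zeros((H, W), dtype=np.int32)
    half = max(junction_width_px // 2, 0)
    selem = disk(half) if half > 0 else None

    vertex_mask = np.zeros((H, W), dtype=bool)
    for p in network.vertices.values():
        rr, cc = draw_disk((p[1], p[0]), vertex_radius_px, shape=(H, W))
        vertex_mask[rr, cc] = True

    empty_junctions = []
    junction_ids = sorted(network.junctions)
    for jid in junction_ids:
        j = network.junctions[jid]
        m = np.zeros((H, W), dtype=bool)
        pth = np.asarray(j.path)
        for k in range(len(pth) - 1):
            rr, cc = draw_line(
                int(round(pth[k][1])),
                int(round(pth[k][0])),
                int(round(pth[k + 1][1])),
                int(round(pth[k + 1][0])),
            )
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            m[rr[ok], cc[ok]] = True
        if selem is not None:
            m = ndimage.binary_dilation(m, structure=selem)
        m &= ~vertex_mask
        m &= jun_lab == 0  # first junction claims contested pixels
        if not m.any():
            empty_junctions.append(jid)
            continue
        jun_lab[m] = jid + 1

    keep_out = ndimage.binary_dilation(
        (jun_lab > 0) | vertex_mask, structure=disk(max(medial_margin_px, 1))
    )
    med_lab = np.zeros((H, W), dtype=np.int32)
    empty_medials = []
    cell_ids = sorted(network.cells)
    for cid in cell_ids:
        cell = network.cells[cid]
        if labels is not None:
            # synthetic label images use cell id + 1 (0 = skeleton); image-
            # derived networks use the label value itself as the cell id
            offset = 1 if 0 in network.cells else 0
            m = labels == cid + offset
        else:
            vids = cell.vertices
            if len(vids) < 3:
                empty_medials.append(cid)
                continue
            poly = np.array([network.vertices[v] for v in vids])
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
            m = np.zeros((H, W), dtype=bool)
            m[rr, cc] = True
        m = m & ~keep_out & (jun_lab == 0)
        if not m.any():
            empty_medials.append(cid)
            continue
        med_lab[m] = cid + 1
    return RoiMap(
        junction_labels=jun_lab,
        medial_labels=med_lab,
        junction_ids=junction_ids,
        cell_ids=cell_ids,
        empty_junctions=empty_junctions,
        empty_medials=empty_medials,
    )


@dataclass
class ChannelDensities:
    """Per-junction line densities and per-cell medial area densities."""

    junction_density: dict[int, float]  # NaN for empty ROIs
    medial_density: dict[int, float]
    empty_junctions: list[int]
    empty_medials: list[int]


def roi_density(image: np.ndarray, rois: RoiMap) -> ChannelDensities:
    """Mean pixel intensity per junctional and medial ROI."""
    img = np.asarray(image, dtype=float)
    if img.shape != rois.junction_labels.shape:
        raise ValueError("image and ROI map shapes differ")

    def means(lab, ids):
        out = {}
        flat = lab.ravel()
        vals = img.ravel()
        sums = np.bincount(flat, weights=vals, minlength=lab.max() + 2)
        counts = np.bincount(flat, minlength=lab.max() + 2)
        for i in ids:
            if i + 1 < len(counts) and counts[i + 1] > 0:
                out[i] = float(sums[i + 1] / counts[i + 1])
            else:
                out[i] = float("nan")
        return out

    return ChannelDensities(
        junction_density=means(rois.junction_labels, rois.junction_ids),
        medial_density=means(rois.medial_labels, rois.cell_ids),
        empty_junctions=list(rois.empty_junctions),
        empty_medials=list(rois.empty_medials),
    )


def vinc_ecad_ratio(
    vinc: dict[int, float], ecad: dict[int, float]
) -> dict[int, float]:
    """Per-junction Vinculin / E-cadherin ratio of line densities.

    Computed as ratio-of-means (each density is already a ROI mean);
    junctions without a positive E-cadherin density are omitted.
    """
    out = {}
    for jid, e in ecad.items():
        v = vinc.get(jid)
        if v is None or not np.isfinite(v) or not np.isfinite(e) or e <= 0:
            continue
        out[jid] = v / e
    return out


# ---------------------------------------------------------------------------
# planar polarity


@dataclass
class PolarityProfile:
    """Angle-binned averaged line densities and the PCP amplitude."""

    ald: np.ndarray  # (6,) averaged line density per angle bin
    counts: np.ndarray  # (6,) junctions per bin
    pcp: float  # ratio of extreme-bin ALDs in the requested orientation
    mode: str  # "DV/AP" or "AP/DV"
    relative_intensity: np.ndarray  # ALD / min(extreme-bin ALDs)

    @property
    def bins(self):
        return list(ANGLE_BINS)


def polarity_profile(
    densities: dict[int, float],
    angles: dict[int, float],
    mode: str = "DV/AP",
) -> PolarityProfile:
    """Six-bin planar-polarity profile of junction line densities.

    ``mode`` selects the orientation of the PCP ratio: "DV/AP" divides the
    75--90 bin ALD by the 0--15 bin ALD (Myosin-style polarity), "AP/DV"
    the converse (E-cadherin-style). Raises if an extreme bin is empty or
    its ALD is non-positive.
    """
    if mode not in ("DV/AP", "AP/DV"):
        raise ValueError("mode must be 'DV/AP' or 'AP/DV'")
    sums = np.zeros(6)
    counts = np.zeros(6, dtype=int)
    for jid, d in densities.items():
        if not np.isfinite(d):
            continue
        a = angles[jid]
        if not 0.0 <= a <= 90.0:
            raise ValueError(f"angle {a} outside [0, 90]")
        b = min(int(a // 15), 5)
        sums[b] += d
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        ald = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    for name, b in (("0-15", 0), ("75-90", 5)):
        if counts[b] == 0:
            raise ValueError(f"extreme angle bin {name} is empty")
    lo, hi = ald[0], ald[5]  # AP extreme, DV extreme
    if lo <= 0 or hi <= 0:
        raise ValueError("extreme-bin ALD must be positive for a PCP ratio")
    pcp = hi / lo if mode == "DV/AP" else lo / hi
    rel = ald / min(lo, hi)
    return PolarityProfile(
        ald=ald, counts=counts, pcp=float(pcp), mode=mode, relative_intensity=rel
    )


# ---------------------------------------------------------------------------
# pixel-scale Vinc/E-cad


@dataclass
class PixelRatioProfile:
    """Mean per-pixel Vinc/E-cad in E-cadherin intensity bins."""

    bin_edges: np.ndarray  # contiguous, width bin_width
    mean_ratio: np.ndarray  # per bin, NaN where empty
    pixel_counts: np.ndarray
    snr_threshold: float
    n_pixels: int

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


def pixel_ratio_profile(
    vinc_image: np.ndarray,
    ecad_image: np.ndarray,
    junction_mask: np.ndarray | None = None,
    bin_width: float = 25.0,
    snr_threshold: float = 1.0,
    background_radius: int = 50,
) -> PixelRatioProfile:
    """Per-pixel Vinc/E-cad ratio profiled against E-cadherin intensity.

    E-cadherin-positive pixels are identified by their signal-to-noise
    ratio: SNR = (I - background) / noise, with the background a median
    filter of the E-cadherin channel (radius ``background_radius``) and the
    noise scale the MAD-based robust standard deviation of the residual
    over non-junctional pixels. Pixels with SNR above the threshold are
    grouped into contiguous E-cadherin-intensity bins of the given width
    and the mean per-pixel Vinc/E-cad is reported per bin.
    """
    vinc = np.asarray(vinc_image, dtype=float)
    ecad = np.asarray(ecad_image, dtype=float)
    if vinc.shape != ecad.shape:
        raise ValueError("channel images must be registered (same shape)")

    if background_radius > 0:
        bg = ndimage.median_filter(ecad, footprint=disk(background_radius))
    else:
        bg = np.zeros_like(ecad)
    resid = ecad - bg
    noise_pool = resid if junction_mask is None else resid[~junction_mask]
    mad = np.median(np.abs(noise_pool - np.median(noise_pool)))
    noise = 1.4826 * mad
    if noise == 0:
        noise = np.finfo(float).eps
    snr = resid / noise
    sel = snr > snr_threshold
    if junction_mask is not None:
        sel &= junction_mask
    sel &= ecad > 0

    e = ecad[sel]
    v = vinc[sel]
    if e.size == 0:
        warnings.warn("no pixels above the SNR threshold; empty ratio profile")
        return PixelRatioProfile(
            bin_edges=np.array([0.0, bin_width]),
            mean_ratio=np.array([np.nan]),
            pixel_counts=np.array([0]),
            snr_threshold=snr_threshold,
            n_pixels=0,
        )
    lo = np.floor(e.min() / bin_width) * bin_width
    hi = np.ceil(e.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(e, edges) - 1, 0, len(edges) - 2)
    ratio = v / e
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=ratio, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean_ratio = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PixelRatioProfile(
        bin_edges=edges,
        mean_ratio=mean_ratio,
        pixel_counts=counts,
        snr_threshold=snr_threshold,
        n_pixels=int(e.size),
    )
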