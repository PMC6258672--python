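"""Correlation machinery for junction-level quantities.

Two bespoke instances of partial correlation are provided. *Conditional
correlation* removes the 1/length confound shared by line densities and
inferred tensions: junctions are sorted by length within each snapshot,
chunked into bins of exactly ``bin_size`` junctions of near-equal length,
and a coefficient is computed inside each bin. *Local correlation*
controls for slow spatial and temporal variation by correlating across
the junctions of each individual cell, with a permutation null obtained
by shuffling one variable across all junctions of the snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import TissueNetwork

__all__ = [
    "ConditionalCorrelationResult",
    "LocalCorrelationResult",
    "conditional_correlation",
    "local_correlation",
    "bootstrap_mean",
    "choose_method",
]


def choose_method(n_points: int, override: str | None = None) -> str:
    """Correlation-method choice rule: Spearman for small samples.

    With fewer than 100 points the assumption of a linear relationship is
    not justified, so Spearman (rank) correlation is used; Pearson
    otherwise. ``override`` forces either method.
    """
    if override is not None:
        if override not in ("pearson", "spearman"):
            raise ValueError("override must be 'pearson' or 'spearman'")
        return override
    return "spearman" if n_points < 100 else "pearson"


def _corr(x, y, method):
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# conditional correlation


@dataclass
class ConditionalCorrelationResult:
    """Per-bin coefficients from length-conditioned correlation."""

    table: pd.DataFrame  # snapshot, bin, mean_length, r, n
    bin_size: int
    method: str
    skipped_snapshots: list = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        return self.table["r"].to_numpy()

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.coefficients))

    def by_length(self, resolution: float = 1.0) -> pd.DataFrame:
        """Mean +/- SE of the coefficient across bins of equal length.

        Bin mean lengths are rounded to ``resolution`` (px) and bins with
        the same rounded length are aggregated.
        """
        t = self.table.copy()
        t["length_group"] = (t["mean_length"] / resolution).round() * resolution
        g = t.groupby("length_group")["r"]
        out = g.agg(["mean", "count"])
        out["se"] = g.sem()
        return out.reset_index()


def conditional_correlation(
    x,
    y,
    lengths,
    snapshots=None,
    bin_size: int = 10,
    method: str = "pearson",
) -> ConditionalCorrelationResult:
    """Correlation of x and y within bins of junctions of near-equal length.

    Within each snapshot, junctions are sorted by length (ties broken by
    input order, deterministically) and chunked into consecutive bins of
    exactly ``bin_size``; trailing junctions that do not fill a bin are
    dropped. One coefficient is computed per bin; the pooled distribution
    across snapshots is the result. Snapshots with fewer than ``bin_size``
    junctions are skipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if not (len(x) == len(y) == len(lengths)):
        raise ValueError("x, y and lengths must have equal length")
    if snapshots is None:
        snapshots = np.zeros(len(x), dtype=int)
    snapshots = np.asarray(snapshots)

    rows = []
    skipped = []
    for snap in np.unique(snapshots):
        m = snapshots == snap
        if m.sum() < bin_size:
            skipped.append(snap)
            warnings.warn(f"snapshot {snap!r} has fewer than {bin_size} junctions")
            continue
        idx = np.flatnonzero(m)
        order = idx[np.argsort(lengths[idx], kind="stable")]
        n_bins = len(order) // bin_size
        for b in range(n_bins):
            sel = order[b * bin_size : (b + 1) * bin_size]
            xb, yb = x[sel], y[sel]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                r = np.nan  # constant within bin: coefficient undefined
            else:
                r = _corr(xb, yb, method)
            rows.append(
                {
                    "snapshot": snap,
                    "bin": b,
                    "mean_length": float(lengths[sel].mean()),
                    "r": r,
                    "n": bin_size,
                }
            )
    table = pd.DataFrame(rows, columns=["snapshot", "bin", "mean_length", "r", "n"])
    return ConditionalCorrelationResult(
        table=table, bin_size=bin_size, method=method, skipped_snapshots=skipped
    )


# ---------------------------------------------------------------------------
# local (per-cell) correlation


@dataclass
class LocalCorrelationResult:
    """Per-cell Pearson coefficients with a matched permutation null."""

    coefficients: np.ndarray  # one per eligible cell
    cell_ids: list
    null_coefficients: np.ndarray  # (n_null, n_cells)
    n_excluded_cells: int
    min_junctions: int

    @property
    def median(self) -> float:
        if len(self.coefficients) == 0:
            return float("nan")
        return float(np.nanmedian(self.coefficients))

    @property
    def null_medians(self) -> np.ndarray:
        return np.nanmedian(self.null_coefficients, axis=1)

    def null_band(self, level: float = 0.95) -> tuple[float, float]:
        """Central band of the null distribution of median coefficients."""
        a = (1 - level) / 2
        lo, hi = np.quantile(self.null_medians, [a, 1 - a])
        return float(lo), float(hi)

    def mannwhitney_p(self, alternative: str = "greater") -> float:
        """Mann-Whitney U p-value of observed vs pooled null coefficients."""
        obs = self.coefficients[np.isfinite(self.coefficients)]
        null = self.null_coefficients.ravel()
        null = null[np.isfinite(null)]
        return float(sps.mannwhitneyu(obs, null, alternative=alternative).pvalue)


def local_correlation(
    cells,
    x,
    y,
    min_junctions: int = 4,
    n_null: int = 1000,
    seed: int = 0,
) -> LocalCorrelationResult:
    """Pearson correlation of x and y across the junctions of each cell.

    ``cells`` is either a :class:`TissueNetwork` (its cells' junction lists
    are used) or a mapping cell id -> list of junction ids; ``x`` and ``y``
    map junction id -> value. Cells with fewer than ``min_junctions``
    junctions carrying both values are excluded and counted. The null
    distribution permutes ``y`` across all junctions of the snapshot
    (preserving per-cell topology and the marginal distribution) and
    recomputes every per-cell coefficient, ``n_null`` times, seeded.
    """
    if isinstance(cells, TissueNetwork):
        membership = {
            c.id: list(c.junctions)
            for c in cells.cells.values()
            if not c.is_boundary
        }
    else:
        membership = {k: list(v) for k, v in cells.items()}

    jids = sorted(set(x) & set(y))
    pos = {jid: k for k, jid in enumerate(jids)}
    xv = np.array([x[j] for j in jids], dtype=float)
    yv = np.array([y[j] for j in jids], dtype=float)

    cell_ids, cell_idx, jun_idx = [], [], []
    n_excluded = 0
    for cid in sorted(membership):
        js = [j for j in membership[cid] if j in pos]
        if len(js) < min_junctions:
            n_excluded += 1
            continue
        k = len(cell_ids)
        cell_ids.append(cid)
        cell_idx.extend([k] * len(js))
        jun_idx.extend(pos[j] for j in js)
    if not cell_ids:
        warnings.warn("no cell has enough junctions for local correlation")
        return LocalCorrelationResult(
            coefficients=np.array([]),
            cell_ids=[],
            null_coefficients=np.empty((0, 0)),
            n_excluded_cells=n_excluded,
            min_junctions=min_junctions,
        )
    cell_idx = np.asarray(cell_idx)
    jun_idx = np.asarray(jun_idx)
    n_cells = len(cell_ids)

    def percell_r(yvals):
        xs = xv[jun_idx]
        ys = yvals[jun_idx]
        n = np.bincount(cell_idx, minlength=n_cells)
        sx = np.bincount(cell_idx, weights=xs, minlength=n_cells)
        sy = np.bincount(cell_idx, weights=ys, minlength=n_cells)
        sxx = np.bincount(cell_idx, weights=xs * xs, minlength=n_cells)
        syy = np.bincount(cell_idx, weights=ys * ys, minlength=n_cells)
        sxy = np.bincount(cell_idx, weights=xs * ys, minlength=n_cells)
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        denom = np.sqrt(np.clip(vx * vy, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        return np.clip(np.where(denom > 0, r, np.nan), -1.0, 1.0)

    observed = percell_r(yv)
    rng = np.random.default_rng(seed)
    null = np.empty((n_null, n_cells))
    for b in range(n_null):
        null[b] = percell_r(yv[rng.permutation(len(yv))])
    return LocalCorrelationResult(
        coefficients=observed,
        cell_ids=cell_ids,
        null_coefficients=null,
        n_excluded_cells=n_excluded,
        min_junctions=min_junctions,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_mean(values, n_boot: int = 10_000, seed: int = 0) -> np.ndarray:
    """Distribution of sample means over seeded resamples with replacement."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return v[idx].mean(axis=1)
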