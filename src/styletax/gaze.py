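"""Fixation-heatmap analysis: from fixation records to a style clustering.

Each (motif, style) stimulus gets a G×G fixation-count grid over the image
rectangle (G = 10 by default; an 824 px image gives 82.4 px cells). Counts
are normalized to unit mass, the dataset-wide mean map (the grand total
bias, dominated by center bias) is subtracted, maps are flattened row-major
and correlated pairwise per motif across styles (Pearson r with two-sided
p), the per-motif correlation matrices are averaged cell-wise over all
motifs, and 1 − r feeds average-linkage clustering.

Heatmaps carry an explicit state (raw_counts → normalized → bias_subtracted)
and the stage functions enforce the state machine: you cannot correlate
un-debiased maps or normalize twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .matrices import PairMatrix
from .records import FixationRecord, StyleSet
from .taxonomy import LinkageTree, average_linkage

STATES = ("raw_counts", "normalized", "bias_subtracted")


@dataclass(frozen=True)
class ImageRect:
    """Axis-aligned image rectangle in screen pixels (origin top-left)."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"empty image rectangle: {self.width} x {self.height}")

    @classmethod
    def centered(cls, screen_size: tuple[int, int], image_size: int) -> "ImageRect":
        sw, sh = screen_size
        return cls(x0=(sw - image_size) / 2.0, y0=(sh - image_size) / 2.0,
                   width=float(image_size), height=float(image_size))


@dataclass(frozen=True)
class HeatmapGrid:
    """G×G spatial mass grid for one stimulus (or an accumulation)."""

    motif: str
    style: str
    mass: np.ndarray
    n_fixations: int
    state: str
    n_discarded: int = 0  # fixations outside the image rectangle

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", mass)
        if mass.ndim != 2 or mass.shape[0] != mass.shape[1]:
            raise ValueError(f"mass must be a square grid, got shape {mass.shape}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if self.state == "raw_counts":
            if np.any(mass < 0) or not np.allclose(mass, np.round(mass)):
                raise ValueError("raw counts must be nonnegative integers")
            if int(mass.sum()) != self.n_fixations:
                raise ValueError("raw counts must sum to n_fixations")

    @property
    def grid_size(self) -> int:
        return self.mass.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major 1D view used for correlation."""
        return self.mass.ravel()


def bin_fixations(
    fixations: Sequence[FixationRecord],
    image_rect: ImageRect,
    grid_size: int = 10,
    *,
    motif: str | None = None,
    style: str | None = None,
) -> HeatmapGrid:
    """Sort one stimulus's fixations into a G×G count grid over the image.

    Cells are half-open ``[edge_k, edge_{k+1})`` with the last row/column
    closed; fixations outside the image rectangle are discarded and counted
    in ``n_discarded``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if motif is None:
        motifs = {f.motif for f in fixations}
        motif = motifs.pop() if len(motifs) == 1 else "ALL"
    if style is None:
        styles = {f.style for f in fixations}
        style = styles.pop() if len(styles) == 1 else "ALL"
    xs = np.array([f.x for f in fixations], dtype=float)
    ys = np.array([f.y for f in fixations], dtype=float)
    # np.histogram2d implements exactly the half-open / last-bin-closed rule
    counts, _, _ = np.histogram2d(
        ys,
        xs,
        bins=grid_size,
        range=[
            [image_rect.y0, image_rect.y0 + image_rect.height],
            [image_rect.x0, image_rect.x0 + image_rect.width],
        ],
    )
    inside = (
        (xs >= image_rect.x0)
        & (xs <= image_rect.x0 + image_rect.width)
        & (ys >= image_rect.y0)
        & (ys <= image_rect.y0 + image_rect.height)
    )
    n_in = int(inside.sum())
    return HeatmapGrid(
        motif=motif,
        style=style,
        mass=counts,
        n_fixations=n_in,
        state="raw_counts",
        n_discarded=len(fixations) - n_in,
    )


def normalize_heatmap(h: HeatmapGrid) -> HeatmapGrid:
    """Scale raw counts to unit total mass."""
    if h.state != "raw_counts":
        raise ValueError(f"can only normalize raw_counts maps, got state {h.state!r}")
    if h.n_fixations < 1:
        raise ValueError(f"map ({h.motif}, {h.style}) has no fixations; cannot normalize")
    return replace(h, mass=h.mass / h.mass.sum(), state="normalized")


def grand_bias(heatmaps: Iterable[HeatmapGrid]) -> np.ndarray:
    """Dataset-wide mean of normalized maps: the grand total (center) bias.

    The unweighted mean over every (motif, style) map; sums to 1.
    """
    maps = list(heatmaps)
    if not maps:
        raise ValueError("need at least one normalized heatmap")
    for h in maps:
        if h.state != "normalized":
            raise ValueError(f"grand bias requires normalized maps, got {h.state!r}")
    return np.mean([h.mass for h in maps], axis=0)


def subtract_bias(h: HeatmapGrid, bias: np.ndarray) -> HeatmapGrid:
    """Remove the grand bias, leaving a zero-sum style/content residual map."""
    if h.state != "normalized":
        raise ValueError(f"can only subtract bias from normalized maps, got {h.state!r}")
    bias = np.asarray(bias, dtype=float)
    if bias.shape != h.mass.shape:
        raise ValueError(f"bias shape {bias.shape} does not match grid {h.mass.shape}")
    return replace(h, mass=h.mass - bias, state="bias_subtracted")


@dataclass
class StyleCorrelation:
    """Pearson correlations between styles' fixation maps.

    ``r`` is symmetric with unit diagonal; ``p`` holds two-sided p-values
    (NaN on the diagonal and wherever r is undefined); ``n_images`` counts,
    per cell, how many per-motif matrices contributed (1 for a single-image
    matrix).
    """

    styles: StyleSet
    r: np.ndarray
    p: np.ndarray
    n_images: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.styles)
        for name in ("r", "p", "n_images"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            setattr(self, name, arr)

    def r_matrix(self) -> PairMatrix:
        return PairMatrix(styles=self.styles, values=self.r, statistic="similarity")

    def distance_matrix(self, rule: str = "one_minus_r") -> PairMatrix:
        """Convert average correlations to clustering distances (default 1 − r)."""
        if rule == "one_minus_r":
            values = 1.0 - self.r
        elif rule == "arccos":
            values = np.arccos(np.clip(self.r, -1.0, 1.0))
        else:
            raise ValueError(f"unknown correlation-to-distance rule {rule!r}")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        return PairMatrix(styles=self.styles, values=values, statistic="distance")


def correlate_styles_for_image(
    heatmaps: Mapping[str, HeatmapGrid], styles: StyleSet
) -> StyleCorrelation:
    """Pairwise Pearson correlation of one motif's maps across styles.

    Maps are flattened row-major; zero-variance maps yield NaN cells with a
    warning rather than a silent 0.
    """
    present = [s for s in styles.labels if s in heatmaps]
    if len(present) < 2:
        raise ValueError("need bias-subtracted maps for at least 2 styles")
    for s in present:
        if heatmaps[s].state != "bias_subtracted":
            raise ValueError(
                f"correlation requires bias_subtracted maps; ({heatmaps[s].motif}, {s}) "
                f"is {heatmaps[s].state!r}"
            )
    n = len(styles)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    n_images = np.zeros((n, n))
    for s in present:
        i = styles.index(s)
        r[i, i] = 1.0
        n_images[i, i] = 1.0
    for ai in range(len(present)):
        for bi in range(ai + 1, len(present)):
            a, b = present[ai], present[bi]
            va, vb = heatmaps[a].flatten(), heatmaps[b].flatten()
            i, j = styles.index(a), styles.index(b)
            if np.std(va) == 0 or np.std(vb) == 0:
                warnings.warn(
                    f"zero-variance map for motif {heatmaps[a].motif!r} "
                    f"({a if np.std(va) == 0 else b}); correlation undefined",
                    stacklevel=2,
                )
                continue
            res = stats.pearsonr(va, vb)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
            n_images[i, j] = n_images[j, i] = 1.0
    return StyleCorrelation(styles=styles, r=r, p=p, n_images=n_images)


def average_correlations(per_image: Sequence[StyleCorrelation]) -> StyleCorrelation:
    """Cell-wise mean of per-motif correlation matrices.

    Cells undefined in some motifs are averaged over the motifs where they
    are defined; ``n_images`` records that count per cell. p-values are not
    combined (the per-image matrices keep them).
    """
    if not per_image:
        raise ValueError("need at least one per-image correlation matrix")
    styles = per_image[0].styles
    for c in per_image[1:]:
        if c.styles.labels != styles.labels:
            raise ValueError("correlation matrices must share one roster")
    stack = np.stack([c.r for c in per_image])
    defined = ~np.isnan(stack)
    n_images = defined.sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean_r = np.nanmean(stack, axis=0)
    mean_r[n_images == 0] = np.nan
    n = len(styles)
    return StyleCorrelation(
        styles=styles, r=mean_r, p=np.full((n, n), np.nan), n_images=n_images
    )


def accumulate_style_heatmaps(
    normalized: Sequence[HeatmapGrid], styles: StyleSet, bias: np.ndarray
) -> dict[str, HeatmapGrid]:
    """Per-style mean of normalized per-image maps, bias-subtracted.

    Each accumulated map sums to 0 (its inputs each sum to 1 and the bias is
    itself a mean of unit-mass maps only when the bias comes from the same
    dataset — the caller supplies it). Styles with no images are omitted.
    """
    by_style: dict[str, list[np.ndarray]] = {}
    for h in normalized:
        if h.state != "normalized":
            raise ValueError("accumulation expects normalized maps")
        by_style.setdefault(h.style, []).append(h.mass)
    out: dict[str, HeatmapGrid] = {}
    for s in styles.labels:
        if s not in by_style:
            continue
        mean_map = np.mean(by_style[s], axis=0)
        out[s] = HeatmapGrid(
            motif="ALL",
            style=s,
            mass=mean_map - bias,
            n_fixations=0,
            state="bias_subtracted",
        )
    return out


@dataclass(frozen=True)
class DensityMap:
    """Kernel-smoothed fixation density over the screen."""

    density: np.ndarray  # (ny, nx), integrates to 1 over the screen
    x_coords: np.ndarray
    y_coords: np.ndarray
    peak_xy: tuple[float, float]
    screen_center: tuple[float, float]


def density_map(
    fixations: Sequence[FixationRecord],
    screen_size: tuple[int, int],
    subject: str | None = None,
    bandwidth: float | None = None,
    resolution: int = 64,
) -> DensityMap:
    """Gaussian-KDE fixation density with the peak location reported.

    ``subject=None`` pools all subjects. The returned grid integrates to 1
    over the screen (cell areas accounted for).
    """
    pts = [f for f in fixations if subject is None or f.subject == subject]
    if not pts:
        raise ValueError("no fixations to smooth")
    xs = np.array([f.x for f in pts])
    ys = np.array([f.y for f in pts])
    sw, sh = screen_size
    gx = np.linspace(0, sw, resolution)
    gy = np.linspace(0, sh, resolution)
    if len(pts) == 1:
        # KDE is degenerate with one point; a single delta-like peak suffices
        density = np.zeros((resolution, resolution))
        iy = int(np.clip(np.searchsorted(gy, ys[0]), 0, resolution - 1))
        ix = int(np.clip(np.searchsorted(gx, xs[0]), 0, resolution - 1))
        density[iy, ix] = 1.0
        peak = (float(xs[0]), float(ys[0]))
    else:
        kde = stats.gaussian_kde(np.vstack([xs, ys]), bw_method=bandwidth)
        mx, my = np.meshgrid(gx, gy)
        density = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(resolution, resolution)
        k = int(np.argmax(density))
        peak = (float(mx.ravel()[k]), float(my.ravel()[k]))
    total = density.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
    if total > 0:
        density = density / total
    return DensityMap(
        density=density,
        x_coords=gx,
        y_coords=gy,
        peak_xy=peak,
        screen_center=(sw / 2.0, sh / 2.0),
    )


@dataclass
class GazeResult:
    """All intermediates of the gaze pipeline plus the final clustering."""

    styles: StyleSet
    n_fixations: int
    n_discarded: int
    per_image: list[StyleCorrelation]
    averaged: StyleCorrelation
    style_heatmaps: dict[str, HeatmapGrid]
    bias: np.ndarray
    tree: LinkageTree

    def report(self) -> dict:
        return {
            "n_fixations": self.n_fixations,
            "n_discarded_outside_image": self.n_discarded,
            "n_motifs": len(self.per_image),
            "distance_rule": "1 - mean Pearson r",
        }


def gaze_pipeline(
    fixations: Sequence[FixationRecord],
    styles: StyleSet,
    *,
    image_rect: ImageRect,
    grid_size: int = 10,
    distance_rule: str = "one_minus_r",
    weighted_linkage: bool = False,
) -> GazeResult:
    """Run the full gaze analysis: bin → normalize → debias → correlate → tree.

    Per-motif maps pool all subjects' raw fixations on that (motif, style)
    stimulus before normalization.
    """
    if not fixations:
        raise ValueError("empty fixation log")
    grouped: dict[tuple[str, str], list[FixationRecord]] = {}
    for f in fixations:
        if f.style not in styles:
            raise KeyError(f"unknown style label {f.style!r}; roster is {styles.labels}")
        grouped.setdefault((f.motif, f.style), []).append(f)

    raw = {
        key: bin_fixations(fx, image_rect, grid_size, motif=key[0], style=key[1])
        for key, fx in grouped.items()
    }
    n_discarded = sum(h.n_discarded for h in raw.values())
    normalized = {}
    for key, h in raw.items():
        if h.n_fixations == 0:
            warnings.warn(f"map {key} has no in-image fixations; excluded", stacklevel=2)
            continue
        normalized[key] = normalize_heatmap(h)
    if not normalized:
        raise ValueError("no stimulus has in-image fixations")
    bias = grand_bias(normalized.values())
    debiased = {key: subtract_bias(h, bias) for key, h in normalized.items()}

    motifs = sorted({m for m, _ in debiased})
    per_image: list[StyleCorrelation] = []
    for motif in motifs:
        maps = {s: debiased[(motif, s)] for (m, s) in debiased if m == motif}
        if len(maps) >= 2:
            per_image.append(correlate_styles_for_image(maps, styles))
    if not per_image:
        raise ValueError("no motif was seen in at least 2 styles; nothing to correlate")
    averaged = average_correlations(per_image)
    style_maps = accumulate_style_heatmaps(list(normalized.values()), styles, bias)
    dist = averaged.distance_matrix(distance_rule)
    tree = average_linkage(dist, weighted=weighted_linkage)
    return GazeResult(
        styles=styles,
        n_fixations=len(fixations),
        n_discarded=n_discarded,
        per_image=per_image,
        averaged=averaged,
        style_heatmaps=style_maps,
        bias=bias,
        tree=tree,
    )
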