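"""Synthetic behavioral data from a planted style taxonomy.

The generator emulates the two-experiment design this package analyzes:

* a singleton-search experiment in which every ordered (target, distractor)
  style pair appears exactly once per block, motifs are never repeated within
  a subject, and responses/RTs follow a psychometric model driven by the
  planted inter-style distance;
* a free-viewing experiment in which every subject sees each motif exactly
  once, in exactly one style, 30 motifs per style by default, and fixations
  are drawn from a mixture of a motif-specific content field, a
  style-specific field diffused along the planted tree, and a central
  Gaussian bias.

All randomness flows from integer seeds through named substreams, so the
design, the trial simulation, and the fixation simulation can be re-run
independently and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .matrices import PairMatrix
from .records import (
    LOCATIONS,
    FixationRecord,
    StyleSet,
    TrialRecord,
    TrialSkeleton,
    Viewing,
)
from .taxonomy import LinkageTree, Merge, cophenetic, from_newick


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named deterministic substream of a single global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(stream)))


# ---------------------------------------------------------------------------
# planted ground truth


@dataclass(frozen=True)
class PlantedTaxonomy:
    """Ground-truth style tree plus a scale mapping cophenetic distance to [0, 1].

    ``distance_scale`` defaults to the tree height, so normalized planted
    distances span (0, 1] off the diagonal and are exactly 0 on it.
    """

    tree: LinkageTree
    distance_scale: float | None = None

    @property
    def scale(self) -> float:
        return self.tree.height if self.distance_scale is None else self.distance_scale

    @property
    def styles(self) -> StyleSet:
        return self.tree.leaves

    def distance_matrix(self) -> PairMatrix:
        """Normalized planted distances in [0, 1]; ultrametric by construction."""
        coph = cophenetic(self.tree)
        scale = self.scale
        if scale <= 0:
            values = np.zeros_like(coph.values)
        else:
            values = coph.values / scale
        return PairMatrix(styles=self.styles, values=values, statistic="distance")

    def distance(self, a: str, b: str) -> float:
        return self.distance_matrix()[a, b]


def default_planted_taxonomy() -> PlantedTaxonomy:
    """An 8-style planted tree with well-separated merge heights.

    Mirrors the shape of the art-historical reference: two era pairs, a
    three-painter lineage, and an outgroup, with heights 1..4 so normalized
    distances take the values {0.25, 0.5, 0.75, 1.0}.
    """
    newick = "((((EI:1,LI:1):1,(EE:1,LE:1):1):1,((C:1,G:1):1,VG:2):1):1,P:4);"
    return PlantedTaxonomy(tree=from_newick(newick))


def star_taxonomy(styles: StyleSet, height: float = 1.0) -> PlantedTaxonomy:
    """All styles equidistant; with ``distance_scale=inf``-like zero signal use scale override."""
    labels = styles.labels
    merges = []
    acc = (labels[0],)
    for lab in labels[1:]:
        merges.append(Merge(a=acc, b=(lab,), height=height))
        acc = tuple(sorted(acc + (lab,)))
    return PlantedTaxonomy(tree=LinkageTree(leaves=styles, merges=tuple(merges)))


def zero_distance_taxonomy(styles: StyleSet) -> PlantedTaxonomy:
    """Planted distances identically zero: no style signal at all."""
    tax = star_taxonomy(styles, height=0.0)
    return tax


# ---------------------------------------------------------------------------
# singleton-search behavior


@dataclass(frozen=True)
class SearchBehaviorModel:
    """Psychometric model coupling accuracy and RT to planted distance D.

    Accuracy follows ``p(D) = chance + (1 - chance) * (1 - exp(-lambda * D))``,
    a saturating psychometric function anchored at chance for
    indistinguishable styles. RTs are lognormal with median
    ``exp(rt_location - rt_similarity_slope * D)`` seconds, so harder
    (more similar) pairs are both slower and less accurate. A small fraction
    of trials are fast guesses (uniform RT in [0.05, 0.15) s, uniform
    response) and another small fraction get a heavy-tailed RT inflation,
    emulating lapses.

    Defaults are matched to the observed scale of the search data: overall
    lognormal location/shape chosen so pair-averaged mean RT sits near 2.2 s
    with median near 1.6 s, and the psychometric gain spans accuracies from
    near-chance to ~95% over D in [0, 1].
    """

    chance_level: float = 0.25
    discrimination_gain: float = 3.0
    rt_location: float = 0.7  # log-seconds at D = 0
    rt_similarity_slope: float = 0.6
    rt_sigma: float = 0.8
    fast_guess_rate: float = 0.02
    outlier_rate: float = 0.05
    subject_sd: float = 0.0  # optional lognormal random intercept across subjects
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chance_level", "fast_guess_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.discrimination_gain <= 0:
            raise ValueError("discrimination_gain must be positive")

    def p_correct(self, distance: float) -> float:
        """Probability of locating the target at planted distance ``distance``."""
        return self.chance_level + (1.0 - self.chance_level) * (
            1.0 - math.exp(-self.discrimination_gain * distance)
        )

    def mean_rt(self, distance: float) -> float:
        """Closed-form mean of the lognormal RT component (no lapses)."""
        mu = self.rt_location - self.rt_similarity_slope * distance
        return math.exp(mu + self.rt_sigma**2 / 2.0)


def make_search_design(
    styles: StyleSet, blocks: int, motif_pool: int, seed: int
) -> list[TrialSkeleton]:
    """Per-subject singleton-search schedule.

    Each block contains every ordered (target, distractor) pair exactly once,
    in seeded random order; motifs are drawn from a pool of ``motif_pool``
    names without repetition across the whole schedule.
    """
    pairs = styles.ordered_pairs()
    needed = blocks * len(pairs)
    if motif_pool < needed:
        raise ValueError(
            f"motif pool too small: need at least {needed} motifs "
            f"({blocks} blocks x {len(pairs)} ordered pairs), got {motif_pool}"
        )
    rng = _rng(seed, 1)
    width = len(str(motif_pool - 1))
    motif_ids = rng.choice(motif_pool, size=needed, replace=False)
    design: list[TrialSkeleton] = []
    k = 0
    for block in range(blocks):
        order = rng.permutation(len(pairs))
        for p in order:
            t, d = pairs[p]
            design.append(
                TrialSkeleton(
                    block=block,
                    target_style=t,
                    distractor_style=d,
                    motif=f"M{motif_ids[k]:0{width}d}",
                    target_location=LOCATIONS[rng.integers(4)],
                )
            )
            k += 1
    return design


def simulate_search_trials(
    design: Sequence[TrialSkeleton],
    taxonomy: PlantedTaxonomy,
    model: SearchBehaviorModel,
    subject: str = "S1",
) -> list[TrialRecord]:
    """Simulate responses and RTs for a search schedule.

    Reproducible under ``model.seed``; unknown styles in the design raise
    KeyError.
    """
    styles = taxonomy.styles
    dmat = taxonomy.distance_matrix()
    dvals = np.array(
        [dmat.values[styles.index(s.target_style), styles.index(s.distractor_style)] for s in design]
    )
    n = len(design)
    rng = _rng(model.seed, 2)
    subj_shift = rng.normal(0.0, model.subject_sd) if model.subject_sd > 0 else 0.0

    fast = rng.random(n) < model.fast_guess_rate
    p = model.chance_level + (1.0 - model.chance_level) * (
        1.0 - np.exp(-model.discrimination_gain * dvals)
    )
    correct = rng.random(n) < p
    mu = model.rt_location - model.rt_similarity_slope * dvals + subj_shift
    rt = np.exp(mu + model.rt_sigma * rng.standard_normal(n))
    outlier = rng.random(n) < model.outlier_rate
    rt = np.where(outlier, rt * (1.0 + rng.exponential(scale=2.0, size=n)), rt)
    fast_rt = 0.05 + 0.10 * rng.random(n)
    fast_resp = rng.integers(4, size=n)
    wrong_pick = rng.integers(3, size=n)

    records: list[TrialRecord] = []
    for i, s in enumerate(design):
        if fast[i]:
            resp = LOCATIONS[fast_resp[i]]
            trial_rt = float(fast_rt[i])
        else:
            if correct[i]:
                resp = s.target_location
            else:
                others = [loc for loc in LOCATIONS if loc != s.target_location]
                resp = others[wrong_pick[i]]
            trial_rt = float(rt[i])
        records.append(
            TrialRecord(
                subject=subject,
                block=s.block,
                target_style=s.target_style,
                distractor_style=s.distractor_style,
                target_location=s.target_location,
                response_location=resp,
                rt=trial_rt,
            )
        )
    return records


# ---------------------------------------------------------------------------
# free-viewing gaze behavior


@dataclass(frozen=True)
class GazeBehaviorModel:
    """Generative model for fixations on stimuli.

    The fixation density for a (motif, style) stimulus is a convex mixture of
    three normalized components on a fine grid over the image:

    * a content field shared by every style rendering of the motif,
    * a style field obtained by Brownian diffusion of a latent field along
      the planted tree (so the correlation between two styles' latent fields
      equals ``1 - D(s, t)``, the stated style-similarity rule),
    * a central Gaussian bias emulating the ubiquitous screen-center bias.

    Fixation counts per subject per image are Poisson with mean
    ``fixations_per_subject_mean`` (default 16, eight subjects per image
    giving ~128 fixations per stimulus); positions are i.i.d. from the mixed
    density and always fall inside the image, hence inside the screen.

    ``field_gain`` sets the contrast of the exponentiated content and style
    fields. The default is chosen so the per-stimulus style signal is of the
    same order as the multinomial sampling noise at ~128 fixations per map;
    much lower gains leave densities nearly uniform and the style structure
    unrecoverable at realistic fixation counts.
    """

    screen_size: tuple[int, int] = (1280, 1024)
    image_size: int = 824
    weight_content: float = 0.35
    weight_style: float = 0.35
    weight_center: float = 0.3
    fixations_per_subject_mean: float = 16.0
    field_grid: int = 20
    field_smoothing: float = 1.0
    field_gain: float = 8.0
    center_sigma_frac: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.weight_content, self.weight_style, self.weight_center)
        if any(x < 0 for x in w):
            raise ValueError("mixture weights must be nonnegative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)}")
        sw, sh = self.screen_size
        if self.image_size > sw or self.image_size > sh:
            raise ValueError("image must fit within the screen")
        if self.fixations_per_subject_mean <= 0:
            raise ValueError("fixations_per_subject_mean must be positive")

    def image_origin(self) -> tuple[float, float]:
        """Top-left corner of the (centered) image on the screen."""
        sw, sh = self.screen_size
        return ((sw - self.image_size) / 2.0, (sh - self.image_size) / 2.0)

    def expected_field_correlation(self, planted_distance: float) -> float:
        """The generator's style-similarity rule: corr = 1 - D."""
        return 1.0 - planted_distance


def make_gaze_design(
    styles: StyleSet,
    motifs_per_style: int,
    seed: int,
    n_subjects: int = 8,
) -> list[Viewing]:
    """Free-viewing schedule for ``n_subjects`` subjects.

    Each subject sees every motif exactly once, in exactly one style, with
    ``motifs_per_style`` motifs per style; each consecutive block of
    |styles| presentations contains one stimulus of each style. Styles are
    rotated across subjects (a Latin design), so with ``n_subjects`` a
    multiple of |styles| every (motif, style) stimulus is seen by
    ``n_subjects / |styles|`` subjects.
    """
    if motifs_per_style < 1:
        raise ValueError("motifs_per_style must be >= 1")
    s = len(styles)
    n_motifs = s * motifs_per_style
    rng = _rng(seed, 3)
    width = len(str(n_motifs - 1))
    motifs = [f"M{m:0{width}d}" for m in range(n_motifs)]
    # seeded random partition of motifs into |S| base groups of equal size
    perm = rng.permutation(n_motifs)
    group = np.empty(n_motifs, dtype=int)
    for g in range(s):
        group[perm[g * motifs_per_style : (g + 1) * motifs_per_style]] = g

    schedule: list[Viewing] = []
    for subj in range(n_subjects):
        subject = f"S{subj:03d}"
        # rotate style assignment per subject; shuffle motif order within group
        by_style: dict[int, list[str]] = {}
        for g in range(s):
            idx = np.flatnonzero(group == g)
            rng_order = rng.permutation(len(idx))
            by_style[(g + subj) % s] = [motifs[idx[i]] for i in rng_order]
        for block in range(motifs_per_style):
            style_order = rng.permutation(s)
            for si in style_order:
                schedule.append(
                    Viewing(
                        subject=subject,
                        block=block,
                        motif=by_style[si][block],
                        style=styles.labels[si],
                    )
                )
    return schedule


def _softmax_density(field: np.ndarray, gain: float) -> np.ndarray:
    z = gain * (field - field.max())
    e = np.exp(z)
    total = e.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate (all-zero) density field")
    return e / total


def _tree_edges(tree: LinkageTree) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """(parent members, child members, branch length) for every edge, leaves at height 0."""
    node_height = {(lab,): 0.0 for lab in tree.leaves.labels}
    edges = []
    for m in tree.merges:
        for child in (m.a, m.b):
            edges.append((m.members, child, m.height - node_height[child]))
        node_height[m.members] = m.height
    return edges


def _style_fields(
    tree: LinkageTree, scale: float, shape: tuple[int, int], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Latent per-style fields via Brownian diffusion along the planted tree.

    Each edge contributes an independent Gaussian increment with variance
    proportional to its (normalized) length; a leaf's field is the sum of
    increments on its root path. Two leaves then share exactly the increments
    above their lowest common ancestor, giving
    ``corr(f_s, f_t) = 1 - cophenetic(s, t) / scale``.
    """
    if scale <= 0:  # zero-signal taxonomy: all styles share one (null) field
        return {lab: np.zeros(shape) for lab in tree.leaves.labels}
    fields: dict[tuple[str, ...], np.ndarray] = {tree.merges[-1].members: np.zeros(shape)}
    for parent, child, length in reversed(_tree_edges(tree)):
        incr = rng.standard_normal(shape) * math.sqrt(max(length, 0.0) / scale)
        fields[child] = fields[parent] + incr
    return {lab: fields[(lab,)] for lab in tree.leaves.labels}


def motif_densities(
    motif_index: int,
    taxonomy: PlantedTaxonomy,
    model: GazeBehaviorModel,
) -> dict[str, np.ndarray]:
    """Per-style fixation densities for one motif on the fine grid.

    Deterministic given ``model.seed`` and the motif index. Each density is
    nonnegative and sums to 1.
    """
    g = model.field_grid
    rng = _rng(model.seed, 4, motif_index)
    content = gaussian_filter(rng.standard_normal((g, g)), model.field_smoothing)
    content_density = _softmax_density(content, model.field_gain)

    raw_fields = _style_fields(taxonomy.tree, taxonomy.scale, (g, g), rng)
    style_densities = {
        lab: _softmax_density(gaussian_filter(f, model.field_smoothing), model.field_gain)
        if np.any(f)
        else np.full((g, g), 1.0 / g**2)
        for lab, f in raw_fields.items()
    }

    centers = (np.arange(g) + 0.5) / g - 0.5  # in image units, centered
    sigma = model.center_sigma_frac
    gx = np.exp(-0.5 * (centers / sigma) ** 2)
    center_density = np.outer(gx, gx)
    center_density /= center_density.sum()

    out = {}
    for lab in taxonomy.styles.labels:
        mix = (
            model.weight_content * content_density
            + model.weight_style * style_densities[lab]
            + model.weight_center * center_density
        )
        total = mix.sum()
        if total <= 0:
            raise ValueError("degenerate (all-zero) density")
        out[lab] = mix / total
    return out


def simulate_fixations(
    design: Sequence[Viewing],
    taxonomy: PlantedTaxonomy,
    model: GazeBehaviorModel,
) -> list[FixationRecord]:
    """Draw fixations for every viewing in the schedule.

    Fixation counts are Poisson per (subject, stimulus); positions are i.i.d.
    from the motif-and-style mixed density, sampled cell-then-uniform on the
    fine grid and mapped to screen pixels. All fixations land inside the
    image rectangle (and hence the screen).
    """
    styles = taxonomy.styles
    for v in design:
        if v.style not in styles:
            raise KeyError(f"unknown style label {v.style!r} in design")
    motif_names = sorted({v.motif for v in design})
    motif_idx = {m: i for i, m in enumerate(motif_names)}
    g = model.field_grid
    cell = model.image_size / g
    x0, y0 = model.image_origin()

    densities: dict[str, dict[str, np.ndarray]] = {}
    records: list[FixationRecord] = []
    rng = _rng(model.seed, 5)
    for v in design:
        if v.motif not in densities:
            densities[v.motif] = motif_densities(motif_idx[v.motif], taxonomy, model)
        dens = densities[v.motif][v.style]
        n = rng.poisson(model.fixations_per_subject_mean)
        if n == 0:
            continue
        flat = dens.ravel()
        cells = rng.choice(flat.size, size=n, p=flat)
        rows, cols = np.divmod(cells, g)
        xs = x0 + (cols + rng.random(n)) * cell
        ys = y0 + (rows + rng.random(n)) * cell
        for x, y in zip(xs, ys):
            records.append(
                FixationRecord(subject=v.subject, motif=v.motif, style=v.style, x=float(x), y=float(y))
            )
    return records
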