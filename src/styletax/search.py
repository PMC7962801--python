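"""Singleton-search analysis: from trial records to a style clustering.

Pipeline order: fast-guess exclusion (RT < 150 ms), winsorization of the
retained RTs at ±3.5 population SDs from the mean, per-pair accuracy and mean
RT matrices, effective RT = mean RT / accuracy (penalizing slow *and*
inaccurate pairs), element-wise inverse → symmetrized distance matrix, and
unweighted average-linkage clustering.

The effective RT is the core similarity statistic: a (target, distractor)
pair that is hard to tell apart yields long RTs at low accuracy, hence a
large effective RT, hence a small inverse distance — similar styles end up
close in the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrices import PairMatrix, require_same_roster
from .records import StyleSet, TrialRecord, validate_styles
from .taxonomy import LinkageTree, average_linkage


@dataclass(frozen=True)
class WinsorizeReport:
    """Moments used for clamping and how many trials each bound touched."""

    mean: float
    sd: float
    k: float
    n_clamped_low: int
    n_clamped_high: int
    n_total: int
    degenerate: bool = False  # < 2 trials or zero SD: pass-through

    @property
    def n_clamped(self) -> int:
        return self.n_clamped_low + self.n_clamped_high

    @property
    def pct_clamped(self) -> float:
        return 100.0 * self.n_clamped / self.n_total if self.n_total else 0.0


def exclude_fast_guesses(
    trials: Sequence[TrialRecord], threshold: float = 0.150
) -> tuple[list[TrialRecord], int]:
    """Drop trials faster than ``threshold`` seconds (accidental double-clicks).

    Returns the retained trials in input order and the count excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained = [t for t in trials if t.rt >= threshold]
    return retained, len(trials) - len(retained)


def winsorize_rts(
    trials: Sequence[TrialRecord], k: float = 3.5
) -> tuple[list[TrialRecord], WinsorizeReport]:
    """Clamp RTs beyond ±k SDs of the sample mean to the band edges.

    The mean and (population) SD are computed once on the input sample;
    values inside the band pass through unchanged, so re-applying with the
    original moments is idempotent. With fewer than 2 trials or zero SD the
    data pass through untouched and the report is flagged degenerate.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rts = np.array([t.rt for t in trials], dtype=float)
    n = rts.size
    if n < 2 or np.std(rts) == 0:
        mean = float(rts.mean()) if n else float("nan")
        return list(trials), WinsorizeReport(
            mean=mean, sd=0.0, k=k, n_clamped_low=0, n_clamped_high=0, n_total=n, degenerate=True
        )
    mean = float(rts.mean())
    sd = float(np.std(rts))
    lo, hi = mean - k * sd, mean + k * sd
    out: list[TrialRecord] = []
    n_lo = n_hi = 0
    for t in trials:
        if t.rt < lo:
            out.append(t.with_rt(lo))
            n_lo += 1
        elif t.rt > hi:
            out.append(t.with_rt(hi))
            n_hi += 1
        else:
            out.append(t)
    return out, WinsorizeReport(
        mean=mean, sd=sd, k=k, n_clamped_low=n_lo, n_clamped_high=n_hi, n_total=n
    )


def _cell_trials(
    trials: Sequence[TrialRecord], styles: StyleSet
) -> dict[tuple[int, int], list[TrialRecord]]:
    validate_styles(
        [t.target_style for t in trials] + [t.distractor_style for t in trials], styles
    )
    cells: dict[tuple[int, int], list[TrialRecord]] = {}
    for t in trials:
        key = (styles.index(t.target_style), styles.index(t.distractor_style))
        cells.setdefault(key, []).append(t)
    return cells


def accuracy_matrix(trials: Sequence[TrialRecord], styles: StyleSet) -> PairMatrix:
    """Fraction correct per (target, distractor) cell; empty cells stay NaN."""
    m = PairMatrix.empty(styles, "accuracy")
    for (i, j), cell in _cell_trials(trials, styles).items():
        m.values[i, j] = sum(t.correct for t in cell) / len(cell)
    return m


def rt_matrix(
    trials: Sequence[TrialRecord], styles: StyleSet, correct_only: bool = False
) -> PairMatrix:
    """Mean RT (seconds) per (target, distractor) cell.

    By default all retained trials contribute; ``correct_only=True``
    restricts to correct responses.
    """
    m = PairMatrix.empty(styles, "mean_rt")
    for (i, j), cell in _cell_trials(trials, styles).items():
        rts = [t.rt for t in cell if t.correct or not correct_only]
        if rts:
            m.values[i, j] = float(np.mean(rts))
    return m


def effective_rt(rt: PairMatrix, acc: PairMatrix) -> PairMatrix:
    """Cell-wise mean RT divided by accuracy.

    Accuracy 1 leaves the RT unchanged; accuracy 0 yields the +inf sentinel
    (infinitely hard discrimination, distance 0 downstream).
    """
    require_same_roster(rt, acc)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = rt.values / acc.values
    values[(acc.values == 0) & ~np.isnan(rt.values)] = np.inf
    return PairMatrix(styles=rt.styles, values=values, statistic="effective_rt")


def distance_from_effective_rt(eff: PairMatrix) -> PairMatrix:
    """Element-wise inverse of the effective RT, symmetrized, zero diagonal.

    1/inf is 0 (maximally similar); the symmetric distance for a pair is the
    arithmetic mean of its two ordered inverses.
    """
    with np.errstate(divide="ignore"):
        inv = 1.0 / eff.values
    inv[np.isinf(eff.values)] = 0.0
    sym = 0.5 * (inv + inv.T)
    np.fill_diagonal(sym, 0.0)
    return PairMatrix(styles=eff.styles, values=sym, statistic="distance")


@dataclass(frozen=True)
class AsymmetryEdge:
    """Directed dominance relation between two styles.

    The arrow points from the style with the larger target-role effective RT
    (harder to find among the other's distractors) toward the smaller.
    """

    source: str
    target: str
    magnitude: float


def asymmetry_matrix(
    eff: PairMatrix, threshold: float = 0.0
) -> tuple[PairMatrix, list[AsymmetryEdge]]:
    """Antisymmetric matrix of target-vs-distractor role differences.

    Cell (i, j) is eff(i as target, j as distractor) − eff(j as target, i as
    distractor). An edge i→j is emitted whenever that difference exceeds
    ``threshold`` (default 0: sign only).
    """
    values = eff.values - eff.values.T
    values[np.isnan(eff.values) | np.isnan(eff.values.T)] = np.nan
    # inf - inf is NaN already via numpy semantics
    m = PairMatrix(styles=eff.styles, values=values, statistic="asymmetry")
    edges: list[AsymmetryEdge] = []
    labels = eff.styles.labels
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            v = values[i, j]
            if np.isnan(v):
                continue
            if v > threshold:
                edges.append(AsymmetryEdge(source=a, target=labels[j], magnitude=float(v)))
            elif -v > threshold:
                edges.append(AsymmetryEdge(source=labels[j], target=a, magnitude=float(-v)))
    return m, edges


@dataclass
class SearchResult:
    """All intermediates of the search pipeline plus the final clustering."""

    styles: StyleSet
    n_input: int
    n_fast_guesses: int
    winsorize: WinsorizeReport
    accuracy: PairMatrix
    mean_rt: PairMatrix
    effective: PairMatrix
    distance: PairMatrix
    asymmetry: PairMatrix
    edges: list[AsymmetryEdge]
    tree: LinkageTree

    def report(self) -> dict:
        return {
            "n_input_trials": self.n_input,
            "n_fast_guesses_excluded": self.n_fast_guesses,
            "pct_fast_guesses": 100.0 * self.n_fast_guesses / self.n_input if self.n_input else 0.0,
            "winsorize_mean_s": self.winsorize.mean,
            "winsorize_sd_s": self.winsorize.sd,
            "winsorize_k": self.winsorize.k,
            "n_winsorize_clamped": self.winsorize.n_clamped,
            "pct_winsorize_clamped": self.winsorize.pct_clamped,
            "symmetrization": "arithmetic mean of the two ordered inverse effective RTs",
        }


def search_pipeline(
    trials: Sequence[TrialRecord],
    styles: StyleSet,
    *,
    fast_guess_threshold: float = 0.150,
    winsorize_k: float = 3.5,
    rt_correct_only: bool = False,
    asymmetry_threshold: float = 0.0,
    weighted_linkage: bool = False,
) -> SearchResult:
    """Run the full search analysis: cleaning → matrices → distances → tree.

    Missing cells (no trials for an ordered pair) propagate as NaN and make
    the clustering step fail with an error naming the pair.
    """
    n_input = len(trials)
    retained, n_fast = exclude_fast_guesses(trials, fast_guess_threshold)
    clean, wreport = winsorize_rts(retained, winsorize_k)
    acc = accuracy_matrix(clean, styles)
    rts = rt_matrix(clean, styles, correct_only=rt_correct_only)
    eff = effective_rt(rts, acc)
    dist = distance_from_effective_rt(eff)
    asym, edges = asymmetry_matrix(eff, asymmetry_threshold)
    tree = average_linkage(dist, weighted=weighted_linkage)
    return SearchResult(
        styles=styles,
        n_input=n_input,
        n_fast_guesses=n_fast,
        winsorize=wreport,
        accuracy=acc,
        mean_rt=rts,
        effective=eff,
        distance=dist,
        asymmetry=asym,
        edges=edges,
        tree=tree,
    )
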