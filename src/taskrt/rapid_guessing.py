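"""Rapid-guessing detection from conditional proportion correct.

Rapid guessers answer much faster than solution-behavior respondents
and score near the chance level implied by the item format.  For each
item this module evaluates the *conditional proportion correct* — the
accuracy among responses at or below each observed RT — and searches
for a time threshold below which accuracy sits at chance while accuracy
above it is clearly higher.  Cells faster than an item's threshold are
flagged as rapid guessing; if every item's flagged fraction is under
2%, rapid guessing is judged negligible for the dataset.

The threshold rule is an explicit, deterministic two-sided criterion
(see :func:`find_threshold`) replacing visual inspection: accuracy at
or below the threshold must be within ``margin`` of chance, and
accuracy above it at least ``2 * margin`` above chance.  Two guards
keep sampling noise from manufacturing thresholds on hard items, where
the cumulative-accuracy path can dip to chance by luck alone: candidate
thresholds are capped at a short-RT bound (default 10 s, comfortably
above the 6-8 s thresholds such procedures typically find), and the
below-threshold group's accuracy must be *significantly* below the
solution criterion by a one-sided binomial test.  The cumulative
(RT <= t) accuracy estimator is the default; a locally binned variant
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .data_model import TaskDataset, register_result

__all__ = [
    "ConditionalPC",
    "ThresholdDecision",
    "BehaviorFlags",
    "conditional_pc",
    "find_threshold",
    "classify_behavior",
    "run_rapid_guessing",
    "NEGLIGIBLE_FRACTION",
]

#: An item's flagged fraction must be strictly below this for the
#: overall verdict to be "negligible".
NEGLIGIBLE_FRACTION = 0.02

MIN_OBSERVATIONS = 20


@dataclass
class ConditionalPC:
    """Conditional proportion correct for one item.

    ``times`` are the deduplicated, sorted observed RTs; ``pc[k]`` is
    the proportion correct among responses with RT <= ``times[k]`` and
    ``counts[k]`` their number (non-decreasing).  ``display_cutoff`` is
    the item's 90th RT percentile, used only to truncate displays;
    statistics always use all data.  ``insufficient`` marks items with
    fewer than 20 observations.
    """

    item_id: int
    times: np.ndarray
    pc: np.ndarray
    counts: np.ndarray
    n: int
    n_correct: int
    display_cutoff: float
    insufficient: bool = False

    def display_mask(self) -> np.ndarray:
        return self.times <= self.display_cutoff


def conditional_pc(
    dataset: TaskDataset, item: int, binned: bool = False, n_bins: int = 20
) -> ConditionalPC:
    """Accuracy as a function of RT for one item (0-based index).

    Default estimator: cumulative proportion correct among responses
    with RT at or below each observed RT.  ``binned=True`` instead
    computes accuracy within ``n_bins`` equal-count RT bins, evaluated
    at the bin upper edges.
    """
    t = dataset.T[:, item]
    y = dataset.Y[:, item]
    n = t.size
    cutoff = float(np.quantile(t, 0.9))
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    if binned:
        edges = np.quantile(ts, np.linspace(0, 1, n_bins + 1)[1:])
        times, pcs, counts = [], [], []
        lo = -np.inf
        for e in np.unique(edges):
            m = (ts > lo) & (ts <= e)
            if m.sum() == 0:
                continue
            times.append(e)
            pcs.append(ys[m].mean())
            counts.append(int((ts <= e).sum()))
            lo = e
        times_arr = np.asarray(times)
        pc_arr = np.asarray(pcs)
        counts_arr = np.asarray(counts)
    else:
        cum_correct = np.cumsum(ys)
        cum_n = np.arange(1, n + 1)
        # last index of each distinct time -> cumulative stats at that time
        last = np.r_[np.nonzero(np.diff(ts))[0], n - 1]
        times_arr = ts[last]
        counts_arr = cum_n[last]
        pc_arr = cum_correct[last] / counts_arr
    return ConditionalPC(
        item_id=item + 1,
        times=times_arr,
        pc=pc_arr,
        counts=counts_arr,
        n=n,
        n_correct=int(y.sum()),
        display_cutoff=cutoff,
        insufficient=n < MIN_OBSERVATIONS,
    )


@register_result
@dataclass
class ThresholdDecision:
    """Per-item threshold search outcome.

    ``threshold`` is in seconds or ``None``; ``rationale`` is one of
    ``"found"``, ``"no-candidate"`` or ``"insufficient"``.
    """

    item_id: int
    threshold: float | None
    n_flagged: int
    fraction_flagged: float
    chance_pc: float
    rationale: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "item_id": self.item_id,
            "threshold": self.threshold,
            "n_flagged": self.n_flagged,
            "fraction_flagged": self.fraction_flagged,
            "chance_pc": self.chance_pc,
            "rationale": self.rationale,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ThresholdDecision":
        return cls(
            item_id=int(d["item_id"]),
            threshold=None if d["threshold"] is None else float(d["threshold"]),
            n_flagged=int(d["n_flagged"]),
            fraction_flagged=float(d["fraction_flagged"]),
            chance_pc=float(d["chance_pc"]),
            rationale=str(d["rationale"]),
        )


def find_threshold(
    cpc: ConditionalPC,
    chance_pc: float,
    margin: float = 0.1,
    solution_margin: float | None = None,
    min_flagged: int = 1,
    max_threshold: float = 10.0,
    alpha: float = 0.05,
) -> ThresholdDecision:
    """Largest time splitting chance-level from solution-level accuracy.

    The threshold t* is the largest grid time, at most ``max_threshold``
    seconds, such that accuracy among RT <= t* is at most
    ``chance_pc + margin`` while accuracy among RT > t* is at least
    ``chance_pc + solution_margin`` (default ``2 * margin``).  Both
    resulting groups must be non-empty (at least ``min_flagged``
    below), and the below group's correct count must be significantly
    below the solution criterion — a one-sided binomial test of
    p = ``chance_pc + solution_margin`` at level ``alpha`` — so that a
    chance dip in the cumulative-accuracy path of a genuinely hard item
    cannot manufacture a threshold.  Returns a no-threshold decision
    when no admissible time exists.
    """
    if solution_margin is None:
        solution_margin = 2.0 * margin
    if cpc.insufficient:
        return ThresholdDecision(
            item_id=cpc.item_id,
            threshold=None,
            n_flagged=0,
            fraction_flagged=0.0,
            chance_pc=chance_pc,
            rationale="insufficient",
        )
    n, total_correct = cpc.n, cpc.n_correct
    p_solution = min(chance_pc + solution_margin, 1.0)
    best: tuple[float, int] | None = None
    for k in range(cpc.times.size):
        t = float(cpc.times[k])
        if t > max_threshold:
            break
        n_below = int(cpc.counts[k])
        n_above = n - n_below
        if n_below < min_flagged or n_above < 1:
            continue
        pc_below = cpc.pc[k]
        pc_above = (total_correct - pc_below * n_below) / n_above
        if pc_below > chance_pc + margin or pc_above < p_solution:
            continue
        correct_below = int(round(pc_below * n_below))
        if stats.binom.cdf(correct_below, n_below, p_solution) >= alpha:
            continue
        best = (t, n_below)
    if best is None:
        return ThresholdDecision(
            item_id=cpc.item_id,
            threshold=None,
            n_flagged=0,
            fraction_flagged=0.0,
            chance_pc=chance_pc,
            rationale="no-candidate",
        )
    thr, n_flagged = best
    return ThresholdDecision(
        item_id=cpc.item_id,
        threshold=thr,
        n_flagged=n_flagged,
        fraction_flagged=n_flagged / n,
        chance_pc=chance_pc,
        rationale="found",
    )


@register_result
@dataclass
class BehaviorFlags:
    """Person-by-item solution vs rapid-guessing classification.

    ``flags[j, i]`` is True when person j's RT on item i falls strictly
    below that item's threshold.  ``verdict`` is "negligible" only when
    every item's flagged fraction is strictly below 2%.
    """

    flags: np.ndarray
    thresholds: list[float | None]
    per_item_fraction: np.ndarray
    overall_fraction: float
    verdict: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "flags": np.asarray(self.flags, dtype=int).tolist(),
            "thresholds": self.thresholds,
            "per_item_fraction": self.per_item_fraction.tolist(),
            "overall_fraction": self.overall_fraction,
            "verdict": self.verdict,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BehaviorFlags":
        return cls(
            flags=np.asarray(d["flags"], dtype=bool),
            thresholds=[None if t is None else float(t) for t in d["thresholds"]],
            per_item_fraction=np.asarray(d["per_item_fraction"], dtype=float),
            overall_fraction=float(d["overall_fraction"]),
            verdict=str(d["verdict"]),
        )


def classify_behavior(
    dataset: TaskDataset, decisions: list[ThresholdDecision]
) -> BehaviorFlags:
    """Flag cells faster than their item's threshold; report fractions.

    A cell is rapid guessing iff its item has a threshold and the RT is
    strictly below it.  The dataset verdict is "negligible" when every
    item's flagged fraction is strictly below 2%.
    """
    if len(decisions) != dataset.I:
        raise ValueError("one threshold decision required per item")
    flags = np.zeros((dataset.J, dataset.I), dtype=bool)
    thresholds: list[float | None] = []
    for i, dec in enumerate(decisions):
        thresholds.append(dec.threshold)
        if dec.threshold is not None:
            flags[:, i] = dataset.T[:, i] < dec.threshold
    per_item = flags.mean(axis=0)
    verdict = (
        "negligible" if np.all(per_item < NEGLIGIBLE_FRACTION) else "not negligible"
    )
    return BehaviorFlags(
        flags=flags,
        thresholds=thresholds,
        per_item_fraction=per_item,
        overall_fraction=float(flags.mean()),
        verdict=verdict,
    )


def run_rapid_guessing(
    dataset: TaskDataset,
    margin: float = 0.1,
    solution_margin: float | None = None,
    max_threshold: float = 10.0,
    alpha: float = 0.05,
    binned: bool = False,
) -> tuple[list[ConditionalPC], list[ThresholdDecision], BehaviorFlags]:
    """Full detection stage: conditional PC, thresholds, classification."""
    cpcs = [conditional_pc(dataset, i, binned=binned) for i in range(dataset.I)]
    decisions = [
        find_threshold(
            cpc,
            chance_pc=meta.chance_pc,
            margin=margin,
            solution_margin=solution_margin,
            max_threshold=max_threshold,
            alpha=alpha,
        )
        for cpc, meta in zip(cpcs, dataset.items)
    ]
    return cpcs, decisions, classify_behavior(dataset, decisions)
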