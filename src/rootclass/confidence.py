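"""Probability-tier confidence grading of per-root predictions.

The maximum class probability of each prediction is banded into seven
tiers — LLL, LL, L (low), M (medium), H, HH, HHH (high) — that partition
(0, 1].  Canonical right-closed bounds:

    (0, 0.400] LLL   (0.400, 0.500] LL   (0.500, 0.600] L
    (0.600, 0.700] M (0.700, 0.800] H    (0.800, 0.900] HH
    (0.900, 1.0] HHH

A "table-compatible" boundary mode moves the LL/L edge to 0.510, matching
the worked decision-example table in which max probabilities of 0.502 to
0.508 are graded LL.  Selecting only predictions above a high probability
threshold (default 0.9) lets a breeder retain root-type calls that are
nearly always correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIER_LABELS = ("LLL", "LL", "L", "M", "H", "HH", "HHH")
#: Upper edges of the seven right-closed tiers, canonical mode.
_CANONICAL_EDGES = (0.400, 0.500, 0.600, 0.700, 0.800, 0.900, 1.0)
_TABLE_EDGES = (0.400, 0.510, 0.600, 0.700, 0.800, 0.900, 1.0)


@dataclass(frozen=True)
class ConfidenceTier:
    """One tier: its label and half-open probability interval (lo, hi]."""

    label: str
    interval: tuple[float, float]


def _edges(mode: str) -> tuple[float, ...]:
    if mode == "canonical":
        return _CANONICAL_EDGES
    if mode == "table":
        return _TABLE_EDGES
    raise ValueError(f"unknown boundary mode {mode!r}")


def tiers(mode: str = "canonical") -> list[ConfidenceTier]:
    """The seven tiers partitioning (0, 1] under the given boundary mode."""
    edges = _edges(mode)
    lo = 0.0
    out = []
    for label, hi in zip(TIER_LABELS, edges):
        out.append(ConfidenceTier(label, (lo, hi)))
        lo = hi
    return out


def assign_tier(max_probability: float, mode: str = "canonical"
                ) -> ConfidenceTier:
    """Tier of a prediction's maximum class probability.

    Boundary values belong to the lower tier (intervals are right-closed).
    """
    p = float(max_probability)
    if not 0.0 < p <= 1.0:
        raise ValueError(f"max probability {p} outside (0, 1]")
    for tier in tiers(mode):
        if p <= tier.interval[1]:
            return tier
    raise AssertionError("unreachable: tiers partition (0, 1]")


def _max_probs(predictions) -> np.ndarray:
    out = []
    for p in predictions:
        out.append(p if isinstance(p, (int, float, np.floating))
                   else p.max_probability)
    return np.asarray(out, dtype=float)


def _predicted(predictions) -> np.ndarray:
    return np.asarray([p.predicted_class for p in predictions])


def bin_error_rates(predictions, truths, mode: str = "canonical"
                    ) -> pd.DataFrame:
    """Per-tier counts and incorrect fraction.

    One row per tier (including empty tiers, n = 0 with NaN fraction):
    columns tier, n, n_incorrect, fraction_incorrect.
    """
    truths = np.asarray(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    probs = _max_probs(predictions)
    pred_cls = _predicted(predictions)
    labels = [assign_tier(p, mode).label for p in probs]
    rows = []
    for t in TIER_LABELS:
        sel = np.array([lab == t for lab in labels])
        n = int(sel.sum())
        wrong = int(np.sum(pred_cls[sel] != truths[sel])) if n else 0
        rows.append({"tier": t, "n": n, "n_incorrect": wrong,
                     "fraction_incorrect": wrong / n if n else float("nan")})
    return pd.DataFrame(rows)


def select_high_confidence(predictions, threshold: float = 0.9, truths=None
                           ) -> tuple[np.ndarray, dict]:
    """Indices of predictions with max probability STRICTLY above threshold.

    The report gives the retention rate and, when truths are supplied, the
    accuracy within the retained subset.
    """
    if not (1.0 / 3.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (1/3, 1]")
    probs = _max_probs(predictions)
    selected = np.flatnonzero(probs > threshold)
    report = {"threshold": threshold, "n_total": len(probs),
              "n_selected": int(len(selected)),
              "retention_rate": len(selected) / len(probs) if len(probs) else 0.0}
    if truths is not None:
        truths = np.asarray(truths)
        pred_cls = _predicted(predictions)
        if len(selected):
            acc = float(np.mean(pred_cls[selected] == truths[selected]))
        else:
            acc = float("nan")
        report["subset_accuracy"] = acc
    return selected, report
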