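"""Prevalence classification of conditions by iterative rank-rank regression.

Conditions are ranked by mention frequency separately in each corpus
(fractional ranks, rank 1 = most frequent; the higher the rank, the less
prevalent). Conditions seen in only one corpus are assigned outright to the
class typical of that corpus. For conditions present in both, the dream
rank is regressed on the waking rank by ordinary least squares; a
condition's residual is its observed dream rank minus the fitted value, so
a large positive residual means the condition sits far less prominently in
dream reports than its waking prominence predicts — typical of waking
discussions — and a large negative residual marks conditions typical of
dreams. Residuals beyond ``k_sigma`` standard deviations of the current
residual mean are peeled off and the line is refit on the remainder,
repeating until an iteration removes nothing; what survives is the
"equally prevalent" class, the near-straight-line core of the rank-rank
scatter.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import linregress, rankdata

from .ingest import MentionRecord, ReportConditionSet

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyTableError",
    "RegressionIteration",
    "ClassificationResult",
    "count_frequencies",
    "count_mention_frequencies",
    "count_report_frequencies",
    "rank_conditions",
    "classify_conditions",
]

#: Final three-way prevalence classes.
CLASSES = ("TYPICAL_WAKING", "EQUAL", "TYPICAL_DREAM")

_SIGMA_FLOOR = 1e-12


class EmptyTableError(ValueError):
    """Raised when a frequency table is requested from empty input."""


def count_mention_frequencies(mentions: Iterable[MentionRecord]) -> dict[str, int]:
    """Raw mention counts: every mention record contributes one count."""
    counts = Counter(m.condition for m in mentions)
    if not counts:
        raise EmptyTableError("no mentions to count")
    return dict(counts)


def count_report_frequencies(reports: Iterable[ReportConditionSet]) -> dict[str, int]:
    """Number-of-reports-containing counts: presence in a report counts once."""
    counts: Counter[str] = Counter()
    for rep in reports:
        counts.update(rep.conditions)
    if not counts:
        raise EmptyTableError("no report conditions to count")
    return dict(counts)


def count_frequencies(
    items: Sequence[MentionRecord] | Sequence[ReportConditionSet],
) -> dict[str, int]:
    """Dispatch to the mention or report counting rule by element type."""
    if not items:
        raise EmptyTableError("empty input")
    if isinstance(items[0], ReportConditionSet):
        return count_report_frequencies(items)  # type: ignore[arg-type]
    return count_mention_frequencies(items)  # type: ignore[arg-type]


def rank_conditions(counts: Mapping[str, int]) -> dict[str, float]:
    """Fractional descending-frequency ranks.

    Rank 1 is the most frequent condition; tied counts share the mean of
    the positions they span, so the ranking is deterministic regardless of
    dict ordering.
    """
    if not counts:
        return {}
    conditions = sorted(counts)
    values = np.array([counts[c] for c in conditions], dtype=float)
    if np.any(values < 1):
        raise ValueError("ranks are defined only for conditions with count >= 1")
    ranks = rankdata(-values, method="average")
    return {c: float(r) for c, r in zip(conditions, ranks)}


@dataclass(frozen=True)
class RegressionIteration:
    """One pass of the fit-residual-trim loop."""

    slope: float
    intercept: float
    mu: float
    sigma: float
    removed_waking: frozenset[str]
    removed_dreams: frozenset[str]
    n_remaining: int


@dataclass
class ClassificationResult:
    """Per-condition class and provenance plus the full iteration trace."""

    class_of: dict[str, str]
    provenance: dict[str, str]
    iterations: list[RegressionIteration] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = Counter(self.class_of.values())
        return {c: counts.get(c, 0) for c in CLASSES}

    def provenance_counts(self) -> dict[str, int]:
        return dict(Counter(self.provenance.values()))


def classify_conditions(
    rank_waking: Mapping[str, float],
    rank_dreams: Mapping[str, float],
    k_sigma: float = 1.5,
    r2_stop: float = 0.95,
) -> ClassificationResult:
    """Partition conditions into the three prevalence classes.

    Parameters
    ----------
    rank_waking, rank_dreams
        Fractional rank per condition in each corpus; a condition absent
        from a corpus is simply absent from that mapping.
    k_sigma
        Residual trimming threshold in units of the per-iteration residual
        standard deviation (default 1.5).
    r2_stop
        Goodness-of-fit level at which the surviving points count as an
        "almost straight line" and trimming stops (default 0.95). Set to
        1.0 to disable and trim until an iteration removes nothing.

    Conditions present in only one corpus are labeled with that corpus's
    typical class and flagged ``waking_only`` / ``dream_only``. On the
    shared conditions, each iteration fits dream rank against waking rank
    by OLS, computes residuals ``res = r_dreams − fitted``, their mean μ
    and standard deviation σ over the surviving points, removes conditions
    with ``res − μ ≥ k_sigma·σ`` as TYPICAL_WAKING and
    ``res − μ ≤ −k_sigma·σ`` as TYPICAL_DREAM, and refits. The loop stops
    when the surviving points already fit an almost straight line
    (R² ≥ ``r2_stop``), when an iteration removes nothing, or when σ
    collapses to zero (the degenerate exactly-straight line); the
    survivors are EQUAL. Without the goodness-of-fit stop, repeated ±kσ
    trimming on any noisy scatter keeps removing the tails of the residual
    distribution long after the outliers are gone, eroding the equally
    prevalent class to a handful of points.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    if not (0 < r2_stop <= 1):
        raise ValueError("r2_stop must lie in (0, 1]")
    class_of: dict[str, str] = {}
    provenance: dict[str, str] = {}
    waking_set = set(rank_waking)
    dream_set = set(rank_dreams)
    for cond in waking_set - dream_set:
        class_of[cond] = "TYPICAL_WAKING"
        provenance[cond] = "waking_only"
    for cond in dream_set - waking_set:
        class_of[cond] = "TYPICAL_DREAM"
        provenance[cond] = "dream_only"

    shared = sorted(waking_set & dream_set)
    for cond in shared:
        provenance[cond] = "both_corpora"

    iterations: list[RegressionIteration] = []
    if len(shared) < 3:
        if shared:
            warnings.warn(
                f"only {len(shared)} conditions shared between corpora; "
                "regression loop skipped, shared conditions labeled EQUAL",
                stacklevel=2,
            )
        for cond in shared:
            class_of[cond] = "EQUAL"
        return ClassificationResult(class_of, provenance, iterations)

    remaining = list(shared)
    max_iter = len(shared)  # each productive iteration removes >= 1 point
    for _ in range(max_iter):
        x = np.array([rank_waking[c] for c in remaining])
        y = np.array([rank_dreams[c] for c in remaining])
        if len(remaining) < 3 or np.ptp(x) == 0:
            break
        fit = linregress(x, y)
        res = y - (fit.slope * x + fit.intercept)
        mu = float(res.mean())
        sigma = float(res.std(ddof=0))
        if fit.rvalue**2 >= r2_stop:
            # survivors already lie on an almost straight line
            iterations.append(
                RegressionIteration(
                    float(fit.slope), float(fit.intercept), mu, sigma,
                    frozenset(), frozenset(), len(remaining),
                )
            )
            break
        if sigma <= _SIGMA_FLOOR:
            iterations.append(
                RegressionIteration(
                    float(fit.slope), float(fit.intercept), mu, sigma,
                    frozenset(), frozenset(), len(remaining),
                )
            )
            break
        z = res - mu
        hi = z >= k_sigma * sigma
        lo = z <= -k_sigma * sigma
        removed_waking = frozenset(c for c, m in zip(remaining, hi) if m)
        removed_dreams = frozenset(c for c, m in zip(remaining, lo) if m)
        n_remaining = len(remaining) - len(removed_waking) - len(removed_dreams)
        iterations.append(
            RegressionIteration(
                float(fit.slope), float(fit.intercept), mu, sigma,
                removed_waking, removed_dreams, n_remaining,
            )
        )
        if not removed_waking and not removed_dreams:
            break
        for cond in removed_waking:
            class_of[cond] = "TYPICAL_WAKING"
        for cond in removed_dreams:
            class_of[cond] = "TYPICAL_DREAM"
        remaining = [c for c in remaining if c not in removed_waking and c not in removed_dreams]
        if not remaining:
            break

    for cond in remaining:
        class_of[cond] = "EQUAL"
    return ClassificationResult(class_of, provenance, iterations)
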