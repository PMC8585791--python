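"""Group-level statistics.

Per-network pair scores are averaged within each surgery group (the
group-wise coefficient G), and the groups are compared with a Welch
(unequal-variance) t-test, one-tailed by default with the alternative that
the minimally invasive group preserves connectivity better (higher c).
Baseline categorical characteristics are compared with the two-tailed Fisher
exact test (point-probability rule).  No multiple-testing correction is
applied by default; an optional Holm adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compare import HEMISPHERE, NETWORK_ORDER, PairScore
from .errors import ValidationError, ZeroVarianceError


@dataclass(frozen=True)
class GroupComparison:
    """Welch comparison of one network's pair scores between two groups."""

    network: str
    G_a: float
    G_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p: float
    alternative: str


def groupwise_mean(scores: Sequence[PairScore]) -> float:
    """Arithmetic mean of one group's pair scores for a single network."""
    if len(scores) == 0:
        raise ValidationError("cannot average an empty score set")
    networks = {s.network for s in scores}
    if len(networks) > 1:
        raise ValidationError(
            f"scores mix networks {sorted(networks)}; group-wise means are "
            "per network"
        )
    return float(np.mean([s.c for s in scores]))


def welch_t(
    a: Sequence[float],
    b: Sequence[float],
    tails: str = "one",
    alternative: str = "b_greater",
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test between samples ``a`` and ``b``.

    Returns ``(t, df, p)`` where ``t = (mean_b - mean_a) / se`` under
    ``alternative="b_greater"`` (sign flipped for ``"a_greater"``), ``df``
    is the Welch–Satterthwaite approximation, and ``p`` is the upper-tail
    probability for one-tailed tests or twice the smaller tail for
    two-tailed tests.
    """
    if tails not in ("one", "two"):
        raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")
    if alternative not in ("b_greater", "a_greater"):
        raise ValidationError(
            f"alternative must be 'b_greater' or 'a_greater', got {alternative!r}"
        )
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ZeroVarianceError(
            "both samples have zero variance; the t statistic is undefined"
        )
    first, second = (y, x) if alternative == "b_greater" else (x, y)
    res = sps.ttest_ind(
        first, second, equal_var=False,
        alternative="greater" if tails == "one" else "two-sided",
    )
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-tailed Fisher exact p for a 2 x 2 table (point-probability rule).

    The p-value is the total hypergeometric probability, at fixed margins,
    of every table no more probable than the observed one.
    """
    counts = np.asarray(table)
    if counts.shape != (2, 2):
        raise ValidationError(f"expected a 2 x 2 table, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValidationError("contingency counts must be non-negative")
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("contingency counts must be integers")
    counts = counts.astype(int)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("every margin must have a positive total")
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def compare_groups(
    network: str,
    scores_a: Sequence[PairScore],
    scores_b: Sequence[PairScore],
    tails: str = "one",
    alternative: str = "b_greater",
) -> GroupComparison:
    """Group-wise means and the Welch comparison for one network."""
    G_a = groupwise_mean(scores_a)
    G_b = groupwise_mean(scores_b)
    t, df, p = welch_t(
        [s.c for s in scores_a], [s.c for s in scores_b],
        tails=tails, alternative=alternative,
    )
    return GroupComparison(
        network=network, G_a=G_a, G_b=G_b,
        n_a=len(scores_a), n_b=len(scores_b),
        t_statistic=t, df=df, p=p, alternative=alternative,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def build_results_table(
    scores: Sequence[PairScore],
    groups: Mapping[str, str],
    group_a: str = "craniotomy",
    group_b: str = "LITT",
    roi_counts: Mapping[str, int] | None = None,
    tails: str = "one",
    alternative: str = "b_greater",
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-network results: group-wise G values and the Welch comparison.

    One row per scored network, hemisphere first then the canonical network
    order.  ``groups`` maps subject_id to its surgery-group label; every
    subject must carry a score for every scored network.  ``adjust="holm"``
    appends a Holm-adjusted p column across the per-network rows (the
    hemisphere row is the primary analysis and is not part of that family).
    """
    if adjust not in ("none", "holm"):
        raise ValidationError(f"adjust must be 'none' or 'holm', got {adjust!r}")
    by_network: dict[str, list[PairScore]] = {}
    subjects: set[str] = set()
    for s in scores:
        if s.subject_id not in groups:
            raise ValidationError(f"subject {s.subject_id!r} missing from group map")
        by_network.setdefault(s.network, []).append(s)
        subjects.add(s.subject_id)

    networks = [HEMISPHERE] + [n for n in NETWORK_ORDER if n in by_network]
    if HEMISPHERE not in by_network:
        networks = networks[1:]

    rows = []
    for network in networks:
        net_scores = by_network[network]
        have = {s.subject_id for s in net_scores}
        missing = subjects - have
        if missing:
            raise ValidationError(
                f"network {network!r}: missing scores for subject(s) "
                f"{sorted(missing)}"
            )
        a = [s for s in net_scores if groups[s.subject_id] == group_a]
        b = [s for s in net_scores if groups[s.subject_id] == group_b]
        if not a or not b:
            raise ValidationError(
                f"network {network!r}: empty group "
                f"({group_a}: {len(a)}, {group_b}: {len(b)})"
            )
        try:
            cmp = compare_groups(network, a, b, tails=tails, alternative=alternative)
        except ZeroVarianceError as exc:
            raise ZeroVarianceError(f"network {network!r}: {exc}") from exc
        rows.append(
            {
                "network": network,
                "n_rois": (roi_counts or {}).get(network, np.nan),
                f"G_{group_a}": cmp.G_a,
                f"G_{group_b}": cmp.G_b,
                f"n_{group_a}": cmp.n_a,
                f"n_{group_b}": cmp.n_b,
                "t": cmp.t_statistic,
                "df": cmp.df,
                "p": cmp.p,
            }
        )
    frame = pd.DataFrame(rows)
    if adjust == "holm" and len(frame):
        mask = frame["network"] != HEMISPHERE
        adj = np.full(len(frame), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = holm_adjust(frame.loc[mask, "p"].to_numpy())
        frame["p_holm"] = adj
    return frame
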