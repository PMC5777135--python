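"""Per-larva response counts and the ChR2+ vs control group comparison.

The headline comparison is a classical (pooled-variance) unpaired Student's
t-test on per-larva counts of inhibited (or excited) neurons, two-tailed,
significant below alpha = 0.05.  A Shapiro-Wilk normality check is reported
alongside but never gates the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

GROUPS = ("chr2", "control")


@dataclass
class LarvaSummary:
    larva_id: str
    group: str
    n_rois_total: int
    n_excited: int
    n_inhibited: int
    pulse_kind: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if min(self.n_rois_total, self.n_excited, self.n_inhibited) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_excited + self.n_inhibited > self.n_rois_total:
            raise ValueError("class counts exceed total ROI count")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_counts(
    classifications: Sequence,
    larva_id: str,
    group: str,
    pulse_kind: str,
) -> LarvaSummary:
    """Tally one larva's final labels into a summary record."""
    labels = [c.label for c in classifications]
    return LarvaSummary(
        larva_id=larva_id,
        group=group,
        n_rois_total=len(labels),
        n_excited=labels.count("excited"),
        n_inhibited=labels.count("inhibited"),
        pulse_kind=pulse_kind,
    )


@dataclass
class GroupComparison:
    metric: str
    group_means: dict
    group_sems: dict
    group_n: dict
    t_statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float
    normality_p: dict            # group -> Shapiro-Wilk p (NaN if n < 3)
    degenerate: bool = False     # zero variance in both groups, equal means

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_means": self.group_means,
            "group_sems": self.group_sems,
            "group_n": self.group_n,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "normality_p": self.normality_p,
            "degenerate": self.degenerate,
        }


def _metric_values(summaries: Iterable[LarvaSummary], metric: str,
                   normalize: bool) -> dict[str, np.ndarray]:
    attr = {"excited": "n_excited", "inhibited": "n_inhibited"}.get(metric)
    if attr is None:
        raise ValueError("metric must be 'excited' or 'inhibited'")
    values: dict[str, list[float]] = {g: [] for g in GROUPS}
    for s in summaries:
        v = float(getattr(s, attr))
        if normalize:
            v = v / s.n_rois_total if s.n_rois_total else 0.0
        values[s.group].append(v)
    return {g: np.asarray(v, dtype=np.float64) for g, v in values.items()}


def compare_groups(
    summaries: Sequence[LarvaSummary],
    metric: str = "inhibited",
    alpha: float = 0.05,
    normalize: bool = False,
) -> GroupComparison:
    """Pooled-variance two-sample two-tailed t-test on per-larva counts.

    With ``normalize=True`` counts are divided by each larva's total ROI
    count before testing.  Zero variance in both groups with equal means is
    reported as t = 0, p = 1 with the ``degenerate`` flag set.
    """
    values = _metric_values(summaries, metric, normalize)
    a, b = values["chr2"], values["control"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two larvae per group")
    zero_var = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    degenerate = zero_var and a.mean() == b.mean()
    if degenerate:
        t_stat, p_val = 0.0, 1.0
    elif zero_var:
        # perfectly separated constant groups: the pooled variance vanishes
        # and the statistic diverges; report the smallest representable p
        t_stat = math.copysign(math.inf, a.mean() - b.mean())
        p_val = float(np.finfo(float).tiny)
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p_val = float(t_stat), float(p_val)
    normality = {}
    for g, v in values.items():
        if len(v) >= 3 and np.ptp(v) > 0:
            normality[g] = float(stats.shapiro(v).pvalue)
        else:
            normality[g] = float("nan")
    sems = {g: (float(stats.sem(v)) if len(v) > 1 else float("nan"))
            for g, v in values.items()}
    return GroupComparison(
        metric=metric,
        group_means={g: float(v.mean()) for g, v in values.items()},
        group_sems=sems,
        group_n={g: int(len(v)) for g, v in values.items()},
        t_statistic=t_stat,
        df=len(a) + len(b) - 2,
        p_value=p_val,
        significant=bool(p_val < alpha),
        alpha=alpha,
        normality_p=normality,
        degenerate=degenerate,
    )


def null_rejection_rate(
    n_cohorts: int = 500,
    n_per_group: int = 6,
    n_cells: int = 100,
    inhibited_fraction: float = 0.08,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the group test on null cohorts.

    Both groups' per-larva inhibited counts are drawn from the same
    generative model (binomial over ``n_cells`` with an equal planted
    inhibited fraction), so every rejection is a false positive.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_cohorts):
        counts = rng.binomial(n_cells, inhibited_fraction, size=2 * n_per_group)
        summaries = [
            LarvaSummary(
                larva_id=f"{g}_{i}", group=g, n_rois_total=n_cells,
                n_excited=0, n_inhibited=int(c), pulse_kind="long",
            )
            for i, (g, c) in enumerate(
                zip(["chr2"] * n_per_group + ["control"] * n_per_group, counts)
            )
        ]
        if compare_groups(summaries, "inhibited", alpha=alpha).significant:
            rejections += 1
    return rejections / n_cohorts
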