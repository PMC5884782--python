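"""Cohort summaries and hypothesis tests.

Mirrors the reporting conventions of clinical dosimetry tables: values as
mean +/- sample SD, a one-way ANOVA across the head/body/tail groups for
each metric, unadjusted Fisher-LSD pairwise comparisons (Bonferroni
available as an option), and a paired t test for pre/post cognitive scores.
Two-tailed P < 0.050 counts as significant. Cells whose group mean is zero
are excluded from testing and flagged with the "—" skip marker, matching
the table convention for untestable all-zero dose-volume cells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateVarianceError, ParameterError

#: marker used in report tables for skipped tests
SKIP_MARKER = "—"

#: two-tailed significance threshold
ALPHA = 0.050

PosthocMethod = Literal["lsd", "bonferroni"]


@dataclass
class GroupSamples:
    """Per-group value vectors (one value per patient) for group tests."""

    labels: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __init__(self, labels: Sequence[str], values: Sequence[Sequence[float]]):
        if len(labels) != len(values):
            raise ValueError("labels and values must have equal length")
        if len(labels) < 2:
            raise ValueError("at least 2 groups required")
        self.labels = tuple(labels)
        self.values = tuple(np.asarray(v, dtype=float) for v in values)
        for lab, v in zip(self.labels, self.values):
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"group {lab!r} needs n >= 2 for variance-based tests")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {lab!r} contains non-finite values")


@dataclass
class PairedScores:
    """Pre/post per-patient score vectors for the paired t test."""

    pre: np.ndarray
    post: np.ndarray

    def __init__(self, pre: Sequence[float], post: Sequence[float]):
        self.pre = np.asarray(pre, dtype=float)
        self.post = np.asarray(post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1 or self.pre.size < 2:
            raise ValueError("pre and post must be equal-length vectors of length >= 2")
        if not (np.all(np.isfinite(self.pre)) and np.all(np.isfinite(self.post))):
            raise ValueError("scores must be finite")


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator).

    For a single value the SD is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("summarize requires at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return mean, sd


def one_way_anova(groups: GroupSamples) -> tuple[float, float]:
    """Classical one-way ANOVA F and two-tailed p across the groups.

    All values identical returns (0, 1). Zero within-group variance with
    unequal means is degenerate (F would be infinite) and raises.
    """
    vals = groups.values
    grand = np.concatenate(vals)
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in vals)
    means = [v.mean() for v in vals]
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return 0.0, 1.0
        raise DegenerateVarianceError("zero within-group variance with unequal group means")
    ssb = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in vals)
    if ssb == 0.0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*vals)
    return float(f), float(p)


def _pooled_msw(groups: GroupSamples) -> tuple[float, int]:
    ssw = sum(float(((v - v.mean()) ** 2).sum()) for v in groups.values)
    df = sum(v.size for v in groups.values) - len(groups.values)
    return ssw / df, df


def pairwise_tests(
    groups: GroupSamples, method: PosthocMethod = "lsd"
) -> dict[frozenset[str], float]:
    """Pairwise comparisons between all group pairs.

    Fisher-LSD style: t = (mean_i - mean_j) / sqrt(MSW * (1/n_i + 1/n_j))
    on the pooled within-group mean square and its N-k degrees of freedom,
    with no multiplicity adjustment; ``method="bonferroni"`` multiplies each
    p by the number of pairs (capped at 1). Keys are unordered label pairs.
    """
    if method not in ("lsd", "bonferroni"):
        raise ParameterError(f"unknown post-hoc method {method!r}")
    msw, df = _pooled_msw(groups)
    n_pairs = math.comb(len(groups.labels), 2)
    out: dict[frozenset[str], float] = {}
    for (la, va), (lb, vb) in itertools.combinations(zip(groups.labels, groups.values), 2):
        delta = float(va.mean() - vb.mean())
        if msw == 0.0:
            if delta == 0.0:
                p = 1.0
            else:
                raise DegenerateVarianceError("zero pooled variance with unequal means")
        else:
            t = delta / math.sqrt(msw * (1.0 / va.size + 1.0 / vb.size))
            p = float(2.0 * sps.t.sf(abs(t), df))
        if method == "bonferroni":
            p = min(1.0, p * n_pairs)
        out[frozenset((la, lb))] = p
    return out


def paired_t(scores: PairedScores) -> tuple[float, float]:
    """Paired t test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1, two-tailed p.

    All-zero differences return (0, 1); zero-variance differences with a
    nonzero mean are degenerate and raise.
    """
    diff = scores.pre - scores.post
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() == 0.0:
            return 0.0, 1.0
        raise DegenerateVarianceError("zero-variance paired differences with nonzero mean")
    t, p = sps.ttest_rel(scores.pre, scores.post)
    return float(t), float(p)


def significance_flag(p: float) -> bool:
    """True iff p < 0.050 (strict, two-tailed convention)."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p must lie in [0, 1], got {p}")
    return p < ALPHA
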