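"""Competitive-fitness estimation from flow-cytometry timecourses.

A query strain is co-cultured with a fluorescent reference and the two are
counted by flow cytometry every ~10 generations.  Under constant selection
the natural-log count ratio changes linearly with generation,

    ln(query/reference) at generation g = intercept + s * g,

so the per-generation selection coefficient s is the OLS slope of the log
ratio on generation.  The slope is intercept-free, so the estimate does
not depend on the initial mixing ratio (1:1 or 50:1).  Deleterious query
strains give negative s.  Results are reported in percent per generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FlowCountTimecourse",
    "FitnessEstimate",
    "estimate_fitness",
    "pool_replicates",
    "anova_tukey",
]


@dataclass
class FlowCountTimecourse:
    replicate: str
    genotype: str
    generations: Sequence[float]
    query_counts: Sequence[int]
    reference_counts: Sequence[int]

    def __post_init__(self) -> None:
        g = list(self.generations)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("generations must be strictly increasing")
        if len(g) != len(self.query_counts) or len(g) != len(self.reference_counts):
            raise ValueError("generations and counts must have equal length")
        if any(c < 0 for c in self.query_counts) or any(c < 0 for c in self.reference_counts):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "list[FlowCountTimecourse]":
        """Split a tidy table (replicate, genotype, generation, query_count,
        reference_count) into one timecourse per (replicate, genotype)."""
        out = []
        for (rep, gt), sub in df.groupby(["replicate", "genotype"], sort=True):
            sub = sub.sort_values("generation")
            out.append(
                cls(
                    replicate=str(rep),
                    genotype=str(gt),
                    generations=sub["generation"].to_numpy(dtype=float),
                    query_counts=sub["query_count"].to_numpy(dtype=int),
                    reference_counts=sub["reference_count"].to_numpy(dtype=int),
                )
            )
        return out


@dataclass
class FitnessEstimate:
    genotype: str
    s_percent: float  # mean selection coefficient, percent per generation
    ci95_half_width: float  # percent; NaN when <2 replicates
    n_replicates: int


def estimate_fitness(tc: FlowCountTimecourse) -> float:
    """Selection coefficient in percent per generation for one timecourse.

    OLS slope of ln(query/reference) on generation, times 100.  Timepoints
    where either count is zero carry no usable ratio and are dropped with
    a warning; at least two usable timepoints are required.
    """
    g = np.asarray(tc.generations, dtype=float)
    q = np.asarray(tc.query_counts, dtype=float)
    r = np.asarray(tc.reference_counts, dtype=float)
    usable = (q > 0) & (r > 0)
    if usable.sum() < len(g):
        logger.warning(
            "%s/%s: dropped %d timepoint(s) with a zero count",
            tc.replicate,
            tc.genotype,
            int(len(g) - usable.sum()),
        )
    if usable.sum() < 2:
        raise ValueError("need >= 2 timepoints with both counts > 0")
    log_ratio = np.log(q[usable] / r[usable])
    slope = stats.linregress(g[usable], log_ratio).slope
    return 100.0 * float(slope)


def pool_replicates(estimates: Sequence[float], genotype: str = "") -> FitnessEstimate:
    """Mean selection coefficient across replicates with a 95% t CI.

    Half-width = t(0.975, n-1) * sd / sqrt(n); NaN for a single replicate.
    """
    s = np.asarray(list(estimates), dtype=float)
    n = len(s)
    if n == 0:
        raise ValueError("no replicate estimates")
    if n >= 2:
        half = float(stats.t.ppf(0.975, n - 1) * s.std(ddof=1) / np.sqrt(n))
    else:
        half = float("nan")
        logger.warning("genotype %r has a single replicate; CI undefined", genotype)
    return FitnessEstimate(
        genotype=genotype, s_percent=float(s.mean()), ci95_half_width=half, n_replicates=n
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across genotype groups with Tukey HSD post hoc.

    Returns {"F", "p", "df_between", "df_within", "tukey": DataFrame with
    pairwise mean differences and adjusted p-values}.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = []
    for lab in labels:
        a = np.asarray(list(groups[lab]), dtype=float)
        if len(a) < 2:
            raise ValueError(f"group {lab!r} has <2 replicates")
        arrays.append(a)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations identical: no variance to partition
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
    df_between = len(labels) - 1
    df_within = sum(len(a) for a in arrays) - len(labels)
    with np.errstate(invalid="ignore"):
        res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": 1.0 if np.isnan(res.pvalue[i, j]) else float(res.pvalue[i, j]),
                }
            )
    return {
        "F": float(F),
        "p": float(p),
        "df_between": df_between,
        "df_within": df_within,
        "tukey": pd.DataFrame(rows),
    }
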