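"""Tetrad segregation models and the log-likelihood suppression test.

A diploid heterozygous for a deleterious allele and a candidate suppressor
(e.g. ``SEC53/sec53 PGM1/pgm1``) is sporulated and tetrads are dissected.
Each spore grows into a large colony (healthy) or a small/absent colony
(sick).  If the candidate is *not* a suppressor only the deleterious locus
segregates, so every tetrad shows a 2:2 large:small pattern and 50% of
spores form large colonies.  If the candidate *is* a (dominant-acting in
the spore) suppressor, two unlinked loci segregate and the tetrad types
PD:NPD:TT occur in the classic 1:1:4 ratio, which maps onto large:small
patterns 2:2, 3:1 and 4:0 in a 1:4:1 ratio, giving 75% large colonies
overall.

The suppression test compares the observed pattern counts under the two
hypotheses by a log-likelihood ratio.  Real dissections contain patterns
that are impossible under one hypothesis (a dead spore, a gene-conversion
event), so a small error probability ``epsilon`` assigns mass to the
otherwise-impossible patterns before the likelihoods are formed.

Dominance is resolved with a second dissection of a strain carrying an
integrated extra wild-type copy of the suppressor gene: a dominant
suppressor still rescues spores that carry a wild-type copy next to the
mutant allele, a recessive one does not.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Tuple

__all__ = [
    "TetradObservation",
    "SegregationModel",
    "SuppressionTestResult",
    "pattern_probs",
    "expected_large_fraction",
    "percent_large",
    "suppression_llr",
    "classify_dominance",
    "enumerate_two_locus_patterns",
]

Hypothesis = Literal["suppression", "non-suppression"]

#: Patterns in the fixed order used throughout: (2:2, 3:1, 4:0) large:small.
PATTERNS = ("2:2", "3:1", "4:0")

#: Sentinel magnitude used when epsilon = 0 makes an observed pattern
#: impossible under one hypothesis (likelihood zero).
LLR_INFINITE = math.inf


@dataclass
class TetradObservation:
    """Counts of dissected tetrads by large:small colony pattern."""

    n22: int = 0
    n31: int = 0
    n40: int = 0
    n_other: int = 0  # 1:3, 0:4, or tetrads with unscoreable spores
    design: Literal["standard", "integrated_PGM1"] = "standard"
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("n22", "n31", "n40", "n_other"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_tetrads(self) -> int:
        """Tetrads entering the likelihood (patterns 2:2, 3:1, 4:0)."""
        return self.n22 + self.n31 + self.n40

    def as_counts(self) -> Tuple[int, int, int]:
        return (self.n22, self.n31, self.n40)


@dataclass
class SegregationModel:
    hypothesis: Hypothesis
    epsilon: float = 0.01
    pattern_probs: Tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.pattern_probs = pattern_probs(self.hypothesis, self.epsilon)


@dataclass
class SuppressionTestResult:
    llr: float
    percent_large: float | None
    verdict: Literal["suppression", "non-suppression"]
    epsilon: float
    log_base: float
    n_tetrads: int


def _check_epsilon(epsilon: float) -> None:
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"epsilon must lie in [0, 0.5), got {epsilon}")


def pattern_probs(hypothesis: Hypothesis, epsilon: float = 0.01) -> Tuple[float, float, float]:
    """Probabilities of the (2:2, 3:1, 4:0) large:small patterns.

    Under suppression two unlinked loci segregate; the tetrad types
    PD:NPD:TT = 1:1:4 translate into large:small patterns in a 1:4:1
    ratio of 2:2, 3:1 and 4:0.  Under non-suppression a single locus
    segregates and every tetrad is 2:2.

    With ``epsilon > 0`` each pattern that has probability zero under the
    hypothesis receives probability ``epsilon`` and the remaining mass is
    spread over the possible patterns in their error-free proportions.

    Parameters
    ----------
    hypothesis
        ``"suppression"`` or ``"non-suppression"``.
    epsilon
        Error probability in [0, 0.5) absorbing biological noise
        (dead spores, gene conversion).  Default 0.01.
    """
    _check_epsilon(epsilon)
    if hypothesis == "suppression":
        base = (1 / 6, 4 / 6, 1 / 6)
    elif hypothesis == "non-suppression":
        base = (1.0, 0.0, 0.0)
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    n_zero = sum(1 for p in base if p == 0.0)
    if n_zero == 0 or epsilon == 0.0:
        return base
    scale = 1.0 - n_zero * epsilon
    return tuple(epsilon if p == 0.0 else p * scale for p in base)  # type: ignore[return-value]


def expected_large_fraction(hypothesis: Hypothesis, epsilon: float = 0.0) -> float:
    """Expected fraction of large-colony spores under a hypothesis.

    Error-free: 3/4 under suppression (1/6*1/2 + 4/6*3/4 + 1/6*1),
    1/2 under non-suppression.
    """
    p22, p31, p40 = pattern_probs(hypothesis, epsilon)
    return p22 * (2 / 4) + p31 * (3 / 4) + p40 * (4 / 4)


def enumerate_two_locus_patterns() -> Tuple[float, float, float]:
    """Brute-force (2:2, 3:1, 4:0) pattern frequencies for two unlinked loci.

    Enumerates every assortment of the two meiosis-II spore pairs at each
    locus.  Each locus yields two spore pairs; for unlinked loci, which
    pair of locus B lands with which pair of locus A — and the within-pair
    orientations after the second division — are equally likely.  A spore
    is "large" when it carries the wild-type deleterious-locus allele OR
    the suppressor allele.

    Serves as an independent check of :func:`pattern_probs`; not used by
    the likelihood code.
    """
    # Locus A (deleterious gene): spores carry A (wild type) or a (mutant).
    # Locus B (suppressor): B (suppressor allele) or b (wild type).
    # First-division orientation at each locus fixes which alleles share a
    # pole; second division splits each into two spores.  For two unlinked
    # loci the joint outcome is equivalent to independently permuting the
    # four spores' B alleles against the A alleles.
    a_alleles = ("A", "A", "a", "a")
    counts = {"2:2": 0, "3:1": 0, "4:0": 0}
    for b_perm in set(itertools.permutations(("B", "B", "b", "b"))):
        large = sum(
            1 for a, b in zip(a_alleles, b_perm) if a == "A" or b == "B"
        )
        small = 4 - large
        counts[f"{large}:{small}"] += 1
    total = sum(counts.values())
    return tuple(counts[p] / total for p in PATTERNS)  # type: ignore[return-value]


def percent_large(obs: TetradObservation) -> float:
    """Percentage of large colonies across all scored spores.

    Each tetrad contributes four spores; the pattern gives the number of
    large colonies.  Raw (unrounded) percentage is returned; for display
    round half-up to an integer, as colony counts are customarily quoted.
    """
    total = obs.n_tetrads
    if total == 0:
        raise ValueError("percent_large requires at least one scored tetrad")
    large = 2 * obs.n22 + 3 * obs.n31 + 4 * obs.n40
    return 100.0 * large / (4 * total)


def display_percent_large(obs: TetradObservation) -> int:
    """Half-up integer rounding of :func:`percent_large` for display."""
    return int(math.floor(percent_large(obs) + 0.5))


def suppression_llr(
    obs: TetradObservation,
    epsilon: float = 0.01,
    log_base: float = 10.0,
    tau: float = 2.0,
) -> SuppressionTestResult:
    """Log-likelihood ratio of suppression vs non-suppression.

    llr = sum over patterns of n_pattern * log(p|suppression / p|non-suppression).
    Positive values favor suppression.  Tetrads in ``n_other`` are excluded
    from the likelihood.

    With ``epsilon = 0`` an observed 3:1 or 4:0 tetrad has zero likelihood
    under non-suppression; the llr is then reported as a signed infinity
    with a warning rather than raising.
    """
    _check_epsilon(epsilon)
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    p_sup = pattern_probs("suppression", epsilon)
    p_non = pattern_probs("non-suppression", epsilon)
    counts = obs.as_counts()
    llr = 0.0
    ln_base = math.log(log_base)
    for n, ps, pn in zip(counts, p_sup, p_non):
        if n == 0:
            continue
        if pn == 0.0:
            warnings.warn(
                "observed pattern impossible under non-suppression with epsilon=0; "
                "llr is +infinity",
                stacklevel=2,
            )
            llr = LLR_INFINITE
            break
        if ps == 0.0:
            warnings.warn(
                "observed pattern impossible under suppression with epsilon=0; "
                "llr is -infinity",
                stacklevel=2,
            )
            llr = -LLR_INFINITE
            break
        llr += n * (math.log(ps) - math.log(pn)) / ln_base
    pct = percent_large(obs) if obs.n_tetrads > 0 else None
    verdict: Hypothesis = "suppression" if llr > tau else "non-suppression"
    return SuppressionTestResult(
        llr=llr,
        percent_large=pct,
        verdict=verdict,
        epsilon=epsilon,
        log_base=log_base,
        n_tetrads=obs.n_tetrads,
    )


def classify_dominance(
    llr_standard: float, llr_integrated: float, tau: float = 2.0
) -> str:
    """Classify a suppressor from paired dissections.

    ``llr_standard`` comes from the plain heterozygous diploid,
    ``llr_integrated`` from the design with an extra integrated wild-type
    copy of the suppressor gene, so that every spore carries a wild-type
    copy.  A dominant suppressor rescues in both designs; a recessive one
    only in the standard design.  Both ratios must use the same epsilon
    and log base.  ``tau`` is the decision threshold on the llr scale
    (default 2 in base 10, i.e. 100:1 odds).
    """
    if llr_standard > tau and llr_integrated > tau:
        return "dominant suppressor"
    if llr_standard > tau:
        return "recessive suppressor"
    return "non-suppressor"
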