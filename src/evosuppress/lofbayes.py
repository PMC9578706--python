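"""Bayesian LOF vs non-LOF classification from mutational spectra.

When adaptation works by destroying a gene's function (loss of function,
LOF), any disruptive mutation is selected, so the recovered spectrum mixes
missense with frameshift and nonsense changes.  When adaptation needs an
*altered* but functional protein (non-LOF), truncating mutations are not
recovered and the spectrum is almost purely missense.  Given training
genes with known selection mode, a gene's observed spectrum (n_missense,
n_truncating) updates a prior over the two modes into a posterior.

The likelihood is binomial in the missense fraction; the binomial
coefficient is identical under both hypotheses and is omitted from the
log-likelihoods (it cancels from every ratio and posterior).  All internal
logs are natural; reported log-likelihoods state their base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "SpectrumObservation",
    "SpectrumClassifierModel",
    "fit_model",
    "log_likelihoods",
    "posterior_non_lof",
]


@dataclass(frozen=True)
class SpectrumObservation:
    """Observed mutational spectrum of one gene."""

    n_missense: int
    n_truncating: int  # frameshift + nonsense
    gene: str = ""

    def __post_init__(self) -> None:
        if self.n_missense < 0 or self.n_truncating < 0:
            raise ValueError("spectrum counts must be >= 0")


@dataclass
class SpectrumClassifierModel:
    prior_lof: float
    prior_nonlof: float
    p_missense_given_lof: float
    p_missense_given_nonlof: float
    n_train_lof_genes: int = 0
    n_train_nonlof_genes: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.prior_lof + self.prior_nonlof - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        for name in ("p_missense_given_lof", "p_missense_given_nonlof"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")


def fit_model(
    lof_training: Sequence[SpectrumObservation],
    nonlof_training: Sequence[SpectrumObservation],
    pseudocount: float = 0.0,
) -> SpectrumClassifierModel:
    """Fit priors and class-conditional missense probabilities.

    The prior for each hypothesis is the fraction of training *genes* with
    that label.  The conditionals pool mutation counts within each label
    (every training spectrum weighted by its counts) and normalise, after
    adding ``pseudocount`` to each of the two classes.  With zero
    pseudocount a hypothesis whose pool lacks one class entirely yields a
    degenerate conditional and raises; use pseudocount 0.5 for sparse
    training data.
    """
    if not lof_training or not nonlof_training:
        raise ValueError("both training sets must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n_lof = len(lof_training)
    n_nonlof = len(nonlof_training)
    prior_lof = n_lof / (n_lof + n_nonlof)

    def pooled_p_missense(spectra: Sequence[SpectrumObservation], label: str) -> float:
        mis = sum(s.n_missense for s in spectra) + pseudocount
        trunc = sum(s.n_truncating for s in spectra) + pseudocount
        total = mis + trunc
        if total == 0:
            raise ValueError(f"{label} training pool has zero mutations and zero pseudocount")
        p = mis / total
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"{label} conditional degenerate (p_missense={p}); add a pseudocount"
            )
        return p

    return SpectrumClassifierModel(
        prior_lof=prior_lof,
        prior_nonlof=1.0 - prior_lof,
        p_missense_given_lof=pooled_p_missense(lof_training, "LOF"),
        p_missense_given_nonlof=pooled_p_missense(nonlof_training, "non-LOF"),
        n_train_lof_genes=n_lof,
        n_train_nonlof_genes=n_nonlof,
        provenance={
            "lof_genes": [s.gene for s in lof_training],
            "nonlof_genes": [s.gene for s in nonlof_training],
            "pseudocount": pseudocount,
        },
    )


def log_likelihoods(
    model: SpectrumClassifierModel, obs: SpectrumObservation
) -> tuple[float, float]:
    """Natural-log likelihoods (loglik_lof, loglik_nonlof) of a spectrum.

    loglik_H = n_missense*ln p(missense|H) + n_truncating*ln(1 - p(missense|H)).
    The binomial coefficient is omitted (identical under both hypotheses).
    """
    def ll(p_mis: float) -> float:
        return obs.n_missense * math.log(p_mis) + obs.n_truncating * math.log(1.0 - p_mis)

    return (ll(model.p_missense_given_lof), ll(model.p_missense_given_nonlof))


def posterior_non_lof(model: SpectrumClassifierModel, obs: SpectrumObservation) -> float:
    """Posterior probability that selection acts on non-LOF.

    Computed in log space: with a = ln prior_lof + loglik_lof and
    b = ln prior_nonlof + loglik_nonlof, the posterior is
    1 / (1 + exp(a - b)), numerically stable for extreme spectra.
    """
    ll_lof, ll_nonlof = log_likelihoods(model, obs)
    a = math.log(model.prior_lof) + ll_lof
    b = math.log(model.prior_nonlof) + ll_nonlof
    d = a - b
    if d > 0:
        return math.exp(-d) / (1.0 + math.exp(-d))
    return 1.0 / (1.0 + math.exp(d))


def posterior_lof(model: SpectrumClassifierModel, obs: SpectrumObservation) -> float:
    return 1.0 - posterior_non_lof(model, obs)


def model_to_dict(model: SpectrumClassifierModel) -> dict:
    return {
        "prior_lof": model.prior_lof,
        "prior_nonlof": model.prior_nonlof,
        "p_missense_given_lof": model.p_missense_given_lof,
        "p_missense_given_nonlof": model.p_missense_given_nonlof,
        "n_train_lof_genes": model.n_train_lof_genes,
        "n_train_nonlof_genes": model.n_train_nonlof_genes,
        "provenance": model.provenance,
    }


def model_from_dict(d: dict) -> SpectrumClassifierModel:
    return SpectrumClassifierModel(
        prior_lof=d["prior_lof"],
        prior_nonlof=d["prior_nonlof"],
        p_missense_given_lof=d["p_missense_given_lof"],
        p_missense_given_nonlof=d["p_missense_given_nonlof"],
        n_train_lof_genes=d.get("n_train_lof_genes", 0),
        n_train_nonlof_genes=d.get("n_train_nonlof_genes", 0),
        provenance=d.get("provenance", {}),
    )
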