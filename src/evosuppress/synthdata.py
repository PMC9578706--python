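"""Seeded synthetic-data generators for every downstream analysis stage.

Each generator emulates the statistical structure one analysis assumes —
not the biology underneath it:

* annotated per-clone mutation tables: Poisson mutation counts per clone
  with group-specific means, multinomial gene assignment over a gene
  universe with optional per-gene enrichment weights, effect classes drawn
  from a per-clone-class spectrum, and allele fractions of 1.0 (haploid)
  or 0.5 (autodiploid);
* tetrad dissections: multinomial pattern counts under the suppression or
  non-suppression hypothesis with error term epsilon;
* labeled mutational spectra for training the LOF/non-LOF classifier;
* flow-cytometry competition timecourses: binomial counts around an
  exponential lineage-ratio trajectory with a fixed selection coefficient;
* Michaelis-Menten rate tables with additive Gaussian noise truncated at
  zero (activities are nonnegative).

Reproducibility contract: one integer master seed; each generator draws
from an independent substream derived as ``SeedSequence([master_seed,
STREAM_ID])`` where STREAM_ID is a fixed per-generator integer.  Fixed
seed implies identical output across runs and platforms.  No global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tetrads import PATTERNS, TetradObservation, pattern_probs

__all__ = [
    "SimulationConfig",
    "gen_mutation_table",
    "gen_tetrads",
    "gen_spectrum",
    "gen_flow_counts",
    "gen_kinetics",
    "MUTATION_TABLE_COLUMNS",
]

# Fixed per-generator stream identifiers (order is part of the contract).
_STREAMS = {
    "mutations": 1,
    "tetrads": 2,
    "spectrum": 3,
    "flow": 4,
    "kinetics": 5,
}

MUTATION_TABLE_COLUMNS = [
    "clone_id",
    "group",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "allele_fraction",
]

#: Default yeast gene-universe size (verified ORFs plus dubious, the count
#: used by the genome-wide binomial tests).
GENE_UNIVERSE_SIZE = 5906

#: Default fraction of clones simulated as autodiploids (heterozygous
#: mutations at allele fraction 0.5); 131 of 188 sequenced clones.
AUTODIPLOID_FRACTION = 131 / 188


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Bundled parameters for a full synthetic-study run.

    ``groups`` maps a genotype label to (clone count, mean mutations per
    clone).  ``enriched_genes`` maps a gene name to a relative mutation
    weight (1.0 = background); unlisted genes get weight 1.  The spectrum
    is a probability pair (missense, frameshift/nonsense) applied to
    nonsynonymous mutations.
    """

    seed: int = 0
    groups: Sequence[tuple[str, int, float]] = field(
        default_factory=lambda: [("wt", 30, 6.49), ("mutant", 30, 5.76)]
    )
    gene_universe_size: int = GENE_UNIVERSE_SIZE
    enriched_genes: Mapping[str, float] = field(default_factory=dict)
    spectrum: tuple[float, float] = (0.8, 0.2)
    autodiploid_fraction: float = AUTODIPLOID_FRACTION
    tetrad_params: tuple[str, float, int] = ("suppression", 0.01, 10)
    fitness_params: tuple[float, Sequence[float], int] = (
        -0.2586,
        (0, 10, 20, 30, 40, 50),
        100_000,
    )
    kinetics_params: tuple[float, float, Sequence[float], float] = (
        10.0,
        0.1,
        (0.0125, 0.025, 0.05, 0.1, 0.2, 0.3, 0.45, 0.6),
        0.2,
    )

    def __post_init__(self) -> None:
        for label, n, mean in self.groups:
            if int(n) != n or n < 0:
                raise ValueError(f"clone count for group {label!r} must be a nonnegative integer")
            if mean < 0:
                raise ValueError(f"mean mutations per clone for group {label!r} must be >= 0")
        if not 0.0 <= self.autodiploid_fraction <= 1.0:
            raise ValueError("autodiploid_fraction must lie in [0, 1]")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must sum to 1")


def gen_mutation_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate an annotated mutation table, one row per mutation.

    Per-clone mutation counts are Poisson with the group mean (the count
    distribution is an assumption, not an observation; override by editing
    the table if another burden model is wanted).  Genes are drawn
    multinomially over ``gene_universe_size`` genes with the enrichment
    weights; effect classes from the configured spectrum; chromosome and
    position are arbitrary unique placeholders.  A configured fraction of
    clones are autodiploids whose mutations appear at allele fraction 0.5.
    """
    rng = _rng(cfg.seed, "mutations")
    genes = [f"GENE{i:04d}" for i in range(cfg.gene_universe_size)]
    weights = np.ones(cfg.gene_universe_size)
    name_to_idx = {g: i for i, g in enumerate(genes)}
    # Named enriched genes replace background slots from the top of the
    # universe (deterministic, keeps the universe size fixed).
    next_slot = cfg.gene_universe_size - 1
    for gene in sorted(cfg.enriched_genes):
        w = cfg.enriched_genes[gene]
        if w < 0:
            raise ValueError(f"enrichment weight for {gene!r} must be >= 0")
        if gene not in name_to_idx:
            genes[next_slot] = gene
            name_to_idx[gene] = next_slot
            next_slot -= 1
        weights[name_to_idx[gene]] = w
    probs = weights / weights.sum()

    p_mis, p_trunc = cfg.spectrum
    rows = []
    for label, n_clones, mean in cfg.groups:
        burdens = rng.poisson(mean, size=int(n_clones))
        diploid = rng.random(int(n_clones)) < cfg.autodiploid_fraction
        for c in range(int(n_clones)):
            clone_id = f"{label}_c{c:03d}"
            af = 0.5 if diploid[c] else 1.0
            k = int(burdens[c])
            if k == 0:
                continue
            gene_idx = rng.choice(cfg.gene_universe_size, size=k, p=probs)
            is_trunc = rng.random(k) < p_trunc
            trunc_kind = rng.random(k) < 0.5
            pos = rng.integers(1, 1_500_000, size=k)
            for j in range(k):
                effect = (
                    ("frameshift" if trunc_kind[j] else "nonsense")
                    if is_trunc[j]
                    else "missense"
                )
                rows.append(
                    (
                        clone_id,
                        label,
                        f"chr{int(gene_idx[j]) % 16 + 1:02d}",
                        int(pos[j]),
                        "A",
                        "T",
                        genes[int(gene_idx[j])],
                        effect,
                        af,
                    )
                )
    return pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)


def gen_tetrads(
    n: int,
    hypothesis: str,
    epsilon: float,
    seed: int,
    design: str = "standard",
) -> TetradObservation:
    """Draw pattern counts for ``n`` dissected tetrads.

    Counts are multinomial with the probabilities from
    :func:`evosuppress.tetrads.pattern_probs` for the hypothesis and error
    term; they sum to ``n``.
    """
    if n < 0 or int(n) != n:
        raise ValueError("tetrad count must be a nonnegative integer")
    probs = pattern_probs(hypothesis, epsilon)  # validates epsilon
    rng = _rng(seed, "tetrads")
    counts = rng.multinomial(int(n), probs)
    return TetradObservation(
        n22=int(counts[0]), n31=int(counts[1]), n40=int(counts[2]), design=design
    )


def gen_spectrum(
    gene_class: str,
    n: int,
    conditionals: Sequence[float],
    seed: int,
) -> tuple[str, int, int]:
    """Draw a labeled mutational spectrum: (class, n_missense, n_truncating).

    ``conditionals`` is the probability pair (missense, frameshift/nonsense)
    under the given selection class.
    """
    if n < 0 or int(n) != n:
        raise ValueError("mutation count must be a nonnegative integer")
    p = np.asarray(conditionals, dtype=float)
    if p.shape != (2,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("conditionals must be a 2-vector of probabilities summing to 1")
    rng = _rng(seed, "spectrum")
    n_mis = int(rng.binomial(int(n), p[0]))
    return (gene_class, n_mis, int(n) - n_mis)


def gen_flow_counts(
    s: float,
    generations: Sequence[float],
    depth: int,
    r0: float = 0.5,
    seed: int = 0,
    replicate: str = "r1",
    genotype: str = "query",
) -> pd.DataFrame:
    """Simulate a query-vs-reference competition timecourse.

    The latent log ratio follows ln(query/ref) = ln(r0/(1-r0)) + s*g; at
    each sampled generation ``depth`` cells are scored and the query count
    is binomial around the latent frequency.  Columns: replicate, genotype,
    generation, query_count, reference_count.
    """
    gens = list(generations)
    if not gens:
        raise ValueError("generations must be non-empty")
    if any(b <= a for a, b in zip(gens, gens[1:])):
        raise ValueError("generations must be strictly increasing")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 < r0 < 1.0:
        raise ValueError("r0 must lie in (0, 1)")
    rng = _rng(seed, "flow")
    logit0 = np.log(r0 / (1 - r0))
    g = np.asarray(gens, dtype=float)
    freq = 1.0 / (1.0 + np.exp(-(logit0 + s * g)))
    q = rng.binomial(int(depth), freq)
    return pd.DataFrame(
        {
            "replicate": replicate,
            "genotype": genotype,
            "generation": g,
            "query_count": q.astype(int),
            "reference_count": (int(depth) - q).astype(int),
        }
    )


def gen_kinetics(
    vmax: float,
    km: float,
    substrate_grid: Sequence[float],
    noise_sd: float,
    seed: int = 0,
    enzyme: str = "enzyme",
) -> pd.DataFrame:
    """Simulate specific-activity measurements on a substrate grid.

    rate = vmax*S/(km + S) + Normal(0, noise_sd), truncated at 0 because
    activities are nonnegative.  Columns: enzyme, substrate_mM, rate.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    S = np.asarray(list(substrate_grid), dtype=float)
    if (S < 0).any():
        raise ValueError("substrate concentrations must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "kinetics")
    rate = vmax * S / (km + S)
    if noise_sd > 0:
        rate = rate + rng.normal(0.0, noise_sd, size=S.shape)
    rate = np.clip(rate, 0.0, None)
    return pd.DataFrame({"enzyme": enzyme, "substrate_mM": S, "rate": rate})


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("clone_id", "group", "chrom", "ref", "alt", "gene", "effect")},
    )
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df
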