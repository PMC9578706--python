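"""Mutation recurrence and gene-set enrichment/depletion tests.

Under neutrality every nonsynonymous mutation is equally likely to land
in any of the G genes of the universe (yeast: 5906), so the count in any
single gene — or in a defined gene set of m genes — is binomial with
success probability 1/G (or m/G) over the N observed mutations.  Exact
binomial tails give enrichment (P(X >= k)) and depletion (P(X <= k))
p-values; genes hit more often than chance are candidate targets of
selection, and a curated set (e.g. the 24 Type 1 CDG homologs) can be
tested as a whole.  Independent experiments can be aggregated by summing
per-gene counts before testing, which gains power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneCountTable",
    "GeneSetTestResult",
    "geneset_test",
    "per_gene_recurrence",
    "aggregate",
    "counts_from_records",
]

#: Yeast gene-universe size used by the genome-wide binomial tests.
DEFAULT_UNIVERSE = 5906
#: Number of Type 1 CDG homolog genes in the curated set.
CDG_SET_SIZE = 24


@dataclass
class GeneCountTable:
    """Per-gene nonsynonymous mutation counts for one experiment/group."""

    counts: Mapping[str, int]
    universe_size: int = DEFAULT_UNIVERSE
    label: str = ""

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.counts.items() if c < 0 or int(c) != c}
        if bad:
            raise ValueError(f"negative or non-integer counts: {bad}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class GeneSetTestResult:
    observed: int
    trials: int
    set_size: int
    universe_size: int
    p_enrich: float
    p_deplete: float


def geneset_test(
    N: int,
    k: int,
    m: int = CDG_SET_SIZE,
    G: int = DEFAULT_UNIVERSE,
) -> GeneSetTestResult:
    """Exact binomial test for enrichment/depletion of mutations in a set.

    With N nonsynonymous mutations observed and a set of m genes out of G,
    the set count under neutrality is X ~ Binomial(N, m/G).
    p_enrich = P(X >= k); p_deplete = P(X <= k); exact tails.
    """
    if not (0 <= k <= N):
        raise ValueError(f"need 0 <= k <= N, got k={k}, N={N}")
    if not (0 < m <= G):
        raise ValueError(f"need 0 < m <= G, got m={m}, G={G}")
    p = m / G
    p_enrich = float(stats.binom.sf(k - 1, N, p)) if N > 0 else 1.0
    p_deplete = float(stats.binom.cdf(k, N, p)) if N > 0 else 1.0
    return GeneSetTestResult(
        observed=k,
        trials=N,
        set_size=m,
        universe_size=G,
        p_enrich=min(p_enrich, 1.0),
        p_deplete=min(p_deplete, 1.0),
    )


def per_gene_recurrence(
    table: GeneCountTable,
    weighting: str = "uniform",
    lengths: Mapping[str, float] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene enrichment p-values against the neutral binomial.

    Uniform weighting gives every gene probability 1/G; length weighting
    uses length/total-length, requiring a length for every counted gene.
    Benjamini-Hochberg q-values are optional and off by default.
    Returns a DataFrame (gene, count, p_enrich[, q]) sorted by p.
    """
    N = table.total
    G = table.universe_size
    genes = sorted(table.counts)
    if weighting == "uniform":
        w = {g: 1.0 / G for g in genes}
    elif weighting == "length":
        if lengths is None:
            raise ValueError("length weighting requires a gene-length table")
        missing = [g for g in genes if g not in lengths]
        if missing:
            raise ValueError(f"missing length for gene(s): {missing[:5]}")
        total_len = float(sum(lengths.values()))
        w = {g: lengths[g] / total_len for g in genes}
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = []
    for g in genes:
        k = int(table.counts[g])
        p = float(stats.binom.sf(k - 1, N, w[g])) if N > 0 else 1.0
        rows.append({"gene": g, "count": k, "p_enrich": min(p, 1.0)})
    df = pd.DataFrame(rows).sort_values(["p_enrich", "gene"], ignore_index=True)
    if bh_adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q"] = multipletests(df["p_enrich"], method="fdr_bh")[1]
    return df


def aggregate(tables: Sequence[GeneCountTable], label: str = "aggregate") -> GeneCountTable:
    """Sum per-gene counts across experiments sharing a gene universe."""
    if not tables:
        raise ValueError("nothing to aggregate")
    sizes = {t.universe_size for t in tables}
    if len(sizes) > 1:
        raise ValueError(f"conflicting universe sizes: {sorted(sizes)}")
    merged: dict[str, int] = {}
    for t in tables:
        for g, c in t.counts.items():
            merged[g] = merged.get(g, 0) + int(c)
    return GeneCountTable(counts=merged, universe_size=tables[0].universe_size, label=label)


def counts_from_records(
    records,
    group: str | None = None,
    universe_size: int = DEFAULT_UNIVERSE,
    collapse_identical: bool = False,
) -> GeneCountTable:
    """Build a GeneCountTable of nonsynonymous mutations from records.

    By default every mutation event counts (the same variant in two clones
    counts twice).  ``collapse_identical`` instead counts unique variants
    (chrom, pos, alt) once per group, the convention for displaying
    "unique nonsynonymous mutations" per gene.
    """
    from .variants import NONSYNONYMOUS

    counts: dict[str, int] = {}
    seen: set[tuple] = set()
    label = group or "all"
    for r in records:
        if group is not None and r.group != group:
            continue
        if r.effect not in NONSYNONYMOUS or not r.gene:
            continue
        if collapse_identical:
            key = (r.group, r.chrom, r.pos, r.alt)
            if key in seen:
                continue
            seen.add(key)
        counts[r.gene] = counts.get(r.gene, 0) + 1
    return GeneCountTable(counts=counts, universe_size=universe_size, label=label)
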