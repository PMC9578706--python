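"""Variant ingestion, effect classification, ploidy calling, and burden.

Consumes annotated variant calls for evolved clones — either the TSV
mutation-table dialect written by :mod:`evosuppress.synthdata` or a VCF
whose records carry SnpEff-style ``ANN`` annotations — and derives
per-clone profiles: effect-class counts, the nonsynonymous burden, and a
haploid/diploid call from allele fractions.  Spontaneous autodiploids are
recognised because their evolved mutations are heterozygous, sitting at
allele fraction ~0.5 instead of 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "CloneProfile",
    "EFFECT_CLASSES",
    "NONSYNONYMOUS",
    "classify_effect",
    "parse_variants",
    "call_ploidy",
    "build_profiles",
    "group_burden",
]

EFFECT_CLASSES = ("missense", "nonsense", "frameshift", "synonymous", "noncoding", "other")

#: Effect classes counted as nonsynonymous: those altering the protein.
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift"})

# SnpEff sequence-ontology terms -> effect classes.  Terms outside this
# closed vocabulary map to "other".
_EFFECT_MAP = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "frameshift_variant": "frameshift",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "intergenic_region": "noncoding",
    "intergenic_variant": "noncoding",
    "intron_variant": "noncoding",
    "upstream_gene_variant": "noncoding",
    "downstream_gene_variant": "noncoding",
    "5_prime_UTR_variant": "noncoding",
    "3_prime_UTR_variant": "noncoding",
    "non_coding_transcript_variant": "noncoding",
    "non_coding_transcript_exon_variant": "noncoding",
    # Pre-classified tables may already carry effect-class names.
    "missense": "missense",
    "nonsense": "nonsense",
    "frameshift": "frameshift",
    "synonymous": "synonymous",
    "noncoding": "noncoding",
    "other": "other",
}


@dataclass(frozen=True)
class MutationRecord:
    clone_id: str
    group: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction must lie in [0, 1], got {self.allele_fraction}")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")


@dataclass
class CloneProfile:
    clone_id: str
    group: str
    ploidy_call: Literal["haploid", "diploid"]
    effect_counts: dict = field(default_factory=dict)

    @property
    def n_nonsynonymous(self) -> int:
        return sum(self.effect_counts.get(e, 0) for e in NONSYNONYMOUS)


def classify_effect(annotation_term: str) -> str:
    """Map a SnpEff-style annotation term to an effect class.

    Total function: unmapped terms classify as ``"other"``.  SnpEff
    compound annotations ("A&B") classify by their first recognised term.
    """
    term = str(annotation_term).strip()
    if term in _EFFECT_MAP:
        return _EFFECT_MAP[term]
    if "&" in term:
        for part in term.split("&"):
            if part in _EFFECT_MAP:
                return _EFFECT_MAP[part]
    return "other"


def _dedup(records: list[MutationRecord]) -> list[MutationRecord]:
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.clone_id, r.chrom, r.pos, r.alt)
        if key in seen:
            logger.warning("duplicate record dropped: %s", key)
            continue
        seen.add(key)
        out.append(r)
    return out


def _parse_tsv(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"clone_id", "group", "chrom", "pos", "ref", "alt", "gene", "effect", "allele_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MutationRecord(
                    clone_id=row.clone_id,
                    group=row.group,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    effect=classify_effect(row.effect),
                    allele_fraction=float(row.allele_fraction),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return _dedup(records)


def _parse_vcf(path: Path, clone_id: str | None, group: str) -> list[MutationRecord]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an extra
        raise ImportError("VCF input requires the cyvcf2 package") from exc
    records = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    default_clone = clone_id or (samples[0] if samples else Path(path).stem)
    for v in vcf:
        ann = v.INFO.get("ANN")
        alts = v.ALT or []
        # ANN entries: Allele|Annotation|...|Gene_Name|... ; one or more per allele.
        ann_by_allele: dict[str, tuple[str, str]] = {}
        if ann:
            for entry in str(ann).split(","):
                fields = entry.split("|")
                if len(fields) < 4:
                    continue
                allele, term, gene = fields[0], fields[1], fields[3]
                ann_by_allele.setdefault(allele, (term, gene))
        # Allele fraction from allelic depths when present.
        af_by_alt: dict[int, float] = {}
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None and len(ad) > 0:
            depths = np.asarray(ad[0], dtype=float)
            total = depths[depths >= 0].sum()
            if total > 0:
                for ai in range(len(alts)):
                    af_by_alt[ai] = float(depths[ai + 1] / total)
        for ai, alt in enumerate(alts):
            term, gene = ann_by_allele.get(alt, ("", ""))
            effect = classify_effect(term)
            if effect == "other" and term not in _EFFECT_MAP and term:
                logger.warning("unknown annotation term %r classified as 'other'", term)
            af = af_by_alt.get(ai)
            if af is None:
                info_af = v.INFO.get("AF")
                if isinstance(info_af, (tuple, list)):
                    af = float(info_af[ai]) if ai < len(info_af) else 1.0
                else:
                    af = float(info_af) if info_af is not None else 1.0
            records.append(
                MutationRecord(
                    clone_id=default_clone,
                    group=group,
                    chrom=v.CHROM,
                    pos=int(v.POS),
                    ref=v.REF,
                    alt=alt,
                    gene=gene,
                    effect=effect,
                    allele_fraction=min(max(af, 0.0), 1.0),
                )
            )
    return _dedup(records)


def parse_variants(
    path,
    format: Literal["tsv", "vcf"] = "tsv",
    clone_id: str | None = None,
    group: str = "",
) -> list[MutationRecord]:
    """Read annotated variants into MutationRecords.

    TSV input follows the synthdata mutation-table dialect.  VCF input
    must carry SnpEff-style ``ANN`` INFO annotations; one record is
    emitted per alternate allele, with the allele fraction computed from
    allelic depths (``AD``) when present, falling back to the ``AF`` INFO
    field, else 1.0.  Duplicates (same clone, chrom, pos, alt) are dropped
    with a warning.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if format == "tsv":
        return _parse_tsv(p)
    if format == "vcf":
        return _parse_vcf(p, clone_id, group)
    raise ValueError(f"unknown format {format!r}")


def call_ploidy(
    records: Sequence[MutationRecord],
    het_window: tuple[float, float] = (0.4, 0.6),
    min_het: int = 2,
) -> str:
    """Call a clone diploid when >= min_het mutations sit at heterozygous
    allele fractions.

    The het window is an open interval around 0.5 (default (0.4, 0.6)),
    absorbing allelic-depth sampling noise.  An empty record list returns
    haploid with a warning (no evidence either way).
    """
    if not records:
        logger.warning("call_ploidy on empty record list; defaulting to haploid")
        return "haploid"
    clones = {r.clone_id for r in records}
    if len(clones) > 1:
        raise ValueError(f"records span multiple clones: {sorted(clones)}")
    lo, hi = het_window
    n_het = sum(1 for r in records if lo < r.allele_fraction < hi)
    return "diploid" if n_het >= min_het else "haploid"


def build_profiles(
    records: Iterable[MutationRecord],
    het_window: tuple[float, float] = (0.4, 0.6),
    min_het: int = 2,
) -> list[CloneProfile]:
    """Aggregate records into per-clone profiles with ploidy calls."""
    by_clone: dict[str, list[MutationRecord]] = {}
    for r in records:
        by_clone.setdefault(r.clone_id, []).append(r)
    profiles = []
    for clone_id in sorted(by_clone):
        recs = by_clone[clone_id]
        counts: dict[str, int] = {e: 0 for e in EFFECT_CLASSES}
        for r in recs:
            counts[r.effect] += 1
        profiles.append(
            CloneProfile(
                clone_id=clone_id,
                group=recs[0].group,
                ploidy_call=call_ploidy(recs, het_window, min_het),
                effect_counts=counts,
            )
        )
    return profiles


def group_burden(profiles: Sequence[CloneProfile]) -> pd.DataFrame:
    """Per-group mean nonsynonymous mutations per clone with a 95% CI.

    The CI half-width is t(0.975, n-1) * sd / sqrt(n).  Groups with fewer
    than two clones are reported with the half-width as NaN (undefined).
    Returns a DataFrame with columns group, n, mean, ci95_half_width.
    """
    by_group: dict[str, list[int]] = {}
    for p in profiles:
        by_group.setdefault(p.group, []).append(p.n_nonsynonymous)
    rows = []
    for group in sorted(by_group):
        counts = np.asarray(by_group[group], dtype=float)
        n = len(counts)
        mean = counts.mean()
        if n >= 2:
            half = stats.t.ppf(0.975, n - 1) * counts.std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
            logger.warning("group %r has <2 clones; CI undefined", group)
        rows.append({"group": group, "n": n, "mean": mean, "ci95_half_width": half})
    return pd.DataFrame(rows)
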