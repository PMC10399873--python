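"""Gene-set fold enrichment and phenotype-ratio analyses.

Fold enrichment of a gene set among the top-ranked genes is defined as

    fold = (k / n_top) / (set_size / universe_size)

where k is the number of top genes in the set; significance is the
hypergeometric upper tail of drawing >= k set members in n_top draws from
the universe.  This covers brain-enriched coding/lncRNA sets and
mouse-nervous-system-phenotype homolog sets alike (the human-resolved
homolog mapping is input data).

Phenotype ratios relate a prioritized gene to clinical terms: among the
samples whose CNVs overlap the gene, the fraction annotated with each
term — a long-format table ready for heat-map plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .features import FeatureKey, overlap_length
from .io import Cohort, GeneRecord


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members <= self.universe:
            extra = sorted(self.members - self.universe)
            raise ValueError(f"gene set {self.name!r} has members outside the universe: {extra[:5]}")


def make_gene_set(name: str, members: Sequence[str], universe: Sequence[str]) -> GeneSet:
    """Build a GeneSet, silently restricting members to the universe."""
    uni = frozenset(universe)
    return GeneSet(name=name, members=frozenset(members) & uni, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    n_top: int
    k_in_set: int
    set_size: int
    universe_size: int
    top_fraction: float
    background_fraction: float
    fold: float
    hypergeom_p: float


def fold_enrichment(
    top_genes: Sequence[str], gene_set: GeneSet, n_top: Optional[int] = None
) -> EnrichmentResult:
    """Fold enrichment of ``gene_set`` within the first ``n_top`` genes.

    ``top_genes`` must be inside the set's universe and is cut at
    ``n_top`` (default: the whole list).  The p-value is the exact
    hypergeometric upper tail P[K >= k].
    """
    if not gene_set.members or not gene_set.universe:
        raise ValueError("gene set and universe must be non-empty")
    if n_top is None:
        n_top = len(top_genes)
    if n_top < 1 or n_top > len(top_genes):
        raise ValueError("n_top must be in 1..len(top_genes)")
    top = list(dict.fromkeys(top_genes[:n_top]))  # preserve order, drop dups
    outside = [g for g in top if g not in gene_set.universe]
    if outside:
        raise ValueError(f"top genes outside the universe: {outside[:5]}")
    k = sum(1 for g in top if g in gene_set.members)
    n = len(top)
    K = len(gene_set.members)
    U = len(gene_set.universe)
    top_frac = k / n
    bg_frac = K / U
    fold = top_frac / bg_frac
    p = float(min(1.0, hypergeom.sf(k - 1, U, K, n)))
    return EnrichmentResult(
        n_top=n,
        k_in_set=k,
        set_size=K,
        universe_size=U,
        top_fraction=top_frac,
        background_fraction=bg_frac,
        fold=fold,
        hypergeom_p=p,
    )


def homolog_phenotype_fraction(
    top_genes: Sequence[str], homolog_set: GeneSet, n_top: Optional[int] = None
) -> tuple[float, EnrichmentResult]:
    """Percent of top genes with a nervous-system-phenotype mouse homolog.

    Returns (percentage, full enrichment result vs the background rate).
    """
    res = fold_enrichment(top_genes, homolog_set, n_top=n_top)
    return 100.0 * res.top_fraction, res


def stratify_top(
    results_frame: pd.DataFrame,
    genes: Sequence[GeneRecord],
    biotype: Optional[str] = None,
    dosage: Optional[str] = None,
) -> list[str]:
    """Filter a ranked-results frame by biotype and/or dosage.

    Returns gene ids in rank order, restricted to non-excluded rows whose
    gene has the requested biotype and whose feature has the requested
    dosage — the top-list side of a stratified enrichment.
    """
    biot = {g.gene_id: g.biotype for g in genes}
    df = results_frame[~results_frame["excluded"].astype(bool)].sort_values("rank")
    out = []
    for gene, status in zip(df["gene"], df["status"]):
        if dosage is not None and status != dosage:
            continue
        if biotype is not None and biot.get(gene) != biotype:
            continue
        if gene not in out:
            out.append(gene)
    return out


@dataclass(frozen=True)
class PhenotypeRatio:
    gene_id: str
    phenotype_term: str
    n_overlapped: int
    n_overlapped_with_phenotype: int
    ratio: float


def phenotype_ratios(
    cohort: Cohort,
    genes: Sequence[GeneRecord],
    key: FeatureKey,
    phenotypes: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> list[PhenotypeRatio]:
    """Per-term fraction of gene-overlapped samples carrying the term.

    ``phenotypes`` is a long table with columns ``sample_id`` and
    ``term``.  Only terms observed among the overlapped samples are
    reported; a gene with zero overlapped samples yields an empty list.
    """
    gene = next((g for g in genes if g.gene_id == key.gene_id), None)
    if gene is None:
        raise KeyError(f"gene {key.gene_id!r} not in annotation")
    overlapped: set[str] = set()
    for r in cohort.records:
        if r.dosage == key.dosage and overlap_length(gene, r) >= min_overlap_bp:
            overlapped.add(r.sample_id)
    if not overlapped:
        return []
    sub = phenotypes[phenotypes["sample_id"].isin(overlapped)]
    n_ov = len(overlapped)
    out = []
    for term, grp in sub.groupby("term"):
        n_with = grp["sample_id"].nunique()
        out.append(
            PhenotypeRatio(
                gene_id=key.gene_id,
                phenotype_term=str(term),
                n_overlapped=n_ov,
                n_overlapped_with_phenotype=int(n_with),
                ratio=n_with / n_ov,
            )
        )
    return out


def ratios_to_frame(rows: Sequence[PhenotypeRatio], dosage: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in rows],
            "status": dosage,
            "term": [r.phenotype_term for r in rows],
            "n_overlapped": [r.n_overlapped for r in rows],
            "n_with_term": [r.n_overlapped_with_phenotype for r in rows],
            "ratio": [r.ratio for r in rows],
        }
    )
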