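"""Sample × (gene, dosage) overlap features for supervised learning.

Each feature is one gene crossed with one CNV dosage (del or dup); its
value for a sample is the total length, in kilobases, of that sample's
CNVs of that dosage intersected with the gene.  Deletions and duplications
of the same gene are separate features because they have distinct effects.
Labels are 0 for controls and 1 for cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CNVRecord, Cohort, GeneRecord

logger = logging.getLogger(__name__)

DOSAGES = ("del", "dup")


class FeatureKey(NamedTuple):
    gene_id: str
    dosage: str  # "del" | "dup"


@dataclass
class FeatureMatrix:
    """Dense overlap-feature matrix with 0/1 labels.

    ``X[i, j]`` is sample i's summed overlap (kb) with feature j's gene for
    feature j's dosage; overlaps from multiple CNVs of one sample add up and
    may exceed the gene length.  ``scaling == "unit_interval"`` divides each
    column by its maximum (all-zero columns stay zero).
    """

    X: np.ndarray  # (n_samples, n_features) float64, >= 0
    y: np.ndarray  # (n_samples,) int, control=0 case=1
    sample_ids: list[str]
    feature_keys: list[FeatureKey]
    scaling: str = "raw"  # "raw" | "unit_interval"
    values: str = "length"  # "length" | "binary"
    ranking_excluded: Optional[np.ndarray] = None  # bool per feature, set by prefilter

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.sample_ids), len(self.feature_keys)):
            raise ValueError("X shape does not match sample/feature axes")
        if self.X.size and self.X.min() < 0:
            raise ValueError("overlap features must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def key_index(self) -> dict[FeatureKey, int]:
        return {k: j for j, k in enumerate(self.feature_keys)}


def overlap_length(gene: GeneRecord, cnv: CNVRecord) -> int:
    """Length in bp of the intersection of a gene and a CNV (0 off-chromosome).

    Both intervals must be on the internal 0-based half-open convention.
    """
    if gene.chrom != cnv.chrom:
        return 0
    return max(0, min(gene.stop, cnv.stop) - max(gene.start, cnv.start))


def _overlap_bp_matrix(
    cohort: Cohort, genes: Sequence[GeneRecord], sample_index: dict[str, int]
) -> np.ndarray:
    """Raw summed overlap in bp, rows = samples, columns = gene × dosage.

    Column layout matches :func:`feature_axis`: for gene g at position i,
    columns 2i (del) and 2i+1 (dup).
    """
    n = len(sample_index)
    m = 2 * len(genes)
    out = np.zeros((n, m), dtype=np.float64)
    by_chrom: dict[str, list[tuple[int, GeneRecord]]] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((gi, g))
    chrom_arrays = {
        c: (
            np.array([gi for gi, _ in lst]),
            np.array([g.start for _, g in lst]),
            np.array([g.stop for _, g in lst]),
        )
        for c, lst in by_chrom.items()
    }
    for r in cohort.records:
        arrs = chrom_arrays.get(r.chrom)
        if arrs is None:
            continue
        gidx, gstart, gstop = arrs
        ov = np.minimum(gstop, r.stop) - np.maximum(gstart, r.start)
        hit = ov > 0
        if not hit.any():
            continue
        col = 2 * gidx[hit] + (0 if r.dosage == "del" else 1)
        np.add.at(out, (sample_index[r.sample_id], col), ov[hit])
    return out


def feature_axis(genes: Sequence[GeneRecord]) -> list[FeatureKey]:
    return [FeatureKey(g.gene_id, d) for g in genes for d in DOSAGES]


def build_feature_matrix(
    cohort: Cohort,
    genes: Sequence[GeneRecord],
    scaling: str = "unit_interval",
    values: str = "length",
    min_overlap_bp: int = 1,
) -> FeatureMatrix:
    """Turn a filtered cohort into the learning matrix.

    Parameters
    ----------
    scaling
        ``"raw"`` keeps kb lengths; ``"unit_interval"`` (default) divides
        each column by its maximum so sigmoid-output decoders can fit it.
    values
        ``"length"`` (default) stores summed overlap in kb; ``"binary"``
        stores 1 if the sample has any CNV of the dosage overlapping the
        gene by at least ``min_overlap_bp``.
    """
    if not genes or cohort.n_samples == 0:
        raise ValueError("need at least one gene and one sample")
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("gene ids must be unique")
    sample_ids = cohort.sample_ids()
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    bp = _overlap_bp_matrix(cohort, genes, sample_index)
    if values == "length":
        X = bp / 1000.0
    elif values == "binary":
        X = (bp >= min_overlap_bp).astype(np.float64)
    else:
        raise ValueError(f"unknown values mode {values!r}")
    if scaling == "unit_interval":
        colmax = X.max(axis=0)
        nz = colmax > 0
        X[:, nz] = X[:, nz] / colmax[nz]
    elif scaling != "raw":
        raise ValueError(f"unknown scaling {scaling!r}")
    y = np.array([1 if cohort.samples[s][0] == "case" else 0 for s in sample_ids])
    return FeatureMatrix(
        X=X,
        y=y,
        sample_ids=sample_ids,
        feature_keys=feature_axis(genes),
        scaling=scaling,
        values=values,
    )


def overlap_counts(
    cohort: Cohort, genes: Sequence[GeneRecord], min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Distinct-sample overlap counts per feature.

    Returns a DataFrame aligned with :func:`feature_axis` with columns
    ``gene_id, dosage, case_ov, control_ov``: the number of distinct case
    (control) samples having at least one CNV of the feature's dosage
    overlapping the gene by ``>= min_overlap_bp``.  A sample with many
    overlapping CNVs counts once.
    """
    sample_ids = cohort.sample_ids()
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    bp = _overlap_bp_matrix(cohort, genes, sample_index)
    carrier = bp >= min_overlap_bp
    is_case = np.array([cohort.samples[s][0] == "case" for s in sample_ids])
    case_ov = carrier[is_case].sum(axis=0)
    control_ov = carrier[~is_case].sum(axis=0)
    keys = feature_axis(genes)
    return pd.DataFrame(
        {
            "gene_id": [k.gene_id for k in keys],
            "dosage": [k.dosage for k in keys],
            "case_ov": case_ov.astype(int),
            "control_ov": control_ov.astype(int),
        }
    )


def overlap_sample_counts(
    cohort: Cohort,
    genes: Sequence[GeneRecord],
    key: FeatureKey,
    min_overlap_bp: int = 1,
) -> tuple[int, int]:
    """(CaseOV, ControlOV) for one gene × dosage feature."""
    gene = next((g for g in genes if g.gene_id == key.gene_id), None)
    if gene is None:
        raise KeyError(f"gene {key.gene_id!r} not in annotation")
    case_samples: set[str] = set()
    control_samples: set[str] = set()
    for r in cohort.records:
        if r.dosage != key.dosage:
            continue
        if overlap_length(gene, r) >= min_overlap_bp:
            (case_samples if r.label == "case" else control_samples).add(r.sample_id)
    return len(case_samples), len(control_samples)


def prefilter_features(matrix: FeatureMatrix, counts: pd.DataFrame) -> FeatureMatrix:
    """Drop never-overlapped features; flag control-dominated ones.

    Features with ``case_ov + control_ov == 0`` are removed outright.
    Features with ``control_ov > case_ov`` (strict) are kept in the matrix —
    the model still trains on them — but flagged in ``ranking_excluded`` so
    the final ranking omits them.
    """
    if len(counts) != matrix.n_features:
        raise ValueError("counts not aligned with feature axis")
    case_ov = counts["case_ov"].to_numpy()
    control_ov = counts["control_ov"].to_numpy()
    keep = (case_ov + control_ov) > 0
    if not keep.any():
        raise ValueError("all features have zero overlap; nothing to model")
    excluded = (control_ov > case_ov)[keep]
    logger.info(
        "prefilter: kept %d/%d features, %d flagged control-dominated",
        int(keep.sum()),
        matrix.n_features,
        int(excluded.sum()),
    )
    return FeatureMatrix(
        X=matrix.X[:, keep],
        y=matrix.y,
        sample_ids=matrix.sample_ids,
        feature_keys=[k for k, m in zip(matrix.feature_keys, keep) if m],
        scaling=matrix.scaling,
        values=matrix.values,
        ranking_excluded=excluded,
    )


def write_feature_matrix(matrix: FeatureMatrix, prefix: str | Path) -> None:
    """Export as ``<prefix>.tsv`` (samples × features) plus ``<prefix>.keys.tsv``
    and an ``<prefix>.npz`` binary cache (arrays X, y and the axes)."""
    prefix = Path(prefix)
    cols = [f"{k.gene_id}|{k.dosage}" for k in matrix.feature_keys]
    pd.DataFrame(matrix.X, index=matrix.sample_ids, columns=cols).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index_label="sample_id"
    )
    pd.DataFrame(
        {
            "gene_id": [k.gene_id for k in matrix.feature_keys],
            "dosage": [k.dosage for k in matrix.feature_keys],
            "ranking_excluded": (
                matrix.ranking_excluded
                if matrix.ranking_excluded is not None
                else np.zeros(matrix.n_features, dtype=bool)
            ),
        }
    ).to_csv(prefix.with_suffix(".keys.tsv"), sep="\t", index=False)
    np.savez_compressed(
        prefix.with_suffix(".npz"),
        X=matrix.X,
        y=matrix.y,
        sample_ids=np.array(matrix.sample_ids),
        gene_ids=np.array([k.gene_id for k in matrix.feature_keys]),
        dosages=np.array([k.dosage for k in matrix.feature_keys]),
        scaling=np.array(matrix.scaling),
        values=np.array(matrix.values),
        ranking_excluded=(
            matrix.ranking_excluded
            if matrix.ranking_excluded is not None
            else np.zeros(matrix.n_features, dtype=bool)
        ),
    )


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    """Reload a matrix written by :func:`write_feature_matrix` (npz cache)."""
    data = np.load(Path(prefix).with_suffix(".npz"), allow_pickle=False)
    keys = [FeatureKey(g, d) for g, d in zip(data["gene_ids"], data["dosages"])]
    return FeatureMatrix(
        X=data["X"],
        y=data["y"],
        sample_ids=[str(s) for s in data["sample_ids"]],
        feature_keys=keys,
        scaling=str(data["scaling"]),
        values=str(data["values"]),
        ranking_excluded=data["ranking_excluded"],
    )
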