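"""Exact and resampling burden statistics.

The burden test compares, for one gene × dosage feature, the number of
distinct case vs control individuals whose CNVs overlap the gene, on the
2×2 table

    a = cases overlapped      b = cases not overlapped
    c = controls overlapped   d = controls not overlapped

with Fisher's exact test (one-sided "greater" by default: case
enrichment).  A permutation test shuffles case/control labels while
preserving the arm sizes.  Sex-segregation rows compare, within males and
females separately, the percentage of overlapped cases to overlapped
controls, and summarize the male-vs-female bias as
log2(male ratio / female ratio).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency, hypergeom
from statsmodels.stats.multitest import multipletests

from .features import FeatureKey, overlap_length
from .io import Cohort, GeneRecord


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # case samples overlapped
    b: int  # case samples not overlapped
    c: int  # control samples overlapped
    d: int  # control samples not overlapped

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2×2 burden table.

    ``greater``: P[X >= a] with X ~ Hypergeom(N, a+c, a+b) — the upper
    tail of overlapped-case counts under fixed margins.  ``two_sided``:
    the sum of point probabilities not exceeding the observed one (the
    standard two-sided convention, with a small relative tolerance for
    floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_case, n_control = a + b, c + d
    if n_case == 0 or n_control == 0:
        raise ValueError("both cohort arms must be non-empty")
    N = n_case + n_control
    K = a + c
    dist = hypergeom(N, K, n_case)
    if alternative == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if alternative == "two_sided":
        support = np.arange(max(0, K - n_control), min(K, n_case) + 1)
        pmf = dist.pmf(support)
        p_obs = dist.pmf(a)
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
        return min(1.0, p)
    raise ValueError(f"unknown alternative {alternative!r}")


def fisher_exact_counts(
    case_ov: np.ndarray,
    control_ov: np.ndarray,
    n_case: int,
    n_control: int,
    alternative: str = "greater",
) -> np.ndarray:
    """Vectorized one-sided/two-sided Fisher p over many features."""
    case_ov = np.asarray(case_ov, dtype=int)
    control_ov = np.asarray(control_ov, dtype=int)
    if alternative == "greater":
        K = case_ov + control_ov
        return np.minimum(
            1.0, hypergeom.sf(case_ov - 1, n_case + n_control, K, n_case)
        )
    return np.array(
        [
            fisher_exact(
                ContingencyTable(a, n_case - a, c, n_control - c), alternative
            )
            for a, c in zip(case_ov, control_ov)
        ]
    )


def _observed_stat(flags: np.ndarray, labels: np.ndarray, statistic: str) -> float:
    a = float(flags[labels == 1].sum())
    if statistic == "case_count":
        return a
    if statistic == "odds_ratio":
        n_case = float((labels == 1).sum())
        n_control = float((labels == 0).sum())
        c = float(flags[labels == 0].sum())
        # Haldane-Anscombe correction keeps the statistic finite
        return ((a + 0.5) * (n_control - c + 0.5)) / ((n_case - a + 0.5) * (c + 0.5))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    flags: Sequence[int] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "case_count",
    exhaustive: bool = False,
) -> float:
    """Empirical p-value under case/control label permutation.

    ``flags`` are per-sample 0/1 overlap indicators, ``labels`` per-sample
    case (1) / control (0).  Permutations preserve the arm sizes.  In
    randomized mode the add-one estimator ``(1 + #{perm >= obs}) /
    (n_perm + 1)`` is used, so p is never exactly zero; in exhaustive mode
    every case-assignment of the given size is enumerated and the plain
    exceedance fraction returned.
    """
    flags = np.asarray(flags, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if flags.shape != labels.shape:
        raise ValueError("flags and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both cases and controls to permute labels")
    obs = _observed_stat(flags, labels, statistic)
    n = len(labels)
    n_case = int((labels == 1).sum())
    if exhaustive:
        count = 0
        total = 0
        for case_idx in itertools.combinations(range(n), n_case):
            perm = np.zeros(n, dtype=int)
            perm[list(case_idx)] = 1
            if _observed_stat(flags, perm, statistic) >= obs - 1e-12:
                count += 1
            total += 1
        return count / total
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 4096
    base = np.zeros(n, dtype=int)
    base[:n_case] = 1
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        for _ in range(m):
            perm = base[rng.permutation(n)]
            if _observed_stat(flags, perm, statistic) >= obs - 1e-12:
                count += 1
        done += m
    return (1 + count) / (n_perm + 1)


def permutation_test_matrix(
    carrier: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Case-count permutation p for every column of a carrier matrix.

    Each feature gets its own permutation stream derived from ``seed`` so
    p-values across features are mutually independent.
    """
    carrier = np.asarray(carrier, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, m = carrier.shape
    n_case = int((labels == 1).sum())
    ps = np.empty(m)
    root = np.random.SeedSequence(seed)
    children = root.spawn(m)
    for j in range(m):
        rng = np.random.default_rng(children[j])
        obs = carrier[labels == 1, j].sum()
        perm_stats = np.empty(n_perm)
        col = carrier[:, j]
        for t in range(n_perm):
            idx = rng.choice(n, size=n_case, replace=False)
            perm_stats[t] = col[idx].sum()
        ps[j] = (1 + np.sum(perm_stats >= obs - 1e-12)) / (n_perm + 1)
    return ps


@dataclass
class SexSegregationRow:
    """One gene × dosage row of the sex-bias table (percent scale)."""

    key: FeatureKey
    pct_male_cases: float
    pct_male_controls: float
    pct_female_cases: float
    pct_female_controls: float
    male_ratio: float
    female_ratio: float
    log2_enrichment: float
    chi2_stat: float
    chi2_p: float
    defined: bool = True


def log2_sex_enrichment(male_ratio: float, female_ratio: float) -> float:
    """log2 of (male case/control ratio over female case/control ratio)."""
    return math.log2(male_ratio / female_ratio)


def sex_segregation(
    cohort: Cohort,
    key: FeatureKey,
    genes: Sequence[GeneRecord],
    min_overlap_bp: int = 1,
) -> SexSegregationRow:
    """Male-vs-female case enrichment for one gene × dosage feature.

    Percentages are overlapped samples over all samples within each
    (sex, arm) stratum, ×100.  The chi-square statistic is computed on the
    2×2 of overlapped-sample counts {male, female} × {case, control}
    without continuity correction.  Any empty stratum marks the row
    undefined (NaN fields).
    """
    gene = next((g for g in genes if g.gene_id == key.gene_id), None)
    if gene is None:
        raise KeyError(f"gene {key.gene_id!r} not in annotation")
    overlapped: set[str] = set()
    for r in cohort.records:
        if r.dosage == key.dosage and overlap_length(gene, r) >= min_overlap_bp:
            overlapped.add(r.sample_id)
    totals = {}
    hits = {}
    for sex in ("male", "female"):
        for label in ("case", "control"):
            ids = [
                s
                for s, (lab, sx) in cohort.samples.items()
                if lab == label and sx == sex
            ]
            totals[(sex, label)] = len(ids)
            hits[(sex, label)] = sum(1 for s in ids if s in overlapped)
    nan = float("nan")
    if min(totals.values()) == 0:
        return SexSegregationRow(key, nan, nan, nan, nan, nan, nan, nan, nan, nan, False)
    pct = {k: 100.0 * hits[k] / totals[k] for k in totals}
    male_ratio = (
        pct[("male", "case")] / pct[("male", "control")]
        if pct[("male", "control")] > 0
        else nan
    )
    female_ratio = (
        pct[("female", "case")] / pct[("female", "control")]
        if pct[("female", "control")] > 0
        else nan
    )
    log2_enr = (
        log2_sex_enrichment(male_ratio, female_ratio)
        if math.isfinite(male_ratio) and math.isfinite(female_ratio) and female_ratio > 0
        else nan
    )
    obs = np.array(
        [
            [hits[("male", "case")], hits[("male", "control")]],
            [hits[("female", "case")], hits[("female", "control")]],
        ]
    )
    if obs.sum() > 0 and (obs.sum(axis=0) > 0).all() and (obs.sum(axis=1) > 0).all():
        chi2, chi2_p = chi2_contingency(obs, correction=False)[:2]
    else:
        chi2, chi2_p = nan, nan
    return SexSegregationRow(
        key=key,
        pct_male_cases=pct[("male", "case")],
        pct_male_controls=pct[("male", "control")],
        pct_female_cases=pct[("female", "case")],
        pct_female_controls=pct[("female", "control")],
        male_ratio=male_ratio,
        female_ratio=female_ratio,
        log2_enrichment=log2_enr,
        chi2_stat=float(chi2),
        chi2_p=float(chi2_p),
        defined=math.isfinite(log2_enr),
    )


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
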