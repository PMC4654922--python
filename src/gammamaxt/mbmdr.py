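"""MB-MDR pairwise association statistic (reference implementation).

The Model-Based Multifactor Dimensionality Reduction statistic for a SNP
pair proceeds in two stages.  Stage 1 labels each of the nine two-locus
genotype cells as higher-risk (H), lower-risk (L) or undecided (O) by a
one-vs-rest association test at a lenient level ``alpha_cell``.  Stage 2
pools the H cells and tests them against everyone else (and likewise for
the L cells); the pair's statistic is the larger of the two pooled test
values.  A pair whose table is all-O yields an exact zero — the point mass
that the gamma-tail null model of :mod:`gammamaxt.gamma_null` accounts for.

Binary traits use Pearson chi-squared tests on 2x2 collapses; continuous
traits use squared pooled-variance Student t statistics, so both scales
produce non-negative values comparable to a chi-squared with one degree of
freedom.

The functions here operate on one pair at a time and are deliberately
simple; the production scans go through the vectorized kernels in
:mod:`gammamaxt.kernels`, which are tested against this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import chi2 as _chi2_dist

from .dataset import BINARY, CONTINUOUS, Dataset
from .kernels import all_pair_statistics, eval_pairs, ids_to_pairs, pair_count

DEFAULT_ALPHA_CELL = 0.1


@dataclass
class PairCrossTab:
    """Two-locus cross tabulation of one SNP pair.

    ``counts[g1, g2]`` is the number of individuals with genotype ``g1`` at
    the first SNP and ``g2`` at the second, both non-missing.  For binary
    traits ``cases`` holds the per-cell case counts; for continuous traits
    ``trait_sum`` and ``trait_sumsq`` hold per-cell first and second moments.
    """

    counts: np.ndarray
    trait_type: str
    cases: np.ndarray | None = None
    trait_sum: np.ndarray | None = None
    trait_sumsq: np.ndarray | None = None


@dataclass
class HLOTable:
    """3x3 matrix of cell labels, each one of ``'H'``, ``'L'``, ``'O'``."""

    labels: np.ndarray


@dataclass
class TopList:
    """The ``n`` best (pair, statistic) entries of a scan, sorted by
    non-increasing statistic; ties broken by the lower lexicographic pair id.
    """

    pairs: np.ndarray  # (k, 2) 0-based SNP indices, a < b
    stats: np.ndarray  # (k,) statistics, non-increasing
    capacity: int

    def __len__(self) -> int:
        return len(self.stats)


def crosstab_pair(dataset: Dataset, pair: tuple[int, int]) -> PairCrossTab:
    """Cross-tabulate one SNP pair, excluding individuals missing at either locus."""
    a, b = pair
    if a == b:
        raise ValueError("self-pair: the two SNP indices must differ")
    g1 = dataset.genotypes[:, a]
    g2 = dataset.genotypes[:, b]
    keep = (g1 >= 0) & (g2 >= 0)
    g1, g2, y = g1[keep], g2[keep], dataset.trait[keep]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1, g2), 1)
    ct = PairCrossTab(counts=counts, trait_type=dataset.trait_type)
    if dataset.trait_type == BINARY:
        cases = np.zeros((3, 3), dtype=np.int64)
        np.add.at(cases, (g1[y == 1], g2[y == 1]), 1)
        ct.cases = cases
    else:
        ct.trait_sum = np.zeros((3, 3))
        ct.trait_sumsq = np.zeros((3, 3))
        np.add.at(ct.trait_sum, (g1, g2), y)
        np.add.at(ct.trait_sumsq, (g1, g2), y * y)
    return ct


def _cell_test_binary(a, row1, col1, n):
    """(chi2, valid) of the 2x2 table with cell a, margins row1/col1, total n."""
    den = row1 * (n - row1) * col1 * (n - col1)
    if den <= 0:
        return 0.0, False
    b = row1 - a
    c = col1 - a
    d = n - row1 - c
    return n * (a * d - b * c) ** 2 / den, True


def _cell_test_continuous(n1, s1, q1, n2, s2, q2):
    """(t2, df, valid, mean_diff): squared pooled-variance Student t.

    The pooled variance keeps the statistic on the chi-squared(1 df) scale
    even for very small groups (a per-group variance would explode when a
    tiny group happens to have near-identical trait values).
    """
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return 0.0, 1.0, False, 0.0
    m1, m2 = s1 / n1, s2 / n2
    df = n1 + n2 - 2.0
    sp2 = (max(q1 - s1 * m1, 0.0) + max(q2 - s2 * m2, 0.0)) / df
    if sp2 <= 0:
        return 0.0, 1.0, False, m1 - m2
    t2 = (m1 - m2) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
    if not np.isfinite(t2):
        return 0.0, 1.0, False, m1 - m2
    return t2, df, True, m1 - m2


def categorize_cells(
    ct: PairCrossTab, trait_type: str, alpha_cell: float = DEFAULT_ALPHA_CELL
) -> HLOTable:
    """Label each genotype cell H, L or O by a one-vs-rest test at ``alpha_cell``.

    Empty cells, and cells whose test is incomputable (zero margin, fewer
    than two observations per side, zero variance contrast), are labelled O.
    """
    if not 0.0 < alpha_cell < 1.0:
        raise ValueError("alpha_cell must lie in (0, 1)")
    labels = np.full((3, 3), "O", dtype="<U1")
    n = ct.counts.sum()
    if trait_type == BINARY:
        crit = _chi2_dist.isf(alpha_cell, 1)
        ncase = ct.cases.sum()
        for g1 in range(3):
            for g2 in range(3):
                nc = ct.counts[g1, g2]
                if nc == 0:
                    continue
                chi, valid = _cell_test_binary(ct.cases[g1, g2], nc, ncase, n)
                if not valid or chi <= crit:
                    continue
                risk_in = ct.cases[g1, g2] / nc
                risk_out = (ncase - ct.cases[g1, g2]) / (n - nc)
                labels[g1, g2] = "H" if risk_in > risk_out else "L"
    else:
        stot, qtot = ct.trait_sum.sum(), ct.trait_sumsq.sum()
        for g1 in range(3):
            for g2 in range(3):
                nc = ct.counts[g1, g2]
                if nc == 0:
                    continue
                t2, df, valid, diff = _cell_test_continuous(
                    nc,
                    ct.trait_sum[g1, g2],
                    ct.trait_sumsq[g1, g2],
                    n - nc,
                    stot - ct.trait_sum[g1, g2],
                    qtot - ct.trait_sumsq[g1, g2],
                )
                if not valid:
                    continue
                pval = 2.0 * special.stdtr(df, -np.sqrt(t2))
                if pval < alpha_cell:
                    labels[g1, g2] = "H" if diff > 0 else "L"
    return HLOTable(labels=labels)


def mbmdr_statistic(hlo: HLOTable, ct: PairCrossTab, trait_type: str) -> float:
    """Stage-2 statistic ``T = max(T_H, T_L)``.

    ``T_H`` tests the pooled H-labelled cells against all other individuals
    (chi-squared for binary traits, squared Student t for continuous traits);
    ``T_L`` analogously.  An absent or untestable category contributes 0, so
    an all-O table returns exactly 0.0.
    """
    n = ct.counts.sum()
    values = []
    for label in ("H", "L"):
        mask = hlo.labels == label
        if not mask.any():
            values.append(0.0)
            continue
        if trait_type == BINARY:
            a = ct.cases[mask].sum()
            row1 = ct.counts[mask].sum()
            chi, valid = _cell_test_binary(a, row1, ct.cases.sum(), n)
            values.append(chi if valid else 0.0)
        else:
            n1 = ct.counts[mask].sum()
            s1 = ct.trait_sum[mask].sum()
            q1 = ct.trait_sumsq[mask].sum()
            t2, _, valid, _ = _cell_test_continuous(
                n1, s1, q1, n - n1, ct.trait_sum.sum() - s1, ct.trait_sumsq.sum() - q1
            )
            values.append(t2 if valid else 0.0)
    return float(max(values))


def pair_statistic(
    dataset: Dataset, pair: tuple[int, int], alpha_cell: float = DEFAULT_ALPHA_CELL
) -> float:
    """Convenience composition: crosstab -> categorize -> statistic."""
    ct = crosstab_pair(dataset, pair)
    hlo = categorize_cells(ct, dataset.trait_type, alpha_cell)
    return mbmdr_statistic(hlo, ct, dataset.trait_type)


def correct_main_effects(dataset: Dataset, snps: list[int] | None = None) -> Dataset:
    """Residualize the trait on codominant (two-dummy) genotype encodings.

    Each selected SNP contributes indicator columns for the heterozygous and
    homozygous-minor genotypes; missing genotypes are mean-imputed in the
    dummy space so no individual is dropped.  The returned dataset carries
    the OLS residuals as a continuous trait, regardless of the original
    trait scale, and is treated as continuous by downstream tests.
    """
    y = dataset.trait
    if np.ptp(y) == 0:
        raise ValueError("degenerate trait: trait column is constant")
    idx = range(dataset.n_snps) if snps is None else snps
    cols = [np.ones(dataset.n_individuals)]
    for j in idx:
        g = dataset.genotypes[:, j]
        for code in (1, 2):
            d = (g == code).astype(np.float64)
            miss = g < 0
            if miss.any():
                known = ~miss
                d[miss] = d[known].mean() if known.any() else 0.0
            cols.append(d)
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return dataset.with_trait(resid, trait_type=CONTINUOUS)


def _pair_statistic_adjusted(
    dataset: Dataset, a: int, b: int, alpha_cell: float
) -> float:
    """Pair statistic after residualizing the trait on this pair's own
    codominant main effects (local correction, complete individuals only)."""
    g1 = dataset.genotypes[:, a]
    g2 = dataset.genotypes[:, b]
    keep = (g1 >= 0) & (g2 >= 0)
    sub = Dataset(
        genotypes=dataset.genotypes[keep][:, [a, b]],
        trait=dataset.trait[keep],
        trait_type=dataset.trait_type,
        snp_ids=[dataset.snp_ids[a], dataset.snp_ids[b]],
    )
    try:
        adj = correct_main_effects(sub)
    except ValueError:
        return 0.0
    return pair_statistic(adj, (0, 1), alpha_cell)


def scan_all_pairs(
    dataset: Dataset,
    n: int = 1000,
    alpha_cell: float = DEFAULT_ALPHA_CELL,
    adjust_main: bool = False,
    block: int = 256,
    pair_range: tuple[int, int] | None = None,
) -> TopList:
    """Exhaustive scan of all SNP pairs, keeping the ``n`` largest statistics.

    ``pair_range=(lo, hi)`` restricts the scan to the contiguous block of
    lexicographic pair ids ``lo..hi-1`` (the unit of work of the parallel
    split/merge workflow); memory stays bounded by the block size and ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = dataset.n_snps
    if s < 2:
        raise ValueError("need at least two SNPs")
    m = pair_count(s)
    lo, hi = (0, m) if pair_range is None else pair_range
    m_range = hi - lo
    if n > m_range:
        warnings.warn(
            f"n={n} exceeds the {m_range} pairs in range; returning all of them",
            stacklevel=2,
        )
        n = m_range

    if adjust_main:
        ids = np.arange(lo, hi)
        aa, bb = ids_to_pairs(ids, s)
        stats = np.array(
            [_pair_statistic_adjusted(dataset, a, b, alpha_cell) for a, b in zip(aa, bb)]
        )
    elif pair_range is None:
        stats = all_pair_statistics(dataset, alpha_cell=alpha_cell, block=block)
        ids = np.arange(m)
    else:
        ids = np.arange(lo, hi)
        aa, bb = ids_to_pairs(ids, s)
        stats = np.empty(m_range)
        for c0 in range(0, m_range, 65536):
            c1 = min(c0 + 65536, m_range)
            stats[c0:c1] = eval_pairs(
                dataset, aa[c0:c1], bb[c0:c1], alpha_cell=alpha_cell
            )

    # top n with deterministic tie-break: higher stat first, lower id first
    if n < stats.size:
        cut = np.partition(stats, stats.size - n)[stats.size - n]
        cand = np.flatnonzero(stats >= cut)  # includes ties at the cut
    else:
        cand = np.arange(stats.size)
    order = np.lexsort((ids[cand], -stats[cand]))[:n]
    sel = cand[order]
    aa, bb = ids_to_pairs(ids[sel], s)
    return TopList(
        pairs=np.column_stack([aa, bb]), stats=stats[sel].copy(), capacity=n
    )
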