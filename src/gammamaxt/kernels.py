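"""Vectorized evaluation of the MB-MDR pair statistic.

Three execution strategies share one pair of "stage" routines (H/L/O cell
labelling followed by the pooled one-vs-rest test):

* :func:`all_pair_statistics` — every unordered SNP pair, computed from
  9 (binary) or 27 (continuous) small matrix products over one-hot genotype
  indicators; used by the exhaustive scan and the exact permutation backends.
* :func:`eval_pairs` — an arbitrary list of pair indices, computed with flat
  ``bincount`` scatter sums; used when sampling null statistics on demand.
* :class:`FixedPairKernel` — a fixed pair list evaluated repeatedly under
  changing trait permutations via one precomputed cell-indicator matrix;
  used for the stored top-n pairs across permutations.

The scalar reference implementation lives in :mod:`gammamaxt.mbmdr`; unit
tests assert agreement between the scalar and vectorized paths.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import chi2 as _chi2_dist

from .dataset import BINARY, Dataset

# ---------------------------------------------------------------------------
# pair enumeration (lexicographic upper triangle, 0-based)
# ---------------------------------------------------------------------------


def pair_count(n_snps: int) -> int:
    return n_snps * (n_snps - 1) // 2


def _row_starts(n_snps: int) -> np.ndarray:
    a = np.arange(n_snps - 1, dtype=np.int64)
    return a * (n_snps - 1) - a * (a - 1) // 2


def pairs_to_ids(a: np.ndarray, b: np.ndarray, n_snps: int) -> np.ndarray:
    """Flat lexicographic id of pairs ``(a, b)`` with ``a < b``."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    return _row_starts(n_snps)[a] + (b - a - 1)


def ids_to_pairs(ids: np.ndarray, n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pairs_to_ids`."""
    ids = np.asarray(ids, dtype=np.int64)
    starts = _row_starts(n_snps)
    a = np.searchsorted(starts, ids, side="right") - 1
    b = ids - starts[a] + a + 1
    return a, b


# ---------------------------------------------------------------------------
# stage routines: cell counts -> T
# ---------------------------------------------------------------------------


def _chi2_2x2(a, row1, col1, n):
    """Pearson chi-squared of the 2x2 table with cell ``a``, margins
    ``row1`` (= a+b), ``col1`` (= a+c) and total ``n``. Returns (chi2, valid).
    """
    b = row1 - a
    c = col1 - a
    d = n - row1 - c
    den = row1 * (n - row1) * col1 * (n - col1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = n * (a * d - b * c) ** 2 / den
    valid = den > 0
    return np.where(valid, chi, 0.0), valid


def stage_binary(case9: np.ndarray, tot9: np.ndarray, alpha_cell: float) -> np.ndarray:
    """MB-MDR statistic for binary traits from per-cell case/total counts.

    ``case9``/``tot9`` have shape ``(P, 9)``: the 9 two-locus genotype cells
    of P pairs, restricted to individuals non-missing at both loci.
    """
    crit = _chi2_dist.isf(alpha_cell, 1)
    case9 = np.asarray(case9, dtype=np.float64)
    tot9 = np.asarray(tot9, dtype=np.float64)
    n = tot9.sum(axis=1, keepdims=True)
    ncase = case9.sum(axis=1, keepdims=True)

    chi, valid = _chi2_2x2(case9, tot9, np.broadcast_to(ncase, case9.shape), n)
    sig = valid & (chi > crit)
    # sign of risk(cell) - risk(rest):  a/(a+b) - c/(c+d)
    risk = case9 * (n - tot9) - (ncase - case9) * tot9
    high = sig & (risk > 0)
    low = sig & (risk < 0)

    nf = n[:, 0]
    ncf = ncase[:, 0]

    def pooled(mask):
        a = (case9 * mask).sum(axis=1)
        row1 = (tot9 * mask).sum(axis=1)
        chi, valid = _chi2_2x2(a, row1, ncf, nf)
        return np.where(valid, chi, 0.0)

    return np.maximum(pooled(high), pooled(low))


def _pooled_t2(n1, s1, q1, n2, s2, q2):
    """Squared pooled-variance Student t of group1 vs group2.

    Groups enter as (count, trait sum, trait sum of squares).  Returns
    ``(t2, df, valid, diff)`` with ``diff = mean1 - mean2`` and
    ``df = n1 + n2 - 2``.  The pooled variance keeps the statistic on the
    chi-squared(1 df) scale even when one group is tiny — a group of one or
    two near-identical values cannot blow the statistic up the way a
    per-group (Welch) variance would.  Entries with an empty group, fewer
    than three observations overall, or zero pooled variance are invalid.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        df = n1 + n2 - 2.0
        sp2 = (np.maximum(q1 - s1 * m1, 0.0) + np.maximum(q2 - s2 * m2, 0.0)) / df
        diff = m1 - m2
        t2 = diff * diff / (sp2 * (1.0 / n1 + 1.0 / n2))
    valid = (n1 >= 1) & (n2 >= 1) & (df >= 1)
    with np.errstate(invalid="ignore"):
        valid &= sp2 > 0
    valid &= np.isfinite(t2)
    return t2, df, valid, diff


def stage_continuous(
    cnt9: np.ndarray, sum9: np.ndarray, sq9: np.ndarray, alpha_cell: float
) -> np.ndarray:
    """MB-MDR statistic for continuous traits from per-cell trait moments."""
    cnt9 = np.asarray(cnt9, dtype=np.float64)
    sum9 = np.asarray(sum9, dtype=np.float64)
    sq9 = np.asarray(sq9, dtype=np.float64)
    n = cnt9.sum(axis=1, keepdims=True)
    s = sum9.sum(axis=1, keepdims=True)
    q = sq9.sum(axis=1, keepdims=True)

    t2, df, valid, diff = _pooled_t2(cnt9, sum9, sq9, n - cnt9, s - sum9, q - sq9)
    with np.errstate(invalid="ignore"):
        pval = 2.0 * special.stdtr(np.where(valid, df, 1.0), -np.sqrt(np.where(valid, t2, 0.0)))
    sig = valid & (pval < alpha_cell)
    high = sig & (diff > 0)
    low = sig & (diff < 0)

    nf, sf, qf = n[:, 0], s[:, 0], q[:, 0]

    def pooled(mask):
        n1 = (cnt9 * mask).sum(axis=1)
        s1 = (sum9 * mask).sum(axis=1)
        q1 = (sq9 * mask).sum(axis=1)
        t2, _, valid, _ = _pooled_t2(n1, s1, q1, nf - n1, sf - s1, qf - q1)
        return np.where(valid, t2, 0.0)

    return np.maximum(pooled(high), pooled(low))


def _stats_from_counts(counts: list[np.ndarray], trait_type: str, alpha_cell: float):
    if trait_type == BINARY:
        tot9, case9 = counts
        return stage_binary(case9, tot9, alpha_cell)
    tot9, sum9, sq9 = counts
    return stage_continuous(tot9, sum9, sq9, alpha_cell)


def _weight_vectors(y: np.ndarray, trait_type: str) -> list[np.ndarray]:
    ones = np.ones_like(y)
    if trait_type == BINARY:
        return [ones, y]
    return [ones, y, y * y]


# ---------------------------------------------------------------------------
# all pairs via one-hot matrix products
# ---------------------------------------------------------------------------


def all_pair_statistics(
    dataset: Dataset,
    trait: np.ndarray | None = None,
    alpha_cell: float = 0.1,
    block: int = 256,
) -> np.ndarray:
    """Statistic of every unordered SNP pair, in lexicographic pair order.

    ``trait`` overrides the dataset's trait column (used for permutations);
    the trait type is taken from the dataset.
    """
    g = dataset.genotypes
    y = dataset.trait if trait is None else np.asarray(trait, dtype=np.float64)
    s = dataset.n_snps
    onehot = [(g == code).astype(np.float64) for code in (0, 1, 2)]
    weights = _weight_vectors(y, dataset.trait_type)
    # left factors: (3 genotype codes) x (weights), each (s, n_ind)
    lefts = [[(oh * w[:, None]).T for oh in onehot] for w in weights]

    out = np.empty(pair_count(s), dtype=np.float64)
    for j0 in range(1, s, block):
        j1 = min(j0 + block, s)
        cols = [oh[:, j0:j1] for oh in onehot]
        # row index i < column index j for pairs in this block
        jj = np.repeat(np.arange(j0, j1), np.arange(j0, j1))
        ii = np.concatenate([np.arange(j) for j in range(j0, j1)]) if j1 > j0 else jj
        jloc = jj - j0
        per_weight = []
        for lw in lefts:
            cells = np.empty((ii.size, 9), dtype=np.float64)
            for a in range(3):
                for b in range(3):
                    prod = lw[a] @ cols[b]  # (s, blk)
                    cells[:, 3 * a + b] = prod[ii, jloc]
            per_weight.append(cells)
        stats = _stats_from_counts(per_weight, dataset.trait_type, alpha_cell)
        out[pairs_to_ids(ii, jj, s)] = stats
    return out


# ---------------------------------------------------------------------------
# arbitrary pair lists via bincount
# ---------------------------------------------------------------------------


def _cell_codes(g: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flat 10-valued cell code (9 = missing) per (individual, pair)."""
    g1 = g[:, a]
    g2 = g[:, b]
    cell = (3 * g1 + g2).astype(np.int32)  # int8 arithmetic; min value -36
    cell[(g1 < 0) | (g2 < 0)] = 9
    return cell


def eval_pairs(
    dataset: Dataset,
    a_idx: np.ndarray,
    b_idx: np.ndarray,
    trait: np.ndarray | None = None,
    alpha_cell: float = 0.1,
    chunk: int = 4096,
) -> np.ndarray:
    """Statistic of the pairs ``(a_idx[k], b_idx[k])`` (0-based SNP indices)."""
    g = dataset.genotypes
    y = dataset.trait if trait is None else np.asarray(trait, dtype=np.float64)
    binary = dataset.trait_type == BINARY
    g_case = g[y == 1.0] if binary else None
    a_idx = np.asarray(a_idx, dtype=np.int64)
    b_idx = np.asarray(b_idx, dtype=np.int64)
    n_ind = g.shape[0]
    out = np.empty(a_idx.size, dtype=np.float64)
    wfull = wfull2 = None
    for c0 in range(0, a_idx.size, chunk):
        c1 = min(c0 + chunk, a_idx.size)
        p = c1 - c0
        a, b = a_idx[c0:c1], b_idx[c0:c1]
        offs = 10 * np.arange(p, dtype=np.int32)[None, :]
        flat = (_cell_codes(g, a, b) + offs).ravel()
        tot = np.bincount(flat, minlength=10 * p).reshape(p, 10)[:, :9]
        if binary:
            flat_case = (_cell_codes(g_case, a, b) + offs).ravel()
            case = np.bincount(flat_case, minlength=10 * p).reshape(p, 10)[:, :9]
            counts = [tot, case]
        else:
            if wfull is None or wfull.size != n_ind * p:
                wfull = np.repeat(y, p)
                wfull2 = np.repeat(y * y, p)
            s = np.bincount(flat, weights=wfull, minlength=10 * p).reshape(p, 10)[:, :9]
            q = np.bincount(flat, weights=wfull2, minlength=10 * p).reshape(p, 10)[:, :9]
            counts = [tot, s, q]
        out[c0:c1] = _stats_from_counts(counts, dataset.trait_type, alpha_cell)
    return out


# ---------------------------------------------------------------------------
# fixed pair list, repeated trait permutations
# ---------------------------------------------------------------------------


class FixedPairKernel:
    """Evaluate a fixed list of pairs under many trait permutations.

    Precomputes a ``(9 * n_pairs, n_individuals)`` cell-indicator matrix so
    each permutation reduces to one or two matrix-vector products, carried
    out in double precision so the results agree with the scalar reference
    path to the last bit for count data.
    """

    def __init__(self, dataset: Dataset, pairs: np.ndarray, alpha_cell: float = 0.1):
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        g = dataset.genotypes
        n_ind = g.shape[0]
        p = pairs.shape[0]
        g1 = g[:, pairs[:, 0]].T.astype(np.int64)  # (P, n_ind)
        g2 = g[:, pairs[:, 1]].T.astype(np.int64)
        cell = 3 * g1 + g2
        valid = (g1 >= 0) & (g2 >= 0)
        rows = 9 * np.arange(p, dtype=np.int64)[:, None] + cell
        cols = np.broadcast_to(np.arange(n_ind, dtype=np.int64), (p, n_ind))
        m = np.zeros((9 * p, n_ind), dtype=np.float64)
        m[rows[valid], cols[valid]] = 1.0
        self._m = m
        self._p = p
        self.pairs = pairs
        self.alpha_cell = alpha_cell
        self.trait_type = dataset.trait_type
        self._tot9 = (m @ np.ones(n_ind)).reshape(p, 9)

    def stats(self, trait: np.ndarray) -> np.ndarray:
        y = np.asarray(trait, dtype=np.float64)
        if self.trait_type == BINARY:
            case9 = (self._m @ y).reshape(self._p, 9)
            return stage_binary(case9, self._tot9, self.alpha_cell)
        s9 = (self._m @ y).reshape(self._p, 9)
        q9 = (self._m @ (y * y)).reshape(self._p, 9)
        return stage_continuous(self._tot9, s9, q9, self.alpha_cell)
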