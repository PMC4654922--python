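"""Step-down maxT permutation engines.

Three interchangeable backends estimate the same family of adjusted
p-values for the top-``n`` SNP pairs of an exhaustive interaction scan:

* ``classical`` — textbook Westfall-Young step-down maxT over all ``m``
  pairs (memory and time proportional to ``m``; the reference oracle).
* ``maxt`` — the memory-bounded variant: only the ``n`` best observed pairs
  are stored, and each permutation contributes its exact maximum ``M_i``
  over the remaining ``m - n`` pairs.
* ``gammamaxt`` — identical, except ``M_i`` is *sampled* from a fitted
  point-mass + shifted-gamma model of the null tail
  (:mod:`gammamaxt.gamma_null`), refit once every ``refit_interval``
  permutations.  This removes the O(B m) remainder sweep.

Reproducibility: one master seed; the permutation (and any tail sampling)
of iteration ``i`` draws from an independent substream keyed by
``(seed, i)``, so serial runs and block-parallel runs produce identical
results whenever blocks start on refit boundaries.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from . import gamma_null
from .dataset import Dataset
from .gamma_null import GammaTailFit, fit_tail, sample_max, sample_tail
from .kernels import (
    FixedPairKernel,
    all_pair_statistics,
    eval_pairs,
    ids_to_pairs,
    pair_count,
    pairs_to_ids,
)
from .mbmdr import TopList, correct_main_effects, scan_all_pairs

logger = logging.getLogger("gammamaxt")

_PERM_STREAM = 0x6D617854  # domain tag for per-permutation substreams

BACKENDS = ("classical", "maxt", "gammamaxt")


@dataclass
class PermutationRecord:
    """Top-n statistics of one permutation, after the remainder-maximum
    substitution and monotonicity enforcement."""

    i: int
    stats: np.ndarray
    M: float


@dataclass
class AdjustedResult:
    """Ranked pairs with step-down adjusted p-values.

    ``pairs`` holds 0-based SNP index pairs (a < b) sorted by non-increasing
    observed statistic; ``pvalues`` are non-decreasing and bounded below by
    ``1 / (B + 1)``.
    """

    pairs: np.ndarray
    stats: np.ndarray
    pvalues: np.ndarray
    B: int
    snp_ids: list[str] | None = None

    def __len__(self) -> int:
        return len(self.stats)


def perm_rng(seed: int, i: int) -> np.random.Generator:
    """Independent random substream for permutation ``i`` of a run."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_PERM_STREAM, int(i)))
    )


def permute_trait(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Dataset with the trait column uniformly permuted, genotypes untouched."""
    return dataset.with_trait(rng.permutation(dataset.trait))


def enforce_monotone_desc(stats: np.ndarray) -> np.ndarray:
    """Suffix maximum from the right: output[j] = max(stats[j:])."""
    return np.maximum.accumulate(np.asarray(stats, dtype=np.float64)[::-1])[::-1]


def exact_remainder_max(
    dataset: Dataset,
    top_pairs: np.ndarray,
    trait: np.ndarray | None = None,
    alpha_cell: float = 0.1,
) -> float:
    """Exact maximum statistic over all pairs not in ``top_pairs``.

    Returns 0.0 when no pairs remain (the empty-maximum convention).
    """
    s = dataset.n_snps
    stats = all_pair_statistics(dataset, trait=trait, alpha_cell=alpha_cell)
    top_pairs = np.asarray(top_pairs, dtype=np.int64).reshape(-1, 2)
    if top_pairs.shape[0] >= stats.size:
        return 0.0
    mask = np.ones(stats.size, dtype=bool)
    mask[pairs_to_ids(top_pairs[:, 0], top_pairs[:, 1], s)] = False
    rest = stats[mask]
    return float(rest.max()) if rest.size else 0.0


def finalize_pvalues(records: list[PermutationRecord], toplist: TopList) -> AdjustedResult:
    """Adjusted p-values from permutation records.

    ``p_j = (1 + #{i : T_{i,j} >= T_{0,j}}) / (B + 1)`` followed by the
    step-down monotonicity pass.
    """
    B = len(records)
    if B < 1:
        raise ValueError("need at least one permutation record")
    t0 = toplist.stats
    counts = np.zeros(len(t0), dtype=np.int64)
    for rec in records:
        counts += rec.stats >= t0
    return aggregate_counts([counts], toplist, B)


def aggregate_counts(
    count_vectors: list[np.ndarray], toplist: TopList, B: int
) -> AdjustedResult:
    """Sum per-block exceedance counts and convert to adjusted p-values."""
    total = np.zeros(len(toplist.stats), dtype=np.int64)
    for v in count_vectors:
        total += np.asarray(v, dtype=np.int64)
    p = (1.0 + total) / (B + 1.0)
    p = np.maximum.accumulate(p)
    return AdjustedResult(
        pairs=toplist.pairs.copy(), stats=toplist.stats.copy(), pvalues=p, B=B
    )


class PermutationEngine:
    """Per-permutation state machine shared by the maxT/gammaMAXT backends.

    Holds the fixed-pair kernel for the stored top pairs, the enumeration of
    unstored pairs, and (for the gamma backend) the cached tail fit, which is
    renewed whenever ``(i - 1) % refit_interval == 0``.
    """

    def __init__(
        self,
        dataset: Dataset,
        toplist: TopList,
        backend: str = "gammamaxt",
        seed: int = 0,
        S: int = gamma_null.DEFAULT_S,
        tail_fraction: float = gamma_null.DEFAULT_TAIL_FRACTION,
        refit_interval: int = gamma_null.DEFAULT_REFIT_INTERVAL,
        alpha_cell: float = 0.1,
        precision: float = gamma_null.DEFAULT_PRECISION,
        initial_guess: float = gamma_null.DEFAULT_INITIAL_GUESS,
    ):
        if backend not in ("maxt", "gammamaxt"):
            raise ValueError(f"unknown permutation backend {backend!r}")
        self.dataset = dataset
        self.toplist = toplist
        self.backend = backend
        self.seed = seed
        self.S = S
        self.tail_fraction = tail_fraction
        self.refit_interval = refit_interval
        self.alpha_cell = alpha_cell
        self.precision = precision
        self.initial_guess = initial_guess
        self.fit: GammaTailFit | None = None

        s = dataset.n_snps
        self.m = pair_count(s)
        top_ids = pairs_to_ids(toplist.pairs[:, 0], toplist.pairs[:, 1], s)
        self.n_top = len(top_ids)
        self.nontop_ids = np.setdiff1d(np.arange(self.m), top_ids)
        if backend == "gammamaxt":
            self._kernel = FixedPairKernel(dataset, toplist.pairs, alpha_cell)

    def _tail_source(self, trait: np.ndarray):
        """Batch statistic source over the unstored pairs.

        When the whole unstored set is no larger than a few times the tail
        sample size, evaluating every pair once (vectorized) and serving
        lookups is cheaper than on-demand evaluation of the (with
        replacement, hence partly duplicated) draws; beyond that the source
        evaluates only the requested pairs.
        """
        if self.nontop_ids.size <= 4 * min(self.S, max(100, self.nontop_ids.size)):
            stats_all = all_pair_statistics(
                self.dataset, trait=trait, alpha_cell=self.alpha_cell
            )
            rest = stats_all[self.nontop_ids]
            return lambda idx: rest[idx]

        a_all, b_all = ids_to_pairs(self.nontop_ids, self.dataset.n_snps)

        def source(idx: np.ndarray) -> np.ndarray:
            return eval_pairs(
                self.dataset, a_all[idx], b_all[idx], trait=trait,
                alpha_cell=self.alpha_cell,
            )

        return source

    def run_permutation(self, i: int) -> PermutationRecord:
        rng = perm_rng(self.seed, i)
        trait = rng.permutation(self.dataset.trait)
        if self.backend == "maxt":
            stats_all = all_pair_statistics(
                self.dataset, trait=trait, alpha_cell=self.alpha_cell
            )
            stats = stats_all[
                pairs_to_ids(
                    self.toplist.pairs[:, 0], self.toplist.pairs[:, 1],
                    self.dataset.n_snps,
                )
            ].copy()
            rest = stats_all[self.nontop_ids]
            m_i = float(rest.max()) if rest.size else 0.0
        else:
            stats = self._kernel.stats(trait)
            if self.nontop_ids.size == 0:
                m_i = 0.0
            else:
                if self.fit is None or (i - 1) % self.refit_interval == 0:
                    sample = sample_tail(
                        self._tail_source(trait),
                        self.m,
                        self.n_top,
                        S=self.S,
                        rng=rng,
                        tail_fraction=self.tail_fraction,
                    )
                    self.fit = fit_tail(sample, self.m, self.n_top)
                    self.fit.precision = self.precision
                    logger.info(
                        "permutation %d tail fit: pi=%.4f y0=%.4f k=%.4f theta=%.4f q=%.1f",
                        i, self.fit.pi, self.fit.y0, self.fit.k, self.fit.theta,
                        self.fit.q,
                    )
                m_i = sample_max(
                    self.fit, rng, initial_guess=self.initial_guess,
                    precision=self.precision,
                )
        if stats.size:
            stats[-1] = max(stats[-1], m_i)
        stats = enforce_monotone_desc(stats)
        return PermutationRecord(i=i, stats=stats, M=m_i)


def run_permutation(
    i: int, dataset: Dataset, toplist: TopList, backend: str, state: PermutationEngine
) -> PermutationRecord:
    """Single-permutation entry point operating on a shared engine state."""
    assert state.backend == backend and state.dataset is dataset
    return state.run_permutation(i)


def partition_permutations(
    B: int, workers: int, refit_interval: int = gamma_null.DEFAULT_REFIT_INTERVAL
) -> list[tuple[int, int]]:
    """Split permutations 1..B into contiguous half-open blocks ``[lo, hi)``.

    Block boundaries are aligned to refit indices (``i = 1 mod
    refit_interval``) so every block starts with a fresh tail fit and the
    blocked run reproduces the serial run exactly.
    """
    groups = [
        (g * refit_interval + 1, min((g + 1) * refit_interval, B) + 1)
        for g in range((B + refit_interval - 1) // refit_interval)
    ]
    workers = max(1, min(workers, len(groups)))
    bounds = np.linspace(0, len(groups), workers + 1).round().astype(int)
    blocks = []
    for w in range(workers):
        sel = groups[bounds[w]:bounds[w + 1]]
        if sel:
            blocks.append((sel[0][0], sel[-1][1]))
    return blocks


def _run_block(
    dataset: Dataset,
    toplist: TopList,
    lo: int,
    hi: int,
    backend: str,
    seed: int,
    S: int,
    tail_fraction: float,
    refit_interval: int,
    alpha_cell: float,
    precision: float,
    initial_guess: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Run permutations ``lo..hi-1``; return (exceedance counts, maxima)."""
    engine = PermutationEngine(
        dataset, toplist, backend=backend, seed=seed, S=S,
        tail_fraction=tail_fraction, refit_interval=refit_interval,
        alpha_cell=alpha_cell, precision=precision, initial_guess=initial_guess,
    )
    counts = np.zeros(len(toplist.stats), dtype=np.int64)
    maxima = np.empty(hi - lo)
    for i in range(lo, hi):
        rec = engine.run_permutation(i)
        counts += rec.stats >= toplist.stats
        maxima[i - lo] = rec.M
    return counts, maxima


def run_maxt(
    dataset: Dataset,
    n: int = 1000,
    B: int = 999,
    backend: str = "gammamaxt",
    S: int = gamma_null.DEFAULT_S,
    tail_fraction: float = gamma_null.DEFAULT_TAIL_FRACTION,
    refit_interval: int = gamma_null.DEFAULT_REFIT_INTERVAL,
    alpha_cell: float = 0.1,
    precision: float = gamma_null.DEFAULT_PRECISION,
    initial_guess: float = gamma_null.DEFAULT_INITIAL_GUESS,
    seed: int | None = None,
    workers: int = 1,
    adjust_main: bool = False,
    return_records: bool = False,
):
    """Full pipeline: exhaustive scan, B permutations, adjusted p-values.

    Deterministic for a fixed ``seed`` and any worker count.  With
    ``return_records=True`` (serial only) the per-permutation records are
    returned alongside the result.
    """
    if backend not in BACKENDS:
        raise ValueError(f"backend must be one of {BACKENDS}")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    if adjust_main:
        dataset = correct_main_effects(dataset)
    if backend == "classical":
        full = classical_maxt(dataset, B=B, seed=seed, alpha_cell=alpha_cell)
        k = min(n, len(full))
        return AdjustedResult(
            pairs=full.pairs[:k], stats=full.stats[:k], pvalues=full.pvalues[:k],
            B=B, snp_ids=dataset.snp_ids,
        )

    toplist = scan_all_pairs(dataset, n=n, alpha_cell=alpha_cell)
    kwargs = dict(
        backend=backend, seed=seed, S=S, tail_fraction=tail_fraction,
        refit_interval=refit_interval, alpha_cell=alpha_cell,
        precision=precision, initial_guess=initial_guess,
    )
    if return_records or workers <= 1:
        engine = PermutationEngine(dataset, toplist, **kwargs)
        records = [engine.run_permutation(i) for i in range(1, B + 1)]
        result = finalize_pvalues(records, toplist)
        result.snp_ids = dataset.snp_ids
        if return_records:
            return result, records
        return result

    blocks = partition_permutations(B, workers, refit_interval)
    with ProcessPoolExecutor(max_workers=len(blocks)) as pool:
        futures = [
            pool.submit(_run_block, dataset, toplist, lo, hi, **kwargs)
            for lo, hi in blocks
        ]
        counts = [f.result()[0] for f in futures]
    result = aggregate_counts(counts, toplist, B)
    result.snp_ids = dataset.snp_ids
    return result


def run_gammamaxt(dataset: Dataset, **kwargs) -> AdjustedResult:
    """Convenience wrapper for :func:`run_maxt` with the gamma backend."""
    kwargs.setdefault("backend", "gammamaxt")
    return run_maxt(dataset, **kwargs)


def classical_maxt(
    dataset: Dataset,
    B: int = 999,
    seed: int | None = None,
    alpha_cell: float = 0.1,
    adjust_main: bool = False,
) -> AdjustedResult:
    """Westfall-Young step-down maxT over all pairs (reference oracle).

    Shares the per-permutation random streams of :func:`run_maxt`, so the
    memory-bounded backends can be checked against it entry for entry.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    if adjust_main:
        dataset = correct_main_effects(dataset)
    s = dataset.n_snps
    t0 = all_pair_statistics(dataset, alpha_cell=alpha_cell)
    order = np.lexsort((np.arange(t0.size), -t0))
    t0_sorted = t0[order]
    counts = np.zeros(t0.size, dtype=np.int64)
    for i in range(1, B + 1):
        rng = perm_rng(seed, i)
        trait = rng.permutation(dataset.trait)
        stats = all_pair_statistics(dataset, trait=trait, alpha_cell=alpha_cell)
        counts += enforce_monotone_desc(stats[order]) >= t0_sorted
    p = np.maximum.accumulate((1.0 + counts) / (B + 1.0))
    a, b = ids_to_pairs(order, s)
    return AdjustedResult(
        pairs=np.column_stack([a, b]), stats=t0_sorted, pvalues=p, B=B,
        snp_ids=dataset.snp_ids,
    )


# ---------------------------------------------------------------------------
# split/merge parallel workflow over the scan
# ---------------------------------------------------------------------------


def split_scan(dataset: Dataset, n: int, workers: int, alpha_cell: float = 0.1) -> list[TopList]:
    """Scan contiguous blocks of the pair enumeration, one TopList each."""
    m = dataset.n_pairs
    bounds = np.linspace(0, m, max(1, workers) + 1).round().astype(int)
    out = []
    for w in range(len(bounds) - 1):
        lo, hi = int(bounds[w]), int(bounds[w + 1])
        if hi > lo:
            out.append(
                scan_all_pairs(
                    dataset, n=min(n, hi - lo), alpha_cell=alpha_cell,
                    pair_range=(lo, hi),
                )
            )
    return out


def merge_toplists(toplists: list[TopList], n: int, n_snps: int) -> TopList:
    """Keep the overall ``n`` best entries across worker top lists."""
    if not toplists:
        raise ValueError("no top lists to merge")
    pairs = np.concatenate([t.pairs for t in toplists])
    stats = np.concatenate([t.stats for t in toplists])
    ids = pairs_to_ids(pairs[:, 0], pairs[:, 1], n_snps)
    ids, keep = np.unique(ids, return_index=True)
    stats = stats[keep]
    order = np.lexsort((ids, -stats))[:n]
    a, b = ids_to_pairs(ids[order], n_snps)
    return TopList(pairs=np.column_stack([a, b]), stats=stats[order], capacity=n)
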