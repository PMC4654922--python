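"""Synthetic genotype/trait generators for the FWER and power experiments.

Covers the study conditions the correction is evaluated under:

* null datasets — Hardy-Weinberg genotypes with per-SNP minor allele
  frequencies drawn uniformly (default U(0.05, 0.5)), and a trait assigned
  independently of the genotypes (balanced case/control, or standard
  normal);
* two-locus pure-epistasis datasets — one functional SNP pair whose
  penetrance follows a checkerboard table with no marginal (main) effects,
  all other SNPs null; a balanced case/control design obtained by
  rejection sampling, or a continuous analogue with a Gaussian trait;
* heritability-calibrated models — the checkerboard deviation amplitude is
  solved (Brent root-finding) so the broad-sense heritability
  ``h2 = sum_g p_g (f_g - K)^2 / (K (1 - K))`` on the penetrance scale hits
  a requested target;
* missingness injection — independent per-genotype dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dataset import BINARY, MISSING, Dataset

#: Checkerboard penetrance table with baseline risk 0.05 and deviation 0.05:
#: at MAF 0.5 every single-locus genotype carries the same marginal risk, so
#: the association is purely epistatic.
CHECKERBOARD_PENETRANCE = np.array(
    [
        [0.0, 0.1, 0.0],
        [0.1, 0.0, 0.1],
        [0.0, 0.1, 0.0],
    ]
)


@dataclass
class PenetranceModel:
    """3x3 two-locus penetrance table with locus allele frequencies.

    ``pen[i, j]`` is P(case | i copies of the minor allele at locus A and
    j copies at locus B); rows/columns follow the 0/1/2 additive coding.
    """

    pen: np.ndarray
    maf_a: float = 0.5
    maf_b: float = 0.5

    def __post_init__(self):
        self.pen = np.asarray(self.pen, dtype=np.float64)
        if self.pen.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if ((self.pen < 0) | (self.pen > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def genotype_probs(self) -> np.ndarray:
        """Hardy-Weinberg joint genotype probabilities, shape (3, 3)."""
        return np.outer(hw_probs(self.maf_a), hw_probs(self.maf_b))

    @property
    def prevalence(self) -> float:
        return float((self.genotype_probs * self.pen).sum())


@dataclass
class SimConfig:
    """Dimensions and nuisance settings of a simulated dataset."""

    n_snps: int = 1000
    n_individuals: int = 1000
    trait_type: str = BINARY
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    balanced: bool = True

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class EpistasisData:
    """Simulated dataset with its causal pair flagged."""

    dataset: Dataset
    causal_pair: tuple[int, int]
    model: PenetranceModel


def hw_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities for 0/1/2 minor-allele copies."""
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def heritability(model: PenetranceModel) -> float:
    """Broad-sense variance explained on the penetrance scale.

    ``h2 = sum_g p_g (f_g - K)^2 / (K (1 - K))`` with ``K`` the prevalence.
    """
    k = model.prevalence
    if not 0.0 < k < 1.0:
        raise ValueError("degenerate model: prevalence must lie strictly in (0, 1)")
    probs = model.genotype_probs
    return float((probs * (model.pen - k) ** 2).sum() / (k * (1.0 - k)))


def _epistatic_contrast(maf_a: float, maf_b: float) -> np.ndarray:
    """Rank-one deviation pattern -u u^T with zero Hardy-Weinberg marginals.

    ``u = (-1, c, -1)`` with ``c`` chosen so ``sum_g p_g u_g = 0``; the outer
    product then has exactly zero marginal penetrance deviations at both
    loci, i.e. pure epistasis for any allele frequency.  The sign is chosen
    so that at MAF 0.5 the pattern is the classic checkerboard with elevated
    risk in the cells of odd minor-allele count (heterozygous at exactly one
    locus), depressed risk elsewhere.
    """

    def contrast(maf):
        p = hw_probs(maf)
        return np.array([-1.0, (p[0] + p[2]) / p[1], -1.0])

    return -np.outer(contrast(maf_a), contrast(maf_b))


def calibrate_penetrance(
    h2_target: float,
    maf: float = 0.5,
    base: float = 0.05,
    maf_b: float | None = None,
) -> PenetranceModel:
    """Checkerboard penetrance model with heritability ``h2_target``.

    The deviation amplitude of a zero-main-effect contrast pattern around
    the baseline risk ``base`` is solved by scalar root-finding so that
    :func:`heritability` returns the target to within 1e-6.  Marginal
    single-locus penetrances stay constant (no main effects).
    """
    if maf_b is None:
        maf_b = maf
    pattern = _epistatic_contrast(maf, maf_b)
    if h2_target < 0:
        raise ValueError("heritability target must be non-negative")
    amp_max = min(
        float((base / np.abs(pattern[pattern < 0])).min()),
        float(((1.0 - base) / np.abs(pattern[pattern > 0])).min()),
    )

    def model_at(a: float) -> PenetranceModel:
        return PenetranceModel(
            pen=np.clip(base + a * pattern, 0.0, 1.0), maf_a=maf, maf_b=maf_b
        )

    h2_max = heritability(model_at(amp_max))
    if h2_target > h2_max:
        raise ValueError(
            f"heritability target {h2_target} unreachable; maximum achievable "
            f"for this pattern is {h2_max:.6g}"
        )
    if h2_target == 0:
        return model_at(0.0)
    amp = optimize.brentq(
        lambda a: heritability(model_at(a)) - h2_target, 0.0, amp_max, xtol=1e-12
    )
    return model_at(amp)


def table_model(maf: float = 0.5) -> PenetranceModel:
    """The canonical checkerboard model (baseline 0.05, deviation 0.05)."""
    return PenetranceModel(pen=CHECKERBOARD_PENETRANCE, maf_a=maf, maf_b=maf)


def _null_genotypes(
    n_ind: int, n_snps: int, maf_range, rng: np.random.Generator
) -> np.ndarray:
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    return rng.binomial(2, mafs, size=(n_ind, n_snps)).astype(np.int8)


def simulate_null(config: SimConfig, rng: np.random.Generator) -> Dataset:
    """Null dataset: genotypes independent of the trait.

    Binary traits get exactly ``floor(n/2)`` cases; continuous traits are
    standard normal.
    """
    g = _null_genotypes(config.n_individuals, config.n_snps, config.maf_range, rng)
    if config.trait_type == BINARY:
        trait = np.zeros(config.n_individuals)
        trait[: config.n_individuals // 2] = 1.0
        trait = rng.permutation(trait)
    else:
        trait = rng.standard_normal(config.n_individuals)
    ds = Dataset(genotypes=g, trait=trait, trait_type=config.trait_type)
    if config.missing_rate > 0:
        ds = inject_missing(ds, config.missing_rate, rng)
    return ds


def _sample_functional_binary(
    model: PenetranceModel, n_cases: int, n_controls: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample functional genotypes until the balanced design fills."""
    k = model.prevalence
    if not 0.0 < k < 1.0:
        raise ValueError("degenerate model: prevalence must lie strictly in (0, 1)")
    probs = model.genotype_probs.ravel()
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    batch = max(256, 4 * (n_cases + n_controls))
    while n_case_have < n_cases or n_ctrl_have < n_controls:
        cells = rng.choice(9, size=batch, p=probs)
        g1, g2 = cells // 3, cells % 3
        affected = rng.uniform(size=batch) < model.pen[g1, g2]
        cases.append(np.column_stack([g1, g2])[affected])
        controls.append(np.column_stack([g1, g2])[~affected])
        n_case_have += int(affected.sum())
        n_ctrl_have += int((~affected).sum())
    case_g = np.concatenate(cases)[:n_cases]
    ctrl_g = np.concatenate(controls)[:n_controls]
    geno = np.concatenate([case_g, ctrl_g]).astype(np.int8)
    trait = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    order = rng.permutation(n_cases + n_controls)
    return geno[order, 0], geno[order, 1], trait[order]


def simulate_epistasis(
    model: PenetranceModel, config: SimConfig, rng: np.random.Generator
) -> EpistasisData:
    """Dataset with one functional (epistatic) SNP pair, the rest null.

    Binary traits: case/control status follows the penetrance table, with
    rejection sampling until the balanced design is reached.  Continuous
    traits: ``trait = mu * z + N(0, 1)`` where ``z`` is the standardized
    epistatic contrast of the two functional genotypes and ``mu`` is set so
    the model explains ``h2`` of the trait variance.
    """
    n_ind, n_snps = config.n_individuals, config.n_snps
    if n_snps < 2:
        raise ValueError("need at least two SNPs")
    if config.trait_type == BINARY:
        n_cases = n_ind // 2
        g1, g2, trait = _sample_functional_binary(model, n_cases, n_ind - n_cases, rng)
    else:
        h2 = heritability(model)
        probs = model.genotype_probs.ravel()
        cells = rng.choice(9, size=n_ind, p=probs)
        g1, g2 = (cells // 3).astype(np.int8), (cells % 3).astype(np.int8)
        contrast = _epistatic_contrast(model.maf_a, model.maf_b)
        zval = contrast[g1, g2]
        mean = (model.genotype_probs * contrast).sum()
        sd = np.sqrt((model.genotype_probs * (contrast - mean) ** 2).sum())
        z = (zval - mean) / sd
        mu = np.sqrt(h2 / (1.0 - h2))
        trait = mu * z + rng.standard_normal(n_ind)

    geno = _null_genotypes(n_ind, n_snps, config.maf_range, rng)
    causal = tuple(sorted(rng.choice(n_snps, size=2, replace=False).tolist()))
    geno[:, causal[0]] = g1
    geno[:, causal[1]] = g2
    ds = Dataset(genotypes=geno, trait=trait, trait_type=config.trait_type)
    if config.missing_rate > 0:
        ds = inject_missing(ds, config.missing_rate, rng)
    return EpistasisData(dataset=ds, causal_pair=causal, model=model)


def inject_missing(dataset: Dataset, rate: float, rng: np.random.Generator) -> Dataset:
    """Set each genotype to MISSING independently with probability ``rate``.

    The trait column is never blanked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return dataset
    g = dataset.genotypes.copy()
    g[rng.uniform(size=g.shape) < rate] = MISSING
    return Dataset(
        genotypes=g, trait=dataset.trait.copy(), trait_type=dataset.trait_type,
        snp_ids=list(dataset.snp_ids),
    )
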