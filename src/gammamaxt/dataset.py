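"""Genotype/trait dataset container.

A dataset couples a rectangular genotype matrix (individuals x SNPs, additive
coding 0/1/2 with a sentinel for missing calls) with a single trait column,
either binary case/control (0/1) or continuous. Every scan, permutation run
and simulator in this package consumes or produces this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel for a missing genotype call (internal coding; the text format
#: uses a configurable token, "-9" by default).
MISSING = -9

BINARY = "binary"
CONTINUOUS = "continuous"

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class Dataset:
    """Genotype matrix plus one trait column.

    Parameters
    ----------
    genotypes
        Integer matrix of shape ``(n_individuals, n_snps)`` with entries in
        ``{0, 1, 2, MISSING}`` (copies of the minor allele).
    trait
        Vector of length ``n_individuals``; values in ``{0, 1}`` when
        ``trait_type == "binary"``, arbitrary reals otherwise.
    trait_type
        ``"binary"`` or ``"continuous"``.
    snp_ids
        Optional labels, one per SNP column; defaults to ``SNP1..SNPs``.
    """

    genotypes: np.ndarray
    trait: np.ndarray
    trait_type: str
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.trait = np.asarray(self.trait, dtype=np.float64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d matrix")
        if self.trait.ndim != 1 or self.trait.shape[0] != self.genotypes.shape[0]:
            raise ValueError("trait length must equal the number of genotype rows")
        if self.trait_type not in (BINARY, CONTINUOUS):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == BINARY and not np.isin(self.trait, (0.0, 1.0)).all():
            raise ValueError("binary trait may only contain 0/1 values")
        codes = np.unique(self.genotypes)
        bad = [int(c) for c in codes if int(c) not in _VALID_CODES]
        if bad:
            raise ValueError(f"invalid genotype codes present: {bad}")
        if not self.snp_ids:
            self.snp_ids = [f"SNP{i + 1}" for i in range(self.genotypes.shape[1])]
        elif len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError("snp_ids length must equal the number of SNP columns")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_pairs(self) -> int:
        s = self.n_snps
        return s * (s - 1) // 2

    def with_trait(self, trait: np.ndarray, trait_type: str | None = None) -> "Dataset":
        """Copy of this dataset with the trait column replaced."""
        return replace(
            self,
            trait=np.asarray(trait, dtype=np.float64),
            trait_type=self.trait_type if trait_type is None else trait_type,
        )
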