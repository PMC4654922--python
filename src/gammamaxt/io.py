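"""Plain-text dataset, top-list and result serialization.

Dataset dialect: whitespace/tab separated; a header row starting with
``trait`` followed by the SNP ids; one row per individual holding the trait
value and the 0/1/2 genotype codes, with a configurable missing token
(default ``-9``).  All other files are TSV with a header:

* topfile — ``rank  snp_a  snp_b  statistic`` (1-based SNP indices);
* permutation counts — per-block exceedance count vectors with a comment
  line recording the block of permutation indices it covers;
* results — ``rank  snp_a  snp_b  statistic  adjusted_p`` at full double
  precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dataset import BINARY, MISSING, Dataset
from .engine import AdjustedResult
from .mbmdr import TopList

DEFAULT_MISSING_CODE = "-9"


def read_dataset(
    path, trait_type: str, missing_code: str = DEFAULT_MISSING_CODE
) -> Dataset:
    """Parse the plain-text dataset dialect, validating codes and trait."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if not header or header[0].lower() != "trait":
            raise ValueError(f"{path}: header must start with 'trait'")
        snp_ids = header[1:]
        n_snps = len(snp_ids)
        if n_snps == 0:
            raise ValueError(f"{path}: no SNP columns in header")
        traits: list[float] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != n_snps + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_snps + 1} fields, got {len(tokens)}"
                )
            try:
                t = float(tokens[0])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: invalid trait value {tokens[0]!r}")
            if trait_type == BINARY and t not in (0.0, 1.0):
                raise ValueError(f"{path}:{lineno}: binary trait value must be 0 or 1")
            row = []
            for col, tok in enumerate(tokens[1:], start=1):
                if tok == missing_code:
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: unknown genotype code {tok!r} in column "
                        f"{col} ({snp_ids[col - 1]})"
                    )
            traits.append(t)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return Dataset(
        genotypes=np.array(rows, dtype=np.int8),
        trait=np.array(traits),
        trait_type=trait_type,
        snp_ids=snp_ids,
    )


def write_dataset(
    dataset: Dataset, path, missing_code: str = DEFAULT_MISSING_CODE
) -> None:
    path = Path(path)
    fmt = "%g" if dataset.trait_type == BINARY else "%.17g"
    with path.open("w") as fh:
        fh.write("trait\t" + "\t".join(dataset.snp_ids) + "\n")
        for t, row in zip(dataset.trait, dataset.genotypes):
            codes = [missing_code if g == MISSING else str(int(g)) for g in row]
            fh.write(fmt % t + "\t" + "\t".join(codes) + "\n")


def write_toplist(toplist: TopList, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("rank\tsnp_a\tsnp_b\tstatistic\n")
        for rank, ((a, b), t) in enumerate(zip(toplist.pairs, toplist.stats), start=1):
            fh.write(f"{rank}\t{a + 1}\t{b + 1}\t{float(t)!r}\n")


def read_toplist(path) -> TopList:
    pairs, stats = [], []
    with Path(path).open() as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            _, a, b, t = line.split("\t")
            pairs.append((int(a) - 1, int(b) - 1))
            stats.append(float(t))
    return TopList(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        stats=np.array(stats),
        capacity=len(stats),
    )


def write_counts(counts: np.ndarray, path, lo: int, hi: int, B: int, seed: int) -> None:
    """Per-block exceedance counts (permutations lo..hi-1 of 1..B)."""
    with Path(path).open("w") as fh:
        fh.write(f"# block\t{lo}\t{hi}\tB\t{B}\tseed\t{seed}\n")
        fh.write("rank\tcount\n")
        for rank, c in enumerate(counts, start=1):
            fh.write(f"{rank}\t{int(c)}\n")


def read_counts(path) -> tuple[np.ndarray, dict]:
    with Path(path).open() as fh:
        meta_line = fh.readline().split("\t")
        meta = {"lo": int(meta_line[1]), "hi": int(meta_line[2]),
                "B": int(meta_line[4]), "seed": int(meta_line[6])}
        fh.readline()
        counts = [int(line.split("\t")[1]) for line in fh if line.strip()]
    return np.array(counts, dtype=np.int64), meta


def write_results(result: AdjustedResult, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("rank\tsnp_a\tsnp_b\tstatistic\tadjusted_p\n")
        for rank, ((a, b), t, p) in enumerate(
            zip(result.pairs, result.stats, result.pvalues), start=1
        ):
            fh.write(f"{rank}\t{a + 1}\t{b + 1}\t{float(t)!r}\t{float(p)!r}\n")


def read_results(path) -> AdjustedResult:
    pairs, stats, pvals = [], [], []
    with Path(path).open() as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            _, a, b, t, p = line.split("\t")
            pairs.append((int(a) - 1, int(b) - 1))
            stats.append(float(t))
            pvals.append(float(p))
    return AdjustedResult(
        pairs=np.array(pairs, dtype=np.int64).reshape(-1, 2),
        stats=np.array(stats),
        pvalues=np.array(pvals),
        B=0,
    )


def write_model_sidecar(path, model, causal_pair=None, extra=None) -> None:
    """JSON sidecar describing a simulated penetrance model."""
    from .simulate import heritability

    payload = {
        "penetrance": model.pen.tolist(),
        "maf_a": model.maf_a,
        "maf_b": model.maf_b,
        "prevalence": model.prevalence,
        "heritability": heritability(model),
    }
    if causal_pair is not None:
        payload["causal_pair_1based"] = [causal_pair[0] + 1, causal_pair[1] + 1]
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
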