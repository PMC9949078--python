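"""Shared test utilities: deterministic count generators and brute-force oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd


def nb_counts(seed: int, n_genes: int = 200, n_samples: int = 6) -> pd.DataFrame:
    """Deterministic negative-binomial count matrix (gamma-Poisson, dispersion 0.1)."""
    rng = np.random.default_rng([9000, seed])
    mu = rng.lognormal(np.log(100.0), 1.5, n_genes)
    size_factor = rng.uniform(0.5, 1.5, n_samples)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        lam = rng.gamma(10.0, mu * size_factor[j] * 0.1)
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


def bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    """Plain Benjamini–Hochberg step-up by explicit enumeration."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * level
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))  # largest i with p_(i) <= i/m * level
        reject[order[: k + 1]] = True
    return reject


def bky_reject_bruteforce(p: np.ndarray, q: float) -> np.ndarray:
    """Two-stage adaptive step-up by explicit enumeration of both stages.

    Stage 1: BH at q' = q/(1+q); r1 rejections. r1 = 0 -> reject nothing,
    r1 = m -> reject everything; otherwise stage 2 is BH at q'*m/(m-r1).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    q_prime = q / (1.0 + q)
    stage1 = bh_reject(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return bh_reject(p, q_prime * m / (m - r1))


def random_marker_table(
    seed: int, n_rows: int = 50, n_types: int = 6, n_symbols: int = 30
) -> pd.DataFrame:
    """Marker rows with seeded cross-cell-type duplicates."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "gene_symbol": [f"G{rng.integers(n_symbols):03d}" for _ in range(n_rows)],
            "expression": rng.lognormal(2, 1, n_rows),
            "cell_type": [f"type{rng.integers(n_types)}" for _ in range(n_rows)],
        }
    )


def set_algebra_unique_markers(records: pd.DataFrame) -> dict[str, str]:
    """Reference-builder oracle: symbols listed under exactly one distinct cell type."""
    by_gene: dict[str, set[str]] = {}
    for sym, ct in zip(records["gene_symbol"], records["cell_type"]):
        by_gene.setdefault(sym.strip().upper(), set()).add(ct)
    return {sym: next(iter(cts)) for sym, cts in by_gene.items() if len(cts) == 1}
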