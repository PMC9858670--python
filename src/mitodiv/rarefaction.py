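"""Haplotype accumulation (rarefaction) curves.

The permutation estimator repeatedly shuffles the order in which sampled
individuals are inspected and counts how many distinct haplotypes appear
among the first g of them, for g = 1..n.  The exact expectation has the
classical hypergeometric closed form

    E[K_g] = sum_h [1 - C(n - c_h, g) / C(n, g)],

which serves as an independent oracle for the Monte-Carlo curve.  The curve
is interpolation-only: no extrapolated richness beyond the observed n.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = ["AccumulationCurve", "haplotype_accumulation", "expected_accumulation_exact"]


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean accumulated haplotype count and its spread per subsample size.

    ``se`` is the standard deviation across permutations (the ribbon
    convention of the usual accumulation-curve helpers, not SD/sqrt(B)).
    """

    g: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_perm: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"g": self.g, "mean": self.mean, "se": self.se})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def haplotype_accumulation(assignments, n_perm: int = 1000, seed: int | None = None) -> AccumulationCurve:
    """Accumulation curve by random permutation of individuals.

    Parameters
    ----------
    assignments : mapping id -> haplotype, or sequence of haplotype labels
    n_perm : number of random orderings
    seed : RNG seed recorded in the result
    """
    labels = list(assignments.values()) if hasattr(assignments, "values") else list(assignments)
    n = len(labels)
    if n < 1 or n_perm < 1:
        raise ValueError("need n >= 1 individuals and n_perm >= 1")
    _, codes = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        order = rng.permutation(n)
        perm = codes[order]
        # first-occurrence indicator -> cumulative distinct count
        seen = np.zeros(codes.max() + 1, dtype=bool)
        new = np.empty(n, dtype=np.int64)
        for i, c in enumerate(perm):
            new[i] = not seen[c]
            seen[c] = True
        curves[b] = np.cumsum(new)
    return AccumulationCurve(
        g=np.arange(1, n + 1),
        mean=curves.mean(axis=0),
        se=curves.std(axis=0, ddof=0),
        n_perm=n_perm,
        seed=seed,
    )


def expected_accumulation_exact(counts) -> np.ndarray:
    """Exact E[K_g] for g = 1..n from haplotype counts (closed form)."""
    c = np.asarray(counts, dtype=int)
    if c.size == 0 or (c < 1).any():
        raise ValueError("counts must be nonempty with all entries >= 1")
    n = int(c.sum())
    out = np.empty(n, dtype=float)
    for g in range(1, n + 1):
        denom = comb(n, g)
        out[g - 1] = sum(1.0 - comb(n - ch, g) / denom for ch in c)
    return out
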