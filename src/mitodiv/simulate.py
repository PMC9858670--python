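"""Synthetic data with the statistical structure the estimators assume.

Three generative layers:

* :func:`sample_esf_partition` — haplotype frequencies from the Ewens
  sampling formula via the Hoppe urn / Chinese-restaurant process (the model
  the Ewens theta estimator inverts);
* :func:`coalescent_infinite_sites` — a neutral Kingman coalescent with
  Poisson infinite-sites mutations, yielding aligned sequences with
  E[S] = theta * a1 and E[mean pairwise differences] = theta;
* :func:`mask_missing` — per-individual random site masking that mimics the
  incomplete consensus sequences of low-coverage museum specimens.

:func:`simulate_two_epoch` composes them into a historical/modern study
design: one haplotype pool, a historical sample, Wright-Fisher drift of the
haplotype frequencies (no new mutations — the drift phase spans decades,
far below the mutational timescale of mtDNA), then a modern sample.  The
default configuration mirrors the whole-mitogenome regime of the wolf study
this package emulates: n = 19/29, L = 15,460, theta = 11.7 (about 41
segregating sites), drift at N_e = 350 breeding females for 12 generations,
historical missing fractions uniform on [0, 0.3].

A single seed fans out deterministically to the component stages through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, GroupAssignment
from .diversity import harmonic_numbers

__all__ = [
    "SimulationConfig",
    "sample_esf_partition",
    "coalescent_infinite_sites",
    "mask_missing",
    "simulate_two_epoch",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Two-epoch study design (defaults: whole-mitogenome regime)."""

    theta: float = 11.7
    n_historical: int = 19
    n_modern: int = 29
    L: int = 15460
    seed: int | None = None
    missing_fraction_max: float = 0.3
    drift_ne: int = 350
    drift_generations: int = 12
    pool_size: int = 60  # extra lineages carrying unsampled diversity

    def __post_init__(self) -> None:
        if self.theta < 0 or self.L < 1:
            raise ValueError("need theta >= 0 and L >= 1")
        if self.n_historical < 2 or self.n_modern < 2:
            raise ValueError("need n >= 2 per epoch")
        if not 0.0 <= self.missing_fraction_max <= 1.0:
            raise ValueError("missing_fraction_max must be in [0, 1]")


def control_region_config(seed: int | None = None) -> SimulationConfig:
    """Short-fragment regime: 425 bp, about 6 segregating sites."""
    return SimulationConfig(theta=1.7, n_historical=17, n_modern=27, L=425, seed=seed)


def sample_esf_partition(theta: float, n: int, seed=None) -> np.ndarray:
    """Haplotype counts for a sample of n under the Ewens sampling formula.

    Hoppe urn: individual i+1 founds a new haplotype with probability
    theta/(theta+i), otherwise copies a uniformly chosen previous one.
    """
    if theta < 0 or n < 1:
        raise ValueError("need theta >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    counts = [1]
    for i in range(1, n):
        if rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            probs = np.array(counts, dtype=float) / i
            counts[rng.choice(len(counts), p=probs)] += 1
    return np.array(counts, dtype=int)


def coalescent_infinite_sites(n: int, theta: float, L: int, seed=None) -> Alignment:
    """Alignment of n sequences from a neutral coalescent, infinite sites.

    A Kingman tree (exponential coalescence times at rate k(k-1)/2 while k
    lineages remain) receives Poisson(theta/2 * total branch length)
    mutations, each on a branch chosen proportionally to its length and at a
    fresh uniformly chosen site.  Sequence ids are ``seq1..seqN``.
    """
    if n < 1 or theta < 0 or L < 1:
        raise ValueError("need n >= 1, theta >= 0, L >= 1")
    if theta * harmonic_numbers(max(n, 2))[0] > L / 2:
        raise ValueError(
            "expected segregating sites exceed L/2; increase L for an "
            "infinite-sites approximation"
        )
    rng = np.random.default_rng(seed)
    # branches as (leaf set, length); build by merging lineages backwards
    lineages: list[tuple[frozenset, float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[tuple[frozenset, float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        lineages = [(s, b + t) for s, b in lineages]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        si, bi = lineages[i]
        sj, bj = lineages[j]
        branches.append((si, bi))
        branches.append((sj, bj))
        merged = (si | sj, 0.0)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)

    data = np.empty((n, L), dtype="S1")
    anc = rng.choice(_BASES, size=L)
    data[:] = anc
    if branches and theta > 0:
        lengths = np.array([b for _, b in branches])
        total = lengths.sum()
        n_mut = rng.poisson(theta / 2.0 * total)
        if n_mut > L:
            raise ValueError("drew more mutations than sites; increase L")
        sites = rng.choice(L, size=n_mut, replace=False)
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        for site, bi in zip(sites, which):
            carriers = list(branches[bi][0])
            current = data[carriers[0], site]
            alt = rng.choice(_BASES[_BASES != current])
            data[carriers, site] = alt
    ids = tuple(f"seq{i + 1}" for i in range(n))
    return Alignment(ids, data)


def mask_missing(aln: Alignment, per_individual_fractions, seed=None) -> Alignment:
    """Set floor(f * L) uniformly chosen sites to N, per individual."""
    fracs = np.asarray(per_individual_fractions, dtype=float)
    if fracs.shape != (aln.n,):
        raise ValueError("need one missing fraction per sequence")
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    data = aln.data.copy()
    for i, f in enumerate(fracs):
        k = int(f * aln.L)
        if k:
            sites = rng.choice(aln.L, size=k, replace=False)
            data[i, sites] = b"N"
    return Alignment(aln.ids, data)


def simulate_two_epoch(config: SimulationConfig) -> tuple[Alignment, Alignment, GroupAssignment]:
    """Historical and modern alignments from one drifting haplotype pool.

    Returns ``(historical, modern, groups)`` with ids ``hist1..``/``mod1..``
    and group labels "historical"/"modern".
    """
    ss = np.random.SeedSequence(config.seed)
    s_pool, s_hist_pick, s_drift, s_mod_pick, s_mask = ss.spawn(5)

    m = config.n_historical + config.pool_size
    pool = coalescent_infinite_sites(m, config.theta, config.L, s_pool)

    rng_hist = np.random.default_rng(s_hist_pick)
    hist_idx = rng_hist.choice(m, size=config.n_historical, replace=False)
    hist_data = pool.data[hist_idx].copy()

    # distinct pool haplotypes and their initial frequencies
    keys, inverse = np.unique(
        pool.data.view(f"S{config.L}").ravel(), return_inverse=True
    )
    freqs = np.bincount(inverse, minlength=len(keys)).astype(float)
    freqs /= freqs.sum()

    rng_drift = np.random.default_rng(s_drift)
    for _ in range(config.drift_generations):
        counts = rng_drift.multinomial(config.drift_ne, freqs)
        freqs = counts / config.drift_ne
    if np.count_nonzero(freqs) == 1:
        import warnings

        warnings.warn("drift fixed a single haplotype; modern sample is monomorphic",
                      stacklevel=2)

    rng_mod = np.random.default_rng(s_mod_pick)
    mod_choice = rng_mod.choice(len(keys), size=config.n_modern, p=freqs)
    mod_data = (
        keys[mod_choice].view("S1").reshape(config.n_modern, config.L).copy()
    )

    hist_ids = tuple(f"hist{i + 1}" for i in range(config.n_historical))
    mod_ids = tuple(f"mod{i + 1}" for i in range(config.n_modern))
    historical = Alignment(hist_ids, hist_data)
    modern = Alignment(mod_ids, mod_data)

    if config.missing_fraction_max > 0:
        rng_mask = np.random.default_rng(s_mask)
        fracs = rng_mask.uniform(0, config.missing_fraction_max, size=config.n_historical)
        historical = mask_missing(historical, fracs, rng_mask)

    groups = GroupAssignment(
        {**{i: "historical" for i in hist_ids}, **{i: "modern" for i in mod_ids}}
    )
    return historical, modern, groups
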