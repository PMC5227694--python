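"""Protein-level PTM co-occurrence against empirical resampling nulls.

The observed quantity is the proportion of a target protein set (here, the
sulfoxidized proteins) that also belongs to another modified set.  Its
significance is assessed against nulls built by resampling same-sized protein
sets from the whole proteome, either uniformly or stratified by protein
abundance so the resampled sets are indistinguishable in abundance from the
target — the control for mass-spectrometry detection bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ptm_tables import ProteinSet
from .stats_core import NullDistribution, empirical_p, ks_two_sample


@dataclass
class OverlapResult:
    observed_proportion: float
    null: NullDistribution
    p: float
    is_bound: bool


@dataclass
class MatchingDiagnostics:
    """Per-sample abundance-matching quality of a stratified null."""

    mean_log10_abundance: np.ndarray   # one value per sample
    ks_statistic: np.ndarray
    ks_p: np.ndarray
    target_mean_log10: float
    quartile_bounds: np.ndarray        # min, q25, q50, q75, max of the target
    strata_sizes: tuple[int, ...]


def overlap_proportion(target: Iterable[str], other: Iterable[str]) -> float:
    """|target intersect other| / |target|."""
    target = set(target)
    if not target:
        raise ValueError("target set must be non-empty")
    other = set(other)
    return len(target & other) / len(target)


def _sample_indices(rng: np.random.Generator, n_pop: int, size: int,
                    n_samples: int) -> np.ndarray:
    """(n_samples, size) index matrix, without replacement within a sample."""
    if n_samples * n_pop <= 40_000_000:
        order = np.argpartition(rng.random((n_samples, n_pop)),
                                size - 1, axis=1)
        return order[:, :size]
    return np.stack([rng.choice(n_pop, size, replace=False)
                     for _ in range(n_samples)])


def null_overlap(proteome: ProteinSet, other: Iterable[str], sample_size: int,
                 n_samples: int = 10_000, seed: int = 0,
                 method: str = "exact") -> NullDistribution:
    """Null overlap proportions from uniform same-size resampling.

    Each of ``n_samples`` samples draws ``sample_size`` proteins uniformly
    without replacement (independently across samples) and records the
    proportion that belongs to ``other``.  The default ``method='exact'``
    draws the intersection count directly from its hypergeometric law —
    distributionally identical to materializing the samples but far cheaper;
    ``method='count'`` materializes the index samples (the two agree in
    distribution, which the test suite checks).
    """
    accs = proteome.accessions()
    if sample_size > len(accs):
        raise ValueError("sample_size exceeds proteome size")
    other = set(other)
    member = np.array([a in other for a in accs], dtype=float)
    rng = np.random.default_rng(seed)
    n_good = int(member.sum())
    if method == "exact":
        counts = rng.hypergeometric(n_good, len(accs) - n_good, sample_size,
                                    size=n_samples)
        values = counts / sample_size
    elif method == "count":
        idx = _sample_indices(rng, len(accs), sample_size, n_samples)
        values = member[idx].mean(axis=1)
    else:
        raise ValueError("method must be 'exact' or 'count'")
    return NullDistribution(values, "overlap_proportion", seed,
                            constraint=f"uniform samples of {sample_size}")


def quartile_strata(target_abundances: Sequence[float],
                    pool_abundances: Sequence[float]
                    ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Assign pool proteins to the target's abundance-quartile ranges.

    Quartile boundaries come from the target distribution.  Ranges are closed
    on the left and open on the right, the last closed; a pool value equal to
    an internal boundary goes to the lower stratum.  Pool proteins outside
    [min, max] of the target are unassigned.  Returns (bounds, stratum sizes
    required, list of candidate index arrays per stratum).
    """
    t = np.asarray(target_abundances, dtype=float)
    pool = np.asarray(pool_abundances, dtype=float)
    bounds = np.concatenate(([t.min()], np.quantile(t, [0.25, 0.5, 0.75]),
                             [t.max()]))
    stratum = np.searchsorted(bounds[1:4], pool, side="left")
    in_range = (pool >= bounds[0]) & (pool <= bounds[4])
    m = t.size
    base, rem = divmod(m, 4)
    sizes = np.array([base + (1 if k < rem else 0) for k in range(4)])
    candidates = [np.flatnonzero(in_range & (stratum == k)) for k in range(4)]
    return bounds, sizes, candidates


def abundance_matched_null(proteome: ProteinSet, target: Iterable[str],
                           other: Iterable[str], n_samples: int = 10_000,
                           seed: int = 0
                           ) -> tuple[NullDistribution, MatchingDiagnostics]:
    """Null overlap from abundance-matched stratified resampling.

    A quarter of each sample is drawn among proteome proteins whose abundance
    falls within the first quartile range of the target's abundance
    distribution, another quarter within the second, and so on; when the
    target size is not divisible by 4 the remainder is allocated one per
    stratum from the lowest quartile upward.  Sampling within strata is
    without replacement.  Diagnostics record, per sample, the mean decimal
    log abundance and a KS comparison against the target distribution.
    """
    target = list(dict.fromkeys(target))
    missing = [a for a in target if a not in proteome
               or proteome[a].abundance is None]
    if missing:
        raise ValueError(f"target proteins without abundance: {missing[:5]}...")
    other = set(other)

    pool_accs = [a for a in proteome.accessions()
                 if proteome[a].abundance is not None]
    pool_ab = np.array([proteome[a].abundance for a in pool_accs])
    t_ab = np.array([proteome[a].abundance for a in target])
    bounds, sizes, candidates = quartile_strata(t_ab, pool_ab)
    for k, (need, cand) in enumerate(zip(sizes, candidates)):
        if cand.size < need:
            raise ValueError(
                f"stratum {k + 1}: {cand.size} candidate(s) < required {need}")

    member = np.array([a in other for a in pool_accs], dtype=float)
    log_ab = np.log10(pool_ab)
    t_log = np.log10(t_ab)
    rng = np.random.default_rng(seed)

    values = np.empty(n_samples)
    means = np.empty(n_samples)
    ks_d = np.empty(n_samples)
    ks_p = np.empty(n_samples)
    for i in range(n_samples):
        picked = np.concatenate([
            cand[rng.choice(cand.size, need, replace=False)]
            for need, cand in zip(sizes, candidates)])
        values[i] = member[picked].mean()
        sample_log = log_ab[picked]
        means[i] = sample_log.mean()
        ks = ks_two_sample(sample_log, t_log)
        ks_d[i], ks_p[i] = ks.statistic, ks.p
    null = NullDistribution(values, "overlap_proportion", seed,
                            constraint="abundance-matched quartile strata")
    diag = MatchingDiagnostics(means, ks_d, ks_p, float(t_log.mean()),
                               bounds, tuple(int(s) for s in sizes))
    return null, diag


def cooccurrence_test(proteome: ProteinSet, target: Iterable[str],
                      other: Iterable[str], n_samples: int = 10_000,
                      seed: int = 0, matched: bool = False) -> OverlapResult:
    """Observed overlap of target with other, with its resampling p-value."""
    target = set(target)
    observed = overlap_proportion(target, other)
    if matched:
        null, _ = abundance_matched_null(proteome, target, other,
                                         n_samples, seed)
    else:
        null = null_overlap(proteome, other, len(target), n_samples, seed)
    p, is_bound = empirical_p(null, observed, tail="upper")
    return OverlapResult(observed, null, p, is_bound)
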