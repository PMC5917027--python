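"""Permutation subsampling to control for unequal group sizes.

Diversity comparisons between groups of very different size (e.g. 68
historical vs. 8 modern samples) are confounded by sample size. Each group
is therefore repeatedly subsampled *without replacement* down to the
smallest group's size and the statistic recomputed, giving a resampling
distribution per group that can be compared at equal n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .alignment_io import Alignment, InputError
from . import popgen_stats

#: named statistics usable with :func:`subsample_stat`
STATISTICS: dict[str, Callable[[Alignment], float]] = {
    "hd": lambda aln: popgen_stats.haplotype_diversity(
        popgen_stats.call_haplotypes(aln).counts
    ),
    "pi": lambda aln: popgen_stats.pairwise_diff_stats(aln)[1],
    "k_bar": lambda aln: popgen_stats.pairwise_diff_stats(aln)[0],
    "S": lambda aln: float(popgen_stats.segregating_sites(aln)),
}


@dataclass(frozen=True)
class ResampleDistribution:
    statistic: str
    target_n: int
    n_reps: int
    values: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.values, [0.025, 0.975])
        return float(lo), float(hi)


def subsample_stat(
    aln_group: Alignment,
    target_n: int,
    n_reps: int,
    statistic: str | Callable[[Alignment], float],
    seed: int,
) -> ResampleDistribution:
    """Recompute ``statistic`` on ``n_reps`` random subsets of size ``target_n``."""
    if target_n > aln_group.n:
        raise InputError(f"target_n {target_n} exceeds group size {aln_group.n}")
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    func = STATISTICS[statistic] if isinstance(statistic, str) else statistic
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    rng = np.random.default_rng(seed)
    values = np.empty(n_reps)
    ids = np.asarray(aln_group.ids)
    for r in range(n_reps):
        chosen = rng.choice(ids, size=target_n, replace=False)
        values[r] = func(aln_group.subset(list(chosen)))
    return ResampleDistribution(name, target_n, n_reps, values, seed)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: str
    mean_a: float
    mean_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    permutation_p: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_groups(
    dist_a: ResampleDistribution,
    dist_b: ResampleDistribution,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Welch two-sample t-test between resampled distributions.

    Because replicates of a resampling distribution are not independent
    observations, a label-shuffling permutation p-value for the mean
    difference is reported alongside and is the preferred inferential
    quantity.
    """
    a, b = dist_a.values, dist_b.values
    if len(a) == 0 or len(b) == 0:
        raise InputError("both distributions must be nonempty")
    if a.std() == 0 and b.std() == 0:
        t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=False)
    obs = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        if abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= obs:
            count += 1
    perm_p = (count + 1) / (n_permutations + 1)
    return ComparisonResult(
        dist_a.statistic, float(a.mean()), float(b.mean()),
        float(a.mean() - b.mean()), float(t_stat), float(p), float(perm_p),
        dist_a.ci95, dist_b.ci95,
    )
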