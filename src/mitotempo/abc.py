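"""Approximate Bayesian computation for temporal demographic inference.

The observed data are two heterochronous groups (modern vs. historical) of
mitogenome sequences. Eight summary statistics are computed per dataset:
haplotype count, private-haplotype count and haplotype (gene) diversity for
each group, plus mean between-group pairwise differences and Hudson F_ST
between the temporal groups.

Inference proceeds by simulating a reference table of parameter draws with
their statistics under three competing demographies (constant size, decline,
expansion in a single recent event), accepting the draws whose standardized
statistics fall closest to the observed vector (rejection), and optionally
sharpening the accepted sample with a Beaumont-style local-linear regression
adjustment on log parameters with Epanechnikov weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .alignment_io import Alignment, InputError
from . import popgen_stats
from .popgen_stats import UndefinedStatistic
from .serial_coalescent import (
    DemographicModel,
    MutationModel,
    SamplingDesign,
    simulate_site_matrix,
)

STAT_NAMES = (
    "H_modern", "H_historical", "P_modern", "P_historical",
    "GD_modern", "GD_historical", "k_between", "fst_between",
)

PARAM_NAMES = ("N_present", "N_historical", "t_change")

#: the study's acceptance proportions, 0.005% .. 0.05%, 10 log-spaced values
DEFAULT_PROPORTIONS = tuple(np.geomspace(5e-5, 5e-4, 10))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _group_summaries(mat_mod: np.ndarray, mat_hist: np.ndarray) -> np.ndarray:
    """The 8-statistic vector from base matrices at variable columns only.

    Matrices hold resolved bases (codes 0..3); rows are samples. Works for
    zero columns (monomorphic data). F_ST is defined as 0 when there is no
    variation at all, keeping the vector finite for degenerate simulations.
    """
    n_mod, n_hist = len(mat_mod), len(mat_hist)
    if n_mod < 2 or n_hist < 2:
        raise InputError("both temporal groups need n >= 2")
    hap_mod = _hap_counts(mat_mod)
    hap_hist = _hap_counts(mat_hist)
    keys_mod, keys_hist = set(hap_mod), set(hap_hist)
    shared = keys_mod & keys_hist
    p_mod = len(keys_mod - shared)
    p_hist = len(keys_hist - shared)
    gd_mod = _gene_diversity(list(hap_mod.values()))
    gd_hist = _gene_diversity(list(hap_hist.values()))
    kw_mod = _mean_within(mat_mod)
    kw_hist = _mean_within(mat_hist)
    k_between = _mean_between(mat_mod, mat_hist)
    if k_between == 0.0:
        fst = 0.0
    else:
        fst = 1.0 - 0.5 * (kw_mod + kw_hist) / k_between
    return np.array([
        len(keys_mod), len(keys_hist), p_mod, p_hist,
        gd_mod, gd_hist, k_between, fst,
    ])


def _hap_counts(mat: np.ndarray) -> dict[bytes, int]:
    counts: dict[bytes, int] = {}
    for row in mat:
        key = row.tobytes()
        counts[key] = counts.get(key, 0) + 1
    return counts


def _gene_diversity(counts: Sequence[int]) -> float:
    n = sum(counts)
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _mean_within(mat: np.ndarray) -> float:
    n = len(mat)
    if mat.shape[1] == 0:
        return 0.0
    total = 0.0
    for b in range(4):
        c = (mat == b).sum(axis=0)
        total += float((c * (c - 1) / 2.0).sum())
    n_pairs = n * (n - 1) / 2.0
    return (n_pairs * mat.shape[1] - total) / n_pairs


def _mean_between(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape[1] == 0:
        return 0.0
    same = 0.0
    for base in range(4):
        ca = (a == base).sum(axis=0)
        cb = (b == base).sum(axis=0)
        same += float((ca * cb).sum())
    cross = len(a) * len(b)
    return (cross * a.shape[1] - same) / cross


def summarize(modern: Alignment, historical: Alignment) -> np.ndarray:
    """SummaryStatVector for an observed pair of temporal groups.

    Delegates to :mod:`popgen_stats` (so missing data is handled with the
    same pairwise-deletion and compatible-haplotype rules as the reported
    diversity tables) and returns the statistics in :data:`STAT_NAMES` order.
    """
    if modern.n < 2 or historical.n < 2:
        raise InputError("both temporal groups need n >= 2")
    tab_mod = popgen_stats.call_haplotypes(modern)
    tab_hist = popgen_stats.call_haplotypes(historical)
    p_mod, p_hist, _ = popgen_stats.private_haplotypes(tab_mod, tab_hist)
    gd_mod = popgen_stats.haplotype_diversity(tab_mod.counts)
    gd_hist = popgen_stats.haplotype_diversity(tab_hist.counts)
    k_between = popgen_stats.mean_between_diffs(modern, historical)
    try:
        fst = popgen_stats.hudson_fst(modern, historical)
    except UndefinedStatistic:
        fst = 0.0
    return np.array([
        tab_mod.H, tab_hist.H, p_mod, p_hist, gd_mod, gd_hist, k_between, fst,
    ])


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors for the three-model comparison.

    Epoch sizes are log-uniform (uninformative over orders of magnitude of
    plausible female effective sizes); the change time is uniform on the
    recent window. Decline/expansion order constraints are enforced by
    redrawing.
    """

    n_low: float = 1e2
    n_high: float = 1e5
    t_low: float = 30.0
    t_high: float = 110.0
    model_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not (0 < self.n_low < self.n_high):
            raise InputError("need 0 < n_low < n_high")
        if not (0 < self.t_low < self.t_high):
            raise InputError("need 0 < t_low < t_high")

    def _draw_n(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.uniform(np.log(self.n_low), np.log(self.n_high))))


def draw_prior(model: str, spec: PriorSpec, rng: np.random.Generator) -> DemographicModel:
    """One demographic-parameter draw satisfying the model's constraint."""
    t = float(rng.uniform(spec.t_low, spec.t_high))
    if model == "constant":
        n = spec._draw_n(rng)
        return DemographicModel("constant", n, n, t)
    while True:
        n_p, n_h = spec._draw_n(rng), spec._draw_n(rng)
        if model == "decline" and n_h > n_p:
            return DemographicModel("decline", n_p, n_h, t)
        if model == "expansion" and n_h < n_p:
            return DemographicModel("expansion", n_p, n_h, t)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summary statistics) rows plus the
    column standardization constants used for distance computation."""

    df: pd.DataFrame
    stat_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    stat_sds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        stats = self.df[list(STAT_NAMES)].to_numpy(dtype=float)
        if self.stat_means is None:
            self.stat_means = stats.mean(axis=0)
        if self.stat_sds is None:
            sds = stats.std(axis=0, ddof=0)
            sds[sds == 0] = 1.0  # constant columns carry no distance signal
            self.stat_sds = sds

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["model"].unique()))

    def standardized_stats(self) -> np.ndarray:
        stats = self.df[list(STAT_NAMES)].to_numpy(dtype=float)
        return (stats - self.stat_means) / self.stat_sds

    def standardize(self, observed: np.ndarray) -> np.ndarray:
        return (np.asarray(observed, dtype=float) - self.stat_means) / self.stat_sds

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _simulate_row(
    model: str,
    spec: PriorSpec,
    design: SamplingDesign,
    mut: MutationModel,
    seed: np.random.SeedSequence,
) -> dict:
    rng = np.random.default_rng(seed)
    for attempt in range(5):  # retry on degenerate failures with a substream
        try:
            demo = draw_prior(model, spec, rng)
            mod, hist, _ = simulate_site_matrix(design, demo, mut, rng)
            stats = _group_summaries(mod, hist)
            break
        except (InputError, UndefinedStatistic):  # pragma: no cover - defensive
            rng = np.random.default_rng(seed.spawn(1)[0])
    row = {"model": model, "N_present": demo.N_present,
           "N_historical": demo.N_historical, "t_change": demo.t_change}
    row.update(dict(zip(STAT_NAMES, stats)))
    return row


def build_reference_table(
    n_sims: int,
    models: Sequence[str],
    spec: PriorSpec,
    design: SamplingDesign,
    mut: MutationModel,
    seed: int,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate ``n_sims`` rows, split equally across models.

    Each row consumes its own spawned seed stream, so the table is
    bit-identical regardless of ``workers``.
    """
    if n_sims < 100:
        raise InputError("n_sims must be >= 100")
    per_model = n_sims // len(models)
    # interleave models so distance ties (degenerate, e.g. monomorphic
    # observations) are broken fairly across models by the row-index rule
    jobs = [(m, i) for i in range(per_model) for m in models]
    seeds = np.random.SeedSequence(seed).spawn(len(jobs))
    if workers <= 1:
        rows = [_simulate_row(m, spec, design, mut, s) for (m, _), s in zip(jobs, seeds)]
    else:
        rows = Parallel(n_jobs=workers, batch_size=256)(
            delayed(_simulate_row)(m, spec, design, mut, s)
            for (m, _), s in zip(jobs, seeds)
        )
    return ReferenceTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# rejection, model choice, regression adjustment
# ---------------------------------------------------------------------------

def distances(table: ReferenceTable, observed: np.ndarray) -> np.ndarray:
    """Euclidean distance on SD-standardized statistics, per table row."""
    delta = table.standardized_stats() - table.standardize(observed)
    return np.sqrt((delta**2).sum(axis=1))


def reject(
    table: ReferenceTable, observed: np.ndarray, proportion: float
) -> pd.DataFrame:
    """Accept the ceil(proportion * rows) closest rows (ties by row index).

    The returned frame carries a ``distance`` column and the original row
    order among accepted rows.
    """
    if not 0 < proportion <= 1:
        raise InputError("proportion must lie in (0, 1]")
    k = math.ceil(proportion * table.n_rows)
    if k == 0:
        raise InputError("acceptance proportion yields zero rows")
    d = distances(table, observed)
    idx = np.argsort(d, kind="stable")[:k]
    idx = np.sort(idx)
    accepted = table.df.iloc[idx].copy()
    accepted["distance"] = d[idx]
    return accepted


@dataclass(frozen=True)
class ModelChoiceResult:
    """Posterior model probabilities per acceptance proportion."""

    proportions: tuple[float, ...]
    posteriors: pd.DataFrame  # index = proportion, columns = model names

    def consistency_range(self) -> pd.Series:
        """Spread of each model's posterior across acceptance proportions."""
        return self.posteriors.max(axis=0) - self.posteriors.min(axis=0)

    def posterior_at_median_proportion(self) -> pd.Series:
        mid = self.posteriors.index[len(self.posteriors) // 2]
        return self.posteriors.loc[mid]


def model_posterior(
    table: ReferenceTable,
    observed: np.ndarray,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
) -> ModelChoiceResult:
    """Rejection-ABC model choice: accepted-row fraction per model."""
    models = table.models
    # a single-model table gives a trivial posterior of 1 (useful in POD
    # sanity checks); real model choice needs >= 2 models
    d = distances(table, observed)
    order = np.argsort(d, kind="stable")
    model_col = table.df["model"].to_numpy()
    rows = []
    for prop in proportions:
        k = max(1, math.ceil(prop * table.n_rows))
        accepted = model_col[order[:k]]
        rows.append({m: float(np.mean(accepted == m)) for m in models})
    posteriors = pd.DataFrame(rows, index=list(proportions))
    return ModelChoiceResult(tuple(proportions), posteriors)


@dataclass(frozen=True)
class PosteriorSample:
    """Accepted (and optionally regression-adjusted) parameter draws."""

    draws: pd.DataFrame  # columns PARAM_NAMES (+ model)
    adjusted: bool

    def ratios(self) -> np.ndarray:
        return (self.draws["N_historical"] / self.draws["N_present"]).to_numpy()


def regression_adjust(accepted: pd.DataFrame, table: ReferenceTable,
                      observed: np.ndarray) -> PosteriorSample:
    """Beaumont-style local-linear adjustment on log parameters.

    Regress log-parameters of the accepted draws on their standardized
    statistics with Epanechnikov weights in distance, then translate each
    draw to the fitted value at the observed statistics plus its residual.
    Falls back to the unadjusted sample when the design is singular.
    """
    if len(accepted) < 30:
        raise InputError("regression adjustment needs >= 30 accepted rows")
    x = (accepted[list(STAT_NAMES)].to_numpy(dtype=float) - table.stat_means) / table.stat_sds
    x0 = table.standardize(observed)
    d = accepted["distance"].to_numpy() if "distance" in accepted else np.sqrt(
        ((x - x0) ** 2).sum(axis=1)
    )
    dmax = d.max()
    w = np.ones_like(d) if dmax == 0 else np.clip(1.0 - (d / dmax) ** 2, 0.0, 1.0)
    w = np.maximum(w, 1e-12)
    y = np.log(accepted[list(PARAM_NAMES)].to_numpy(dtype=float))
    # statistics that are constant across the accepted rows carry no local
    # information and would be collinear with the intercept; drop them
    informative = x.std(axis=0) > 1e-10
    design = np.column_stack([np.ones(len(x)), (x - x0)[:, informative]])
    sw = np.sqrt(w)
    try:
        beta, _, _, _ = np.linalg.lstsq(design * sw[:, None], y * sw[:, None], rcond=None)
    except np.linalg.LinAlgError:
        warnings.warn("singular regression design; returning unadjusted rejection sample")
        return PosteriorSample(accepted[["model", *PARAM_NAMES]].reset_index(drop=True), False)
    fitted = design @ beta
    adjusted_log = beta[0] + (y - fitted)  # fit at observed + residuals
    out = pd.DataFrame(np.exp(adjusted_log), columns=list(PARAM_NAMES))
    out.insert(0, "model", accepted["model"].to_numpy())
    return PosteriorSample(out, True)


def estimate_reduction(posterior: PosteriorSample) -> tuple[float, tuple[float, float]]:
    """Median and equal-tailed 95% CI of N_historical / N_present."""
    ratios = posterior.ratios()
    if len(ratios) == 0:
        raise InputError("empty posterior sample")
    lo, med, hi = np.quantile(ratios, [0.025, 0.5, 0.975])
    return float(med), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# one-call estimation pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbcConfig:
    """Everything needed to run model choice + estimation on one design."""

    design: SamplingDesign
    mut: MutationModel
    prior: PriorSpec = PriorSpec()
    models: tuple[str, ...] = ("constant", "decline", "expansion")
    n_sims: int = 30_000
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    estimation_proportion: float = 0.01
    workers: int = 1


def estimate(
    table: ReferenceTable, observed: np.ndarray, proportion: float = 0.01
) -> PosteriorSample:
    """Rejection + regression adjustment in one step."""
    accepted = reject(table, observed, proportion)
    return regression_adjust(accepted, table, observed)
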