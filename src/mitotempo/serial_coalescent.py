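"""Serial (heterochronous) coalescent simulation of a single non-recombining
maternally inherited locus.

The genealogy process is the standard haploid coalescent run backwards in
time, with two extensions needed for museum/modern sampling designs:

* lineages enter the process at their own sampling age (converted from
  calendar years to generations), and
* the female effective size N(t) is piecewise constant with a single change
  at ``t_change`` years before present, covering constant, decline and
  expansion histories.

While k lineages are active the pairwise coalescence rate is
k(k-1)/2 * 1/N(t) per generation; waiting times are exponential and re-drawn
at every epoch boundary and sample-activation time (valid by memorylessness).

Mutations follow a finite-sites K80-like model: per-branch counts are
Poisson(branch length in generations * per-generation rate * sites), each
mutation hits a uniformly chosen site, is a transition with probability
R/(R+1) (R = Ts/Tv bias) and otherwise one of the two transversions chosen
uniformly. Repeat hits at a site are allowed and applied in time order along
each root-to-tip path. The root sequence is uniform random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment_io import Alignment, InputError, SampleTable, alignment_from_codes
import pandas as pd

#: transition partner for each base code (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
#: the two transversion targets for each base code
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)

MODEL_CLASSES = ("constant", "decline", "expansion")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant female effective size with one recent change.

    Sizes are numbers of breeding females (mtDNA is maternally inherited, so
    the haploid coalescent uses N = female effective size). ``t_change`` is
    in years before the reference (sampling) year.
    """

    model_class: str
    N_present: float
    N_historical: float
    t_change: float

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise InputError(f"unknown model class: {self.model_class}")
        if self.N_present <= 0 or self.N_historical <= 0 or self.t_change <= 0:
            raise InputError("population sizes and t_change must be positive")
        if self.model_class == "constant" and self.N_present != self.N_historical:
            raise InputError("constant model requires equal epoch sizes")
        if self.model_class == "decline" and not self.N_historical > self.N_present:
            raise InputError("decline requires N_historical > N_present")
        if self.model_class == "expansion" and not self.N_historical < self.N_present:
            raise InputError("expansion requires N_historical < N_present")

    @property
    def reduction_factor(self) -> float:
        """N_historical / N_present (>1 for decline)."""
        return self.N_historical / self.N_present

    def size_at(self, t_generations: float, generation_time: float) -> float:
        return self.N_present if t_generations < self.t_change / generation_time else self.N_historical


def constant_model(n: float, t_change: float = 70.0) -> DemographicModel:
    return DemographicModel("constant", n, n, t_change)


@dataclass(frozen=True)
class MutationModel:
    """Finite-sites K80-like mutation process.

    ``rate`` is in substitutions/site/year (the scale on which mitogenome
    rates are usually calibrated) and is converted internally with
    ``generation_time``; ``ts_tv_bias`` R is the expected transition :
    transversion count ratio.
    """

    rate: float = 1.28e-8
    ts_tv_bias: float = 0.933
    length: int = 15_000
    generation_time: float = 20.0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.ts_tv_bias <= 0 or self.length <= 0 or self.generation_time <= 0:
            raise InputError("invalid mutation model parameters")

    @property
    def rate_per_generation(self) -> float:
        return self.rate * self.generation_time


@dataclass(frozen=True)
class SamplingDesign:
    """Heterochronous sampling: (age in years before reference, count) pairs."""

    ages_counts: tuple[tuple[float, int], ...]
    reference_year: int = 2014

    def __post_init__(self) -> None:
        for age, count in self.ages_counts:
            if age < 0 or count < 1:
                raise InputError("ages must be >= 0 and counts >= 1")

    @property
    def n(self) -> int:
        return sum(c for _, c in self.ages_counts)

    def tip_ages_years(self) -> np.ndarray:
        return np.repeat(
            [a for a, _ in self.ages_counts], [c for _, c in self.ages_counts]
        ).astype(float)


@dataclass
class Genealogy:
    """A coalescent tree over 2n-1 nodes; tips are nodes 0..n-1.

    Times are in generations before present and increase towards the root;
    ``parent[root] == -1``.
    """

    n_tips: int
    times: np.ndarray  # (2n-1,)
    parent: np.ndarray  # (2n-1,) int
    tip_ages: np.ndarray  # (n,) generations

    def __post_init__(self) -> None:
        root = np.flatnonzero(self.parent == -1)
        if len(root) != 1:
            raise InputError("genealogy must have exactly one root")
        self.root = int(root[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        lengths = np.zeros(len(self.times))
        non_root = np.flatnonzero(self.parent >= 0)
        lengths[non_root] = self.times[self.parent[non_root]] - self.times[non_root]
        return lengths

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {}
        for node, par in enumerate(self.parent):
            if par >= 0:
                kids.setdefault(int(par), []).append(node)
        return kids

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def simulate_genealogy(
    design: SamplingDesign,
    demo: DemographicModel,
    generation_time: float,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under the serial two-epoch coalescent."""
    tip_ages = np.sort(design.tip_ages_years() / generation_time)
    n = len(tip_ages)
    if n < 2:
        raise InputError("need at least 2 tips")
    n_nodes = 2 * n - 1
    times = np.zeros(n_nodes)
    times[:n] = tip_ages
    parent = np.full(n_nodes, -1, dtype=np.int64)
    t_switch = demo.t_change / generation_time

    active: list[int] = []
    pending = list(range(n))  # sorted by age ascending
    t = 0.0
    next_node = n
    while len(active) + len(pending) > 1 or len(active) > 1:
        # activate any tips sampled at the current time
        while pending and tip_ages[pending[0]] <= t:
            active.append(pending.pop(0))
        k = len(active)
        if k < 2:
            t = tip_ages[pending[0]]
            continue
        n_now = demo.N_present if t < t_switch else demo.N_historical
        wait = rng.exponential(n_now / (k * (k - 1) / 2.0))
        boundaries = []
        if pending:
            boundaries.append(tip_ages[pending[0]])
        if t < t_switch:
            boundaries.append(t_switch)
        next_boundary = min(boundaries) if boundaries else np.inf
        if t + wait >= next_boundary:
            t = next_boundary  # re-draw (memoryless) in the new regime
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        times[next_node] = t
        parent[a] = parent[b] = next_node
        active = [x for x in active if x not in (a, b)]
        active.append(next_node)
        next_node += 1
    return Genealogy(n, times, parent, tip_ages)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

@dataclass
class MutationPlacement:
    """Mutation events placed on a genealogy, before base resolution.

    Per event: the node below the mutated branch, the hit site, the event
    time (generations), whether it is a transition, and (if transversion)
    which of the two targets. Base changes are resolved during the root-to-
    tip sweep because targets depend on the current base (finite sites).
    """

    sites: np.ndarray  # (m,) site index of each event
    nodes: np.ndarray  # (m,) node below the branch
    times: np.ndarray  # (m,) event time in generations
    is_transition: np.ndarray  # (m,) bool
    tv_choice: np.ndarray  # (m,) 0/1

    @property
    def n_events(self) -> int:
        return len(self.sites)


def place_mutations(
    gen: Genealogy, mut: MutationModel, rng: np.random.Generator
) -> MutationPlacement:
    lengths = gen.branch_lengths()
    lam = lengths * mut.rate_per_generation * mut.length
    counts = rng.poisson(lam)
    nodes = np.repeat(np.arange(len(lengths)), counts)
    m = len(nodes)
    sites = rng.integers(0, mut.length, size=m)
    # uniform position along each branch, as absolute time
    u = rng.random(m)
    times = gen.times[nodes] + u * lengths[nodes]
    p_ts = mut.ts_tv_bias / (mut.ts_tv_bias + 1.0)
    is_transition = rng.random(m) < p_ts
    tv_choice = rng.integers(0, 2, size=m)
    return MutationPlacement(sites, nodes, times, is_transition, tv_choice)


def resolve_mutations(
    gen: Genealogy, placement: MutationPlacement, root_seq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep root-to-tip applying mutations in descending time order.

    Returns (positions, tip_matrix): the sorted unique mutated sites and an
    (n_tips, n_positions) int8 matrix of tip bases at those sites. Sites
    never hit are identical across tips (equal to the root base), so all
    variation lives in this matrix.
    """
    positions = np.unique(placement.sites)
    if len(positions) == 0:
        return positions, np.zeros((gen.n_tips, 0), dtype=np.int8)
    col = {int(s): i for i, s in enumerate(positions)}
    per_node: dict[int, list[tuple[float, int, bool, int]]] = {}
    for s, nd, t, ts, tv in zip(
        placement.sites, placement.nodes, placement.times,
        placement.is_transition, placement.tv_choice,
    ):
        per_node.setdefault(int(nd), []).append((float(t), col[int(s)], bool(ts), int(tv)))
    kids = gen.children()
    tips = np.zeros((gen.n_tips, len(positions)), dtype=np.int8)
    root_state = root_seq[positions].astype(np.int8)

    stack: list[tuple[int, np.ndarray]] = [(gen.root, root_state)]
    while stack:
        node, state = stack.pop()
        events = per_node.get(node)
        if events:
            state = state.copy()
            for _, c, ts, tv in sorted(events, reverse=True):  # oldest first
                b = state[c]
                state[c] = _TRANSITION[b] if ts else _TRANSVERSIONS[b, tv]
        if node < gen.n_tips:
            tips[node] = state
        else:
            for child in kids[node]:
                stack.append((child, state))
    return positions, tips


def drop_mutations(
    gen: Genealogy, mut: MutationModel, rng: np.random.Generator,
    ids: Sequence[str] | None = None,
) -> Alignment:
    """Simulate sequences down the genealogy and emit a full alignment."""
    root_seq = rng.integers(0, 4, size=mut.length, dtype=np.int8)
    placement = place_mutations(gen, mut, rng)
    positions, tips = resolve_mutations(gen, placement, root_seq)
    codes = np.tile(root_seq, (gen.n_tips, 1))
    codes[:, positions] = tips
    if ids is None:
        ids = [f"s{i:03d}" for i in range(gen.n_tips)]
    return alignment_from_codes(ids, codes)


def simulate_dataset(
    design: SamplingDesign,
    demo: DemographicModel,
    mut: MutationModel,
    rng: np.random.Generator,
) -> tuple[Alignment, SampleTable]:
    """One simulation replicate: alignment plus era-labelled metadata.

    Tips are ordered by sampling age ascending (modern first), matching the
    genealogy's tip order. Era is modern at age 0, historical otherwise.
    """
    gen = simulate_genealogy(design, demo, mut.generation_time, rng)
    ages_years = np.sort(design.tip_ages_years())
    ids = []
    rows = []
    for i, age in enumerate(ages_years):
        era = "modern" if age == 0 else "historical"
        sid = f"{'mod' if era == 'modern' else 'hist'}_{i:03d}"
        ids.append(sid)
        rows.append({
            "id": sid, "taxon": "synthetic", "era": era,
            "collection_year": int(round(design.reference_year - age)),
        })
    aln = drop_mutations(gen, mut, rng, ids=ids)
    table = SampleTable(pd.DataFrame(rows), reference_year=design.reference_year)
    return aln, table


def simulate_site_matrix(
    design: SamplingDesign,
    demo: DemographicModel,
    mut: MutationModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fast replicate for reference-table building: only mutated columns.

    Returns (modern_matrix, historical_matrix, tmrca) where the matrices
    hold tip bases at the mutated sites only (tips at unmutated sites are
    identical, so every summary statistic except sequence length is a
    function of these columns). Consumes the RNG identically to
    :func:`simulate_dataset`, so both paths give the same data per seed.
    """
    gen = simulate_genealogy(design, demo, mut.generation_time, rng)
    root_seq = rng.integers(0, 4, size=mut.length, dtype=np.int8)
    placement = place_mutations(gen, mut, rng)
    _, tips = resolve_mutations(gen, placement, root_seq)
    modern = gen.tip_ages == 0
    return tips[modern], tips[~modern], gen.tmrca
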