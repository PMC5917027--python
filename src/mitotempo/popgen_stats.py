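"""Haplotype calling, diversity indices, neutrality tests, differentiation,
variant classification and minimum spanning haplotype networks.

All statistics use pairwise deletion of missing data: a site contributes to
a pair only when both sequences carry a resolved base (A/C/G/T) there. Per-
pair difference totals are therefore computed per site from resolved-base
counts, which is algebraically identical to looping over pairs but runs in
O(n * L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .alignment_io import (
    Alignment,
    InputError,
    MISSING_CODE_MIN,
    CODE_BASES,
)

_PAM250 = substitution_matrices.load("PAM250")
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class UndefinedStatistic(ValueError):
    """The requested statistic is undefined for this input (e.g. S = 0)."""


# ---------------------------------------------------------------------------
# site-count helpers
# ---------------------------------------------------------------------------

def _base_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L) counts of resolved bases per column of an (n, L) code matrix."""
    resolved = codes < MISSING_CODE_MIN
    counts = np.zeros((4, codes.shape[1]), dtype=np.int64)
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    return counts


def _pair_sums(codes: np.ndarray) -> tuple[float, float]:
    """(total pair differences, total pair comparable sites) over all
    unordered pairs, with pairwise deletion, summed per site:
    diffs_s = C(r_s, 2) - sum_b C(c_bs, 2); comparable_s = C(r_s, 2)."""
    counts = _base_counts(codes)
    r = counts.sum(axis=0)
    comparable = r * (r - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    return float((comparable - same).sum()), float(comparable.sum())


def segregating_sites(aln: Alignment) -> int:
    """Number of columns with at least two distinct resolved bases."""
    counts = _base_counts(aln.to_codes())
    return int(((counts > 0).sum(axis=0) >= 2).sum())


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    label: str
    representative: str
    member_ids: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]
    source: Alignment

    @property
    def n(self) -> int:
        return sum(h.count for h in self.haplotypes)

    @property
    def H(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(h.count for h in self.haplotypes)


def _resolved_diff(a: np.ndarray, b: np.ndarray) -> int:
    both = (a < MISSING_CODE_MIN) & (b < MISSING_CODE_MIN)
    return int(((a != b) & both).sum())


def call_haplotypes(aln: Alignment, mode: str = "compatible") -> HaplotypeTable:
    """Group sequences into haplotypes.

    mode="compatible" (default): two sequences share a haplotype iff they
    show zero differences over sites resolved in both, merged greedily with
    the most-complete sequence of each cluster as seed. This keeps museum
    sequences with N-runs from inflating the haplotype count.

    mode="strict": columns containing any missing base are excluded, then
    haplotypes are exact string matches over the remaining columns.
    """
    codes = aln.to_codes()
    if mode == "strict":
        keep = (codes < MISSING_CODE_MIN).all(axis=0)
        key_of = {sid: codes[i, keep].tobytes() for i, sid in enumerate(aln.ids)}
        clusters: dict[bytes, list[str]] = {}
        for sid in aln.ids:
            clusters.setdefault(key_of[sid], []).append(sid)
        members_list = list(clusters.values())
    elif mode == "compatible":
        miss = (codes >= MISSING_CODE_MIN).sum(axis=1)
        order = sorted(range(aln.n), key=lambda i: (miss[i], aln.ids[i]))
        cluster_rows: list[list[int]] = []
        for i in order:
            for rows in cluster_rows:
                if all(_resolved_diff(codes[i], codes[j]) == 0 for j in rows):
                    rows.append(i)
                    break
            else:
                cluster_rows.append([i])
        members_list = [[aln.ids[i] for i in rows] for rows in cluster_rows]
    else:
        raise InputError(f"unknown haplotype-calling mode: {mode}")

    seq_of = dict(zip(aln.ids, aln.seqs))
    haps = []
    for members in members_list:
        label = min(members)
        haps.append(Haplotype(label, seq_of[members[0]], tuple(sorted(members))))
    haps.sort(key=lambda h: h.label)
    return HaplotypeTable(tuple(haps), aln)


def haplotype_diversity(counts: Sequence[int], n: int | None = None) -> float:
    """Gene diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    total = float(counts.sum()) if n is None else float(n)
    if total < 2:
        raise UndefinedStatistic("haplotype diversity requires n >= 2")
    p = counts / total
    return float(total / (total - 1.0) * (1.0 - np.sum(p**2)))


def private_haplotypes(
    table_a: HaplotypeTable, table_b: HaplotypeTable, mode: str = "compatible"
) -> tuple[int, int, int]:
    """(private to A, private to B, shared) haplotype counts.

    Computed by re-calling haplotypes on the pooled sequences so that the
    merge rule used within groups also decides sharing between groups;
    privA + privB + shared equals the pooled haplotype count.
    """
    a, b = table_a.source, table_b.source
    if a.length != b.length:
        raise InputError("groups must share a common column space")
    pooled = Alignment(
        tuple(f"A::{s}" for s in a.ids) + tuple(f"B::{s}" for s in b.ids),
        a.seqs + b.seqs,
    )
    union = call_haplotypes(pooled, mode=mode)
    priv_a = priv_b = shared = 0
    for hap in union.haplotypes:
        groups = {m.split("::", 1)[0] for m in hap.member_ids}
        if groups == {"A"}:
            priv_a += 1
        elif groups == {"B"}:
            priv_b += 1
        else:
            shared += 1
    return priv_a, priv_b, shared


# ---------------------------------------------------------------------------
# diversity and neutrality
# ---------------------------------------------------------------------------

def pairwise_diff_stats(aln: Alignment) -> tuple[float, float]:
    """Mean pairwise differences k_bar and per-site nucleotide diversity pi.

    pi divides k_bar by the mean number of pairwise-comparable sites, so
    missing data shrinks the denominator rather than deflating pi.
    """
    if aln.n < 2:
        raise UndefinedStatistic("pairwise statistics require n >= 2")
    diffs, comparable = _pair_sums(aln.to_codes())
    n_pairs = aln.n * (aln.n - 1) / 2.0
    k_bar = diffs / n_pairs
    pi = diffs / comparable if comparable > 0 else 0.0
    return k_bar, pi


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D from total S and mean pairwise differences."""
    if aln.n < 4:
        raise UndefinedStatistic("Tajima's D requires n >= 4")
    s = segregating_sites(aln)
    if s == 0:
        raise UndefinedStatistic("Tajima's D undefined for monomorphic data")
    k_bar, _ = pairwise_diff_stats(aln)
    n = aln.n
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    return float((k_bar - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1)))


def hudson_fst(group_a: Alignment, group_b: Alignment) -> float:
    """F_ST = 1 - Hw/Hb from mean pairwise differences.

    Hw averages the two within-group means; Hb is the mean over all
    between-group pairs. The raw (possibly negative) value is returned.
    """
    if group_a.n < 2 or group_b.n < 2:
        raise UndefinedStatistic("F_ST requires n >= 2 in both groups")
    if group_a.length != group_b.length:
        raise InputError("groups must share a common column space")
    kw_a, _ = pairwise_diff_stats(group_a)
    kw_b, _ = pairwise_diff_stats(group_b)
    hb = mean_between_diffs(group_a, group_b)
    hw = 0.5 * (kw_a + kw_b)
    if hb == 0:
        raise UndefinedStatistic("F_ST undefined: no between-group differences")
    return float(1.0 - hw / hb)


def mean_between_diffs(group_a: Alignment, group_b: Alignment) -> float:
    """Mean resolved-site differences over between-group pairs.

    Pairs with identical sample ids (the same individual present in both
    groups) are self-comparisons and are excluded, so two copies of one
    group are exactly undifferentiated.
    """
    codes_a, codes_b = group_a.to_codes(), group_b.to_codes()
    ca = _base_counts(codes_a)
    cb = _base_counts(codes_b)
    ra, rb = ca.sum(axis=0), cb.sum(axis=0)
    total = float((ra * rb - (ca * cb).sum(axis=0)).sum())
    n_pairs = group_a.n * group_b.n
    shared = set(group_a.ids) & set(group_b.ids)
    if shared:
        ia = {sid: i for i, sid in enumerate(group_a.ids)}
        ib = {sid: i for i, sid in enumerate(group_b.ids)}
        for sid in shared:
            total -= _resolved_diff(codes_a[ia[sid]], codes_b[ib[sid]])
        n_pairs -= len(shared)
    if n_pairs == 0:
        return 0.0
    return total / n_pairs


@dataclass(frozen=True)
class DiversityStats:
    """Per-group summary: sample size, haplotype and nucleotide diversity,
    segregating sites and Tajima's D (NaN when undefined)."""

    n: int
    H: int
    Hd: float
    k_bar: float
    pi: float
    S: int
    tajima_d: float

    def as_dict(self) -> dict:
        return {
            "n": self.n, "H": self.H, "Hd": self.Hd, "k_bar": self.k_bar,
            "pi": self.pi, "S": self.S, "tajima_d": self.tajima_d,
        }


def diversity_stats(aln: Alignment, hap_mode: str = "compatible") -> DiversityStats:
    table = call_haplotypes(aln, mode=hap_mode)
    hd = haplotype_diversity(table.counts) if aln.n >= 2 else math.nan
    k_bar, pi = pairwise_diff_stats(aln) if aln.n >= 2 else (math.nan, math.nan)
    s = segregating_sites(aln)
    try:
        d = tajimas_d(aln)
    except UndefinedStatistic:
        d = math.nan
    return DiversityStats(aln.n, table.H, hd, k_bar, pi, s, d)


def diversity_table(groups: dict[str, Alignment], hap_mode: str = "compatible") -> pd.DataFrame:
    """DiversityStats for each group as a DataFrame (one row per group)."""
    rows = []
    for label, aln in groups.items():
        rows.append({"group": label, **diversity_stats(aln, hap_mode).as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantClass:
    position: int
    alleles: tuple[str, ...]  # major allele first
    substitution_class: str  # transition | transversion | multiallelic
    context: str  # coding | rRNA | tRNA | non-coding
    gene: str | None = None
    coding_effect: str | None = None  # synonymous | nonsynonymous | stop_gained
    pam250: int | None = None
    commonly_observed: bool | None = None  # PAM250 score >= 0
    stop_gained: bool = False


def _substitution_class(a: str, b: str) -> str:
    pair = {a, b}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def _translate(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def _codon_at(
    consensus: np.ndarray, pos: int, allele: str, gene: pd.Series
) -> str | None:
    """Codon containing alignment column ``pos``, with ``allele`` substituted
    at that column, read in the gene's frame and strand. None when the codon
    is truncated at a gene boundary."""
    start, end = int(gene["start"]), int(gene["end"])
    frame = int(gene.get("frame", 0) or 0)
    if gene["strand"] == "+":
        offset = pos - start - frame
        if offset < 0:
            return None
        first = start + frame + 3 * (offset // 3)
        positions = [first, first + 1, first + 2]
    else:
        offset = (end - 1 - frame) - pos
        if offset < 0:
            return None
        first = (end - 1 - frame) - 3 * (offset // 3)
        positions = [first, first - 1, first - 2]  # genomic order of codon pos 1,2,3
    if min(positions) < start or max(positions) >= end:
        return None
    bases = []
    for p in positions:
        b = allele if p == pos else CODE_BASES[consensus[p]]
        if b not in "ACGT":
            return None
        bases.append(b if gene["strand"] == "+" else _COMPLEMENT[b])
    return "".join(bases)


def classify_variants(aln: Alignment, annotation: pd.DataFrame) -> list[VariantClass]:
    """Classify every segregating site of the alignment.

    ``annotation`` needs columns gene, start, end, strand, frame, type with
    type in {coding, rRNA, tRNA}; unannotated columns are non-coding.
    Coding variants are translated with the vertebrate mitochondrial code and
    nonsynonymous changes scored with PAM250 (score >= 0 flags amino-acid
    replacements commonly observed in nature).
    """
    codes = aln.to_codes()
    counts = _base_counts(codes)
    # majority-resolved consensus per column (code 4 = N where unresolved)
    consensus = np.where(counts.sum(axis=0) > 0, counts.argmax(axis=0), 4).astype(np.int8)
    results: list[VariantClass] = []
    for pos in np.flatnonzero((counts > 0).sum(axis=0) >= 2):
        pos = int(pos)
        site = counts[:, pos]
        order = np.argsort(-site, kind="stable")
        alleles = tuple(CODE_BASES[b] for b in order if site[b] > 0)
        if len(alleles) > 2:
            results.append(VariantClass(pos, alleles, "multiallelic", _context(annotation, pos)[0]))
            continue
        major, minor = alleles
        sub = _substitution_class(major, minor)
        context, gene = _context(annotation, pos)
        effect = pam = common = None
        stop = False
        if context == "coding" and gene is not None:
            ref_codon = _codon_at(consensus, pos, major, gene)
            alt_codon = _codon_at(consensus, pos, minor, gene)
            if ref_codon and alt_codon:
                aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
                if aa_ref == aa_alt:
                    effect = "synonymous"
                elif aa_alt == "*":
                    effect, stop = "stop_gained", True
                else:
                    effect = "nonsynonymous"
                    pam = int(_PAM250[aa_ref, aa_alt])
                    common = pam >= 0
        results.append(
            VariantClass(pos, alleles, sub, context,
                         gene=None if gene is None else str(gene["gene"]),
                         coding_effect=effect, pam250=pam,
                         commonly_observed=common, stop_gained=stop)
        )
    return results


def _context(annotation: pd.DataFrame, pos: int) -> tuple[str, pd.Series | None]:
    hits = annotation[(annotation["start"] <= pos) & (pos < annotation["end"])]
    if hits.empty:
        return "non-coding", None
    row = hits.iloc[0]
    return str(row["type"]), row


def variants_table(variants: Iterable[VariantClass]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in variants])


def ts_tv_tally(variants: Iterable[VariantClass]) -> tuple[int, int, int]:
    """(transitions, transversions, multiallelic) counts."""
    ts = tv = multi = 0
    for v in variants:
        if v.substitution_class == "transition":
            ts += 1
        elif v.substitution_class == "transversion":
            tv += 1
        else:
            multi += 1
    return ts, tv, multi


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeNetwork:
    """Minimum spanning network (epsilon = 0): the union of all minimum
    spanning trees over haplotype distances, so tied alternative connections
    are retained."""

    graph: nx.Graph

    @property
    def total_mst_weight(self) -> float:
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return float(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), int(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def min_spanning_network(table: HaplotypeTable) -> HaplotypeNetwork:
    """Build the epsilon-0 MSN over pairwise resolved-site distances.

    Kruskal over sorted edges; within each weight class an edge is kept iff
    its endpoints lie in different components at the start of the class, so
    every edge belonging to some minimum spanning tree is included.
    Deterministic: edges processed in (weight, label-pair) order.
    """
    haps = table.haplotypes
    g = nx.Graph()
    for h in haps:
        g.add_node(h.label, count=h.count, representative=h.representative)
    if len(haps) < 2:
        return HaplotypeNetwork(g)
    reps = {h.label: h for h in haps}
    codes = {h.label: Alignment((h.label,), (h.representative,)).to_codes()[0] for h in haps}
    edges = []
    labels = sorted(reps)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            edges.append((_resolved_diff(codes[a], codes[b]), a, b))
    edges.sort()
    uf = nx.utils.UnionFind(labels)
    i = 0
    while i < len(edges):
        w = edges[i][0]
        group = []
        while i < len(edges) and edges[i][0] == w:
            group.append(edges[i])
            i += 1
        added = [(a, b) for _, a, b in group if uf[a] != uf[b]]
        for a, b in added:
            g.add_edge(a, b, weight=max(int(w), 1) if w == 0 else int(w))
            # zero distances cannot occur between distinct haplotypes under
            # the compatible rule, but guard the >= 1 edge-weight invariant
        for a, b in added:
            uf.union(a, b)
    return HaplotypeNetwork(g)
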