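"""Group-wise divergence scans, Venn partitioning, trees and clustering.

Per-SNP divergence between two groups is tested with a two-sided
Fisher's exact test on the 2x2 table of allele counts (ref/alt x
group), significance at p < alpha with no multiple-testing correction.
Three pairwise comparisons partition into the seven Venn regions; the
"focal unique" set (sites diverged from both the allopatric and the
sympatric contrast) feeds the ghost scan.

Individual-level structure uses Nei's (1972) standard genetic distance
on per-individual allele-frequency vectors, a classical neighbour-
joining tree with site-bootstrap supports, and average-linkage
hierarchical clustering of the pairwise multilocus F_ST matrix on
Euclidean row distances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .genotypes import MISSING, GenotypeMatrix
from .sumstats import pairwise_fst

__all__ = [
    "ScanResult",
    "VennPartition",
    "fisher_scan",
    "venn_partition",
    "nei_distance_matrix",
    "nei_nj_tree",
    "fst_matrix_and_clustering",
]


@dataclass
class ScanResult:
    """Per-site Fisher divergence scan between two groups."""

    group1: str
    group2: str
    alpha: float
    table: pd.DataFrame  # chrom, pos, ref1, alt1, ref2, alt2, p, fst
    multilocus_fst: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.alpha]

    def significant_ids(self) -> set[tuple[str, int]]:
        sig = self.significant
        return set(zip(sig["chrom"], sig["pos"]))


def fisher_scan(gm: GenotypeMatrix, group1: str, group2: str,
                alpha: float = 0.001, grouping: str = "group") -> ScanResult:
    """Two-sided Fisher's exact divergence test at every site.

    Allele-count (2N) tables from non-missing calls; the two-sided p
    sums all tables with point probability <= the observed one.  Sites
    monomorphic across both groups get p = 1.
    """
    g1 = gm.genotypes[gm.group_rows(group1, grouping)]
    g2 = gm.genotypes[gm.group_rows(group2, grouping)]
    shared = ((g1 != MISSING).any(axis=0)) & ((g2 != MISSING).any(axis=0))
    if not shared.any():
        raise ValueError(
            f"groups {group1!r} and {group2!r} share no genotyped site")

    def counts(g):
        miss = g == MISSING
        n = (~miss).sum(axis=0)
        alt = np.where(miss, 0, g).sum(axis=0)
        return 2 * n - alt, alt  # ref copies, alt copies

    r1, a1 = counts(g1)
    r2, a2 = counts(g2)
    pvals = np.ones(gm.n_sites)
    for j in np.flatnonzero(shared):
        t = [[int(r1[j]), int(a1[j])], [int(r2[j]), int(a2[j])]]
        if (a1[j] + a2[j] == 0) or (r1[j] + r2[j] == 0):
            pvals[j] = 1.0  # monomorphic across both groups
        else:
            pvals[j] = sps.fisher_exact(t, alternative="two-sided")[1]
    try:
        per_site_fst = pairwise_fst(gm, group1, group2, mode="per-site",
                                    grouping=grouping)
        ml = pairwise_fst(gm, group1, group2, mode="multilocus",
                          grouping=grouping)
    except ValueError:  # every site monomorphic across both groups
        per_site_fst = np.full(gm.n_sites, np.nan)
        ml = float("nan")
    table = pd.DataFrame({
        "chrom": gm.sites["chrom"], "pos": gm.sites["pos"],
        "ref1": r1, "alt1": a1, "ref2": r2, "alt2": a2,
        "p": pvals, "fst": per_site_fst,
    })
    return ScanResult(group1=group1, group2=group2, alpha=alpha, table=table,
                      multilocus_fst=ml)


@dataclass
class VennPartition:
    """The seven inclusion-exclusion regions of three site-ID sets.

    Region keys: '100', '010', '001', '110', '101', '011', '111' in the
    order (AB, RA, RB) of the input comparisons; ``focal_unique`` is the
    set of sites diverged in both comparisons involving the focal
    lineage (RB and AB), the signature of lineage-wide divergence.
    """

    regions: dict[str, set]
    focal_unique: set

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def union(self) -> set:
        out = set()
        for v in self.regions.values():
            out |= v
        return out


def venn_partition(setAB: set, setRA: set, setRB: set) -> VennPartition:
    """Disjoint Venn regions of the three pairwise divergence sets."""
    regions = {
        "100": setAB - setRA - setRB,
        "010": setRA - setAB - setRB,
        "001": setRB - setAB - setRA,
        "110": (setAB & setRA) - setRB,
        "101": (setAB & setRB) - setRA,
        "011": (setRA & setRB) - setAB,
        "111": setAB & setRA & setRB,
    }
    return VennPartition(regions=regions, focal_unique=setRB & setAB)


# ---------------------------------------------------------------------------
# Nei distance + neighbour joining

def _nei_from_array(g: np.ndarray, ids: list[str]) -> np.ndarray:
    n = len(ids)
    freq_alt = np.where(g == MISSING, np.nan, g / 2.0)
    freq_ref = 1.0 - freq_alt
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(freq_alt[i]) & ~np.isnan(freq_alt[j])
            if not ok.any():
                raise ValueError(
                    f"individuals {ids[i]!r} and {ids[j]!r} share no "
                    "genotyped site")
            jxy = (freq_ref[i, ok] * freq_ref[j, ok]
                   + freq_alt[i, ok] * freq_alt[j, ok]).mean()
            jx = (freq_ref[i, ok] ** 2 + freq_alt[i, ok] ** 2).mean()
            jy = (freq_ref[j, ok] ** 2 + freq_alt[j, ok] ** 2).mean()
            ident = jxy / np.sqrt(jx * jy)
            D[i, j] = D[j, i] = max(0.0, -np.log(min(ident, 1.0)))
    return D


def nei_distance_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Nei's (1972) standard distance between individuals.

    Each individual's per-site allele frequencies are (1 - d/2, d/2)
    from its dosage d; loci missing in either individual of a pair are
    excluded.  D = -ln( Jxy / sqrt(Jx Jy) ) with J the per-locus mean
    cross-products.  A pair sharing no genotyped site is an error.
    """
    ids = list(gm.individuals["id"])
    return _nei_from_array(gm.genotypes, ids), ids


def _nj_newick(D: np.ndarray, ids: list[str]) -> str:
    """Classical neighbour joining, newick without supports."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(D, ids))
    return str(tree).strip()


def _canon_split(side: frozenset, taxa: frozenset) -> frozenset:
    """Canonical key of a bipartition: smaller side, lexicographic on ties."""
    other = taxa - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return side if sorted(side) < sorted(other) else other


def _bipartitions(newick: str, taxa: frozenset) -> set[frozenset]:
    """Nontrivial bipartitions, canonically keyed."""
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(_canon_split(side, taxa))
    return parts


def nei_nj_tree(gm: GenotypeMatrix, n_boot: int = 1000,
                seed: int = 0) -> tuple[str, dict[frozenset, float]]:
    """Neighbour-joining tree on Nei distances with bootstrap supports.

    Bootstraps resample sites with replacement (individuals fixed).
    Returns (newick with support values as internal-node labels,
    {bipartition: support fraction}).
    """
    if gm.n_individuals < 4:
        raise ValueError("need at least 4 individuals for a NJ tree")
    import skbio

    D, ids = nei_distance_matrix(gm)
    main = _nj_newick(D, ids)
    taxa = frozenset(ids)
    main_parts = _bipartitions(main, taxa)
    counts = {p: 0 for p in main_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, gm.n_sites, gm.n_sites)
        Db = _nei_from_array(gm.genotypes[:, cols], ids)
        for p in _bipartitions(_nj_newick(Db, ids), taxa):
            if p in counts:
                counts[p] += 1
    support = {p: c / n_boot for p, c in counts.items()}

    tree = skbio.TreeNode.read(io.StringIO(main))
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        key = _canon_split(side, taxa)
        if key in support:
            node.name = f"{100 * support[key]:.0f}"
    return str(tree).strip(), support


# ---------------------------------------------------------------------------
# F_ST matrix + hierarchical clustering

def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def rec(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        a, b, h = int(Z[i - n, 0]), int(Z[i - n, 1]), Z[i - n, 2]
        sa, ha = rec(a)
        sb, hb = rec(b)
        return f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", h

    s, _ = rec(2 * n - 2)
    return s + ";"


def fst_matrix_and_clustering(gm: GenotypeMatrix, units: list[str],
                              grouping: str = "group"):
    """Pairwise multilocus F_ST matrix and its average-linkage dendrogram.

    The symmetric zero-diagonal matrix is clustered on Euclidean
    distances between its rows (UPGMA linkage); returns
    (DataFrame matrix, scipy linkage, newick dendrogram).
    """
    if len(units) < 3:
        raise ValueError("need at least 3 units to cluster")
    k = len(units)
    M = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = pairwise_fst(gm, units[i], units[j], mode="multilocus",
                             grouping=grouping)
            M[i, j] = M[j, i] = f
    from scipy.spatial.distance import pdist

    d = pdist(M, metric="euclidean")
    Z = hierarchy.average(d)
    newick = _linkage_to_newick(Z, list(units))
    return pd.DataFrame(M, index=units, columns=units), Z, newick
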