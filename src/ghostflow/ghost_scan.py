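"""Ghost-introgression signal detection on diverged SNP panels.

A lineage that received gene flow from an extinct or unsampled donor
carries physically clustered private SNPs; if the introgressed alleles
swept, heterozygosity drops while the private-allele frequency and the
divergence to non-introgressed lineages stay high.  The scan therefore
profiles each candidate SNP in the focal lineage (private-allele
frequency P_F, observed heterozygosity H_o, inbreeding coefficient
F_IS, pairwise F_ST to each contrast lineage) and chains sites passing
all thresholds into physical clusters.

``plant_introgression`` writes a synthetic introgressed block into a
genotype matrix, providing the positive control for the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .sumstats import _site_counts, _wc_components

__all__ = [
    "SnpProfile",
    "GhostCandidate",
    "ClusterThresholds",
    "snp_profiles",
    "detect_clusters",
    "plant_introgression",
]


@dataclass(frozen=True)
class SnpProfile:
    """Per-SNP ghost-scan statistics for the focal lineage."""

    chrom: str
    pos: int
    p_f: float                      # private-allele frequency in focal
    h_o: float                      # observed heterozygosity in focal
    f_is: float | None              # heterozygote deficit in focal
    fst: dict[str, float] = field(default_factory=dict)  # per contrast

    def min_fst(self) -> float:
        return min(self.fst.values())


@dataclass(frozen=True)
class ClusterThresholds:
    """Candidate filter; defaults bracket a strong sweep-like signal."""

    min_p_f: float = 0.5
    max_h_o: float = 0.5
    min_f_is: float = 0.1
    min_fst: float = 0.15

    def passes(self, s: SnpProfile) -> bool:
        return (s.p_f >= self.min_p_f and s.h_o <= self.max_h_o
                and s.f_is is not None and s.f_is >= self.min_f_is
                and s.min_fst() >= self.min_fst)


@dataclass
class GhostCandidate:
    """A physically clustered run of passing SNPs on one chromosome."""

    chrom: str
    members: list[SnpProfile]

    @property
    def span(self) -> int:
        return self.members[-1].pos - self.members[0].pos

    @property
    def n_snps(self) -> int:
        return len(self.members)

    def summary(self) -> dict:
        return {
            "chrom": self.chrom, "start": self.members[0].pos,
            "end": self.members[-1].pos, "n_snps": self.n_snps,
            "min_p_f": min(m.p_f for m in self.members),
            "max_h_o": max(m.h_o for m in self.members),
            "min_fst": min(m.min_fst() for m in self.members),
        }


def _focal_site_stats(g: np.ndarray, j: int):
    col = g[:, j]
    called = col != MISSING
    n = int(called.sum())
    if n == 0:
        return 0, 0, 0
    alt = int(col[called].sum())
    het = int((col[called] == 1).sum())
    return n, alt, het


def snp_profiles(gm: GenotypeMatrix, focal: str, contrasts: list[str],
                 sites: list[tuple[str, int]] | None = None,
                 grouping: str = "group") -> list[SnpProfile]:
    """Profile P_F, H_o, F_IS and pairwise F_ST at the given sites.

    ``sites`` is a list of (chrom, pos) — typically the focal lineage's
    diverged SNPs from a divergence scan; None profiles every site.
    P_F is 0 where the focal lineage carries no private allele.  F_IS
    is 1 - H_o/H_exp within the focal group; at H_exp = 0 it is set to
    1 when the allele is present in >= 2 copies with no heterozygote
    (complete deficit), else reported as None.
    """
    g_focal = gm.genotypes[gm.group_rows(focal, grouping)]
    g_contrast = {c: gm.genotypes[gm.group_rows(c, grouping)]
                  for c in contrasts}
    g_others = np.vstack(list(g_contrast.values()))

    if sites is None:
        idx = list(range(gm.n_sites))
    else:
        wanted = set(sites)
        idx = [j for j in range(gm.n_sites)
               if (gm.sites["chrom"].iat[j], int(gm.sites["pos"].iat[j]))
               in wanted]
    out: list[SnpProfile] = []
    for j in idx:
        n_f, alt_f, het_f = _focal_site_stats(g_focal, j)
        if n_f == 0:
            continue
        n_o, alt_o, _ = _focal_site_stats(g_others, j)
        # private allele of the focal group at this site, if any
        p_alt = alt_f / (2 * n_f)
        if alt_f > 0 and (n_o == 0 or alt_o == 0):
            p_f = p_alt
        elif alt_f < 2 * n_f and n_o > 0 and alt_o == 2 * n_o:
            p_f = 1.0 - p_alt
        else:
            p_f = 0.0
        h_o = het_f / n_f
        h_exp = 2.0 * p_alt * (1.0 - p_alt)
        if h_exp > 0:
            f_is = 1.0 - h_o / (h_exp * 2 * n_f / (2 * n_f - 1))
        elif het_f == 0 and min(alt_f, 2 * n_f - alt_f) == 0 and \
                (alt_f >= 2 or alt_f == 0):
            # monomorphic in focal: complete deficit convention only when
            # the fixed allele is private (>= 2 copies seen)
            f_is = 1.0 if p_f > 0 else None
        else:
            f_is = None
        fst = {}
        for c, gc in g_contrast.items():
            n_c, alt_c, het_c = _focal_site_stats(gc, j)
            if n_c == 0 or n_f < 2 or n_c < 2:
                continue
            tot_alt, tot_n = alt_f + alt_c, 2 * (n_f + n_c)
            if tot_alt == 0 or tot_alt == tot_n:
                fst[c] = 0.0
                continue
            a, b, cc = _wc_components(
                float(n_f), p_alt, h_o, float(n_c), alt_c / (2 * n_c),
                het_c / n_c)
            denom = a + b + cc
            fst[c] = float(a / denom) if denom != 0 else 0.0
        if not fst:
            continue
        out.append(SnpProfile(
            chrom=str(gm.sites["chrom"].iat[j]),
            pos=int(gm.sites["pos"].iat[j]),
            p_f=float(p_f), h_o=float(h_o), f_is=f_is, fst=fst))
    return out


def detect_clusters(profiles: list[SnpProfile], window_bp: int = 1000,
                    min_snps: int = 2,
                    thresholds: ClusterThresholds | None = None,
                    ) -> list[GhostCandidate]:
    """Chain threshold-passing SNPs into physical clusters.

    Consecutive passing sites on one chromosome within ``window_bp`` of
    each other join a cluster; clusters with at least ``min_snps``
    members are returned sorted by chromosome then position.
    """
    thresholds = thresholds or ClusterThresholds()
    passing = sorted((s for s in profiles if thresholds.passes(s)),
                     key=lambda s: (s.chrom, s.pos))
    clusters: list[GhostCandidate] = []
    current: list[SnpProfile] = []
    for s in passing:
        if current and s.chrom == current[-1].chrom \
                and s.pos - current[-1].pos <= window_bp:
            current.append(s)
        else:
            if len(current) >= min_snps:
                clusters.append(GhostCandidate(current[0].chrom, current))
            current = [s]
    if len(current) >= min_snps:
        clusters.append(GhostCandidate(current[0].chrom, current))
    return clusters


def plant_introgression(gm: GenotypeMatrix, focal: str, n_sites: int = 4,
                        carrier_fraction: float = 1.0,
                        block_span: int = 200, seed: int = 0,
                        grouping: str = "group") -> GenotypeMatrix:
    """Plant a synthetic introgressed block (validation fixture).

    Overwrites ``n_sites`` consecutive sites of the chromosome with most
    sites: carriers (a random ``carrier_fraction`` of the focal group)
    become homozygous for a divergent allele absent elsewhere; all other
    individuals become homozygous reference.  Site positions inside the
    block are compacted to span at most ``block_span`` bp.  Reproducible
    under ``seed``; ``carrier_fraction=0`` returns an unchanged copy.
    """
    out = gm.copy()
    if carrier_fraction == 0:
        return out
    rows = out.group_rows(focal, grouping)
    rng = np.random.default_rng(seed)
    chrom = out.sites["chrom"].value_counts().idxmax()
    chrom_idx = np.flatnonzero((out.sites["chrom"] == chrom).to_numpy())
    if len(chrom_idx) < n_sites:
        raise ValueError(
            f"block of {n_sites} sites exceeds chromosome {chrom} "
            f"({len(chrom_idx)} sites)")
    start = int(rng.integers(0, len(chrom_idx) - n_sites + 1))
    block = chrom_idx[start:start + n_sites]
    n_carriers = max(1, int(round(carrier_fraction * len(rows))))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    out.genotypes[:, block] = 0
    out.genotypes[np.ix_(carriers, block)] = 2
    # compact the block physically so it reads as one tight cluster
    base = int(out.sites["pos"].iat[block[0]])
    step = max(1, block_span // max(1, n_sites - 1))
    new_pos = out.sites["pos"].to_numpy().copy()
    for k, j in enumerate(block):
        new_pos[j] = base + k * step
    # keep positions strictly increasing on the chromosome
    for j in range(1, len(chrom_idx)):
        a, b = chrom_idx[j - 1], chrom_idx[j]
        if new_pos[b] <= new_pos[a]:
            new_pos[b] = new_pos[a] + 1
    out.sites = out.sites.assign(pos=new_pos)
    return out
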