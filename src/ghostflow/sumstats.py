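"""Diversity statistics and the 22-element two-population summary vector.

Per-unit diversity follows the usual SNP-panel conventions: expected
heterozygosity per site is 2p(1-p) with the small-sample correction
2n/(2n-1); observed heterozygosity is the heterozygote fraction among
non-missing calls; F_IS is the per-site heterozygote deficit
1 - H_obs/H_exp averaged over polymorphic sites; a private allele is an
allele seen in the focal unit and in no other unit.

Between-population differentiation uses the Weir & Cockerham (1984)
F_ST estimator; the multilocus value is the ratio of summed variance
components.  The 22-statistic vector used for ABC covers divergence,
expansion and size signals: eight per-group statistics for each of the
two groups (polymorphic-site count, mean H_exp, mean H_obs, mean F_IS,
Tajima's D, singleton fraction, private-site count, mean private-allele
frequency) plus six joint ones (multilocus F_ST, SD of per-site F_ST,
mean absolute allele-frequency difference, shared-polymorphism count,
fixed-difference count, d_xy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "STAT_NAMES",
    "DiversityReport",
    "diversity_report",
    "pairwise_fst",
    "site_pattern_stats",
    "compute_sumstats",
    "sumstats_from_dosages",
]

logger = logging.getLogger(__name__)

_GROUP_STATS = ("poly", "hexp", "hobs", "fis", "tajd", "singleton",
                "priv", "privfreq")
_JOINT_STATS = ("fst", "fst_site_sd", "afd_mean", "shared_poly",
                "fixed_diff", "dxy")

#: canonical names and order of the 22 summary statistics
STAT_NAMES: tuple[str, ...] = tuple(
    f"{s}_A" for s in _GROUP_STATS) + tuple(
    f"{s}_B" for s in _GROUP_STATS) + _JOINT_STATS

assert len(STAT_NAMES) == 22


# ---------------------------------------------------------------------------
# per-site frequency machinery (vectorized over sites)

def _site_counts(geno: np.ndarray):
    """(called diploids, alt copies, het count) per site, missing-aware."""
    miss = geno == MISSING
    n = (~miss).sum(axis=0)
    alt = np.where(miss, 0, geno).sum(axis=0)
    het = (geno == 1).sum(axis=0)
    return n, alt, het


def _group_block(geno: np.ndarray):
    """The eight per-group statistics from one group's dosage submatrix.

    Statistics undefined on the input (e.g. Tajima's D with no
    polymorphism) are imputed with 0; imputations are logged.
    """
    n, alt, het = _site_counts(geno)
    ok = n >= 2
    two_n = 2.0 * n[ok]
    p = alt[ok] / two_n
    poly = (alt[ok] > 0) & (alt[ok] < 2 * n[ok])
    n_poly = int(poly.sum())

    hexp = 2.0 * p * (1.0 - p) * two_n / (two_n - 1.0)
    hobs = het[ok] / n[ok]
    mean_hexp = float(hexp.mean()) if hexp.size else 0.0
    mean_hobs = float(hobs.mean()) if hobs.size else 0.0

    if n_poly:
        fis = float(np.mean(1.0 - hobs[poly] / hexp[poly]))
    else:
        logger.debug("F_IS undefined (no polymorphic sites); imputed 0")
        fis = 0.0

    # Tajima's D over the panel's polymorphic sites, haploid sample size
    # taken as the (rounded) mean number of called haplotypes
    if n_poly:
        nh = int(round(two_n[poly].mean()))
        minor = np.minimum(alt[ok][poly], 2 * n[ok][poly] - alt[ok][poly])
        k2 = alt[ok][poly] * (2.0 * n[ok][poly] - alt[ok][poly])
        pi = float((2.0 * k2 / (two_n[poly] * (two_n[poly] - 1.0))).sum())
        tajd = _tajima_d(n_poly, pi, nh)
        singleton = float((minor == 1).mean())
    else:
        logger.debug("Tajima's D undefined (no polymorphic sites); imputed 0")
        tajd = 0.0
        singleton = 0.0

    return {
        "poly": float(n_poly), "hexp": mean_hexp, "hobs": mean_hobs,
        "fis": fis, "tajd": tajd, "singleton": singleton,
    }, (n, alt)


def _tajima_d(S: int, pi: float, nh: int) -> float:
    """Tajima's D from segregating sites S, mean pairwise diff pi, n haplotypes."""
    if S == 0 or nh < 4:
        return 0.0
    i = np.arange(1, nh)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (nh + 1.0) / (3.0 * (nh - 1.0))
    b2 = 2.0 * (nh * nh + nh + 3.0) / (9.0 * nh * (nh - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (nh + 2.0) / (a1 * nh) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return 0.0
    return (pi - S / a1) / math.sqrt(var)


def _private_stats(n1, alt1, n2, alt2):
    """Private-site count and mean private-allele frequency for unit 1.

    An allele is private to unit 1 when it is observed there and absent
    from unit 2 (among called genotypes); its frequency is taken within
    unit 1.  Sites with no calls in either unit are skipped.
    """
    ok = (n1 > 0) & (n2 > 0)
    a1, a2 = alt1[ok], alt2[ok]
    t1 = 2 * n1[ok]
    priv_alt = (a1 > 0) & (a2 == 0)
    priv_ref = (a1 < t1) & (a2 == 2 * n2[ok])
    freqs = np.concatenate([
        a1[priv_alt] / t1[priv_alt],
        (t1[priv_ref] - a1[priv_ref]) / t1[priv_ref],
    ])
    count = int(priv_alt.sum() + priv_ref.sum())
    mean_freq = float(freqs.mean()) if freqs.size else 0.0
    return count, mean_freq


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST

def _wc_components(n1, p1, h1, n2, p2, h2):
    """Per-site W-C variance components (a, b, c) for two populations.

    ``n`` are called diploid counts, ``p`` alternate-allele frequencies,
    ``h`` observed heterozygote frequencies.  Follows the r=2 special
    case of the 1984 estimator, component by component.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                             - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c


def _fst_from_dosages(g1: np.ndarray, g2: np.ndarray, mode: str):
    n1, alt1, het1 = _site_counts(g1)
    n2, alt2, het2 = _site_counts(g2)
    ok = (n1 >= 2) & (n2 >= 2)
    # exclude sites monomorphic across both units
    tot_alt = alt1 + alt2
    tot_n = 2 * (n1 + n2)
    ok &= (tot_alt > 0) & (tot_alt < tot_n)
    if not ok.any():
        raise ValueError("no usable sites for F_ST")
    f1, f2 = n1[ok].astype(float), n2[ok].astype(float)
    p1, p2 = alt1[ok] / (2 * f1), alt2[ok] / (2 * f2)
    h1, h2 = het1[ok] / f1, het2[ok] / f2
    a, b, c = _wc_components(f1, p1, h1, f2, p2, h2)
    if mode == "per-site":
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(denom != 0, a / denom, np.nan)
        out = np.full(ok.shape, np.nan)
        out[ok] = theta
        return out
    denom = float((a + b + c).sum())
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


# ---------------------------------------------------------------------------
# public API

@dataclass
class DiversityReport:
    """Per-unit diversity table; ``table`` is indexed by unit name."""

    grouping: str
    table: pd.DataFrame

    def __getitem__(self, unit: str) -> pd.Series:
        return self.table.loc[unit]


def diversity_report(gm: GenotypeMatrix,
                     grouping: str = "group") -> DiversityReport:
    """H_exp, H_obs, F_IS, private alleles and polymorphism per unit.

    Units with fewer than two genotyped individuals are skipped with a
    warning.  P_F is reported as NaN (absent) when a unit has no private
    alleles.
    """
    units = gm.unit_indices(grouping)
    counts = {}
    usable = {}
    for name, rows in units.items():
        sub = gm.genotypes[rows]
        if (np.sum((sub != MISSING).any(axis=1))) < 2:
            logger.warning("unit %r has < 2 genotyped individuals; skipped",
                           name)
            continue
        usable[name] = sub
        counts[name] = _site_counts(sub)

    records = []
    for name, sub in usable.items():
        block, (n, alt) = _group_block(sub)
        # private alleles vs. the union of all other usable units
        others = [counts[o] for o in usable if o != name]
        if others:
            n_o = sum(o[0] for o in others)
            alt_o = sum(o[1] for o in others)
            pn, pf = _private_stats(n, alt, n_o, alt_o)
        else:
            pn, pf = 0, 0.0
        records.append({
            "unit": name, "n_individuals": int(len(units[name])),
            "polymorphic_sites": int(block["poly"]),
            "H_exp": block["hexp"], "H_obs": block["hobs"],
            "F_IS": block["fis"], "P_N": pn,
            "P_F": pf if pn else np.nan,
        })
    if not records:
        raise ValueError("no unit has >= 2 genotyped individuals")
    table = pd.DataFrame.from_records(records).set_index("unit")
    return DiversityReport(grouping=grouping, table=table)


def pairwise_fst(gm: GenotypeMatrix, unit1: str, unit2: str,
                 mode: str = "multilocus", grouping: str = "group"):
    """Weir-Cockerham F_ST between two units.

    ``mode='multilocus'`` returns the ratio of summed variance components
    (a float); ``mode='per-site'`` returns an array aligned with
    ``gm.sites`` (NaN where undefined).  Sites monomorphic across both
    units are excluded; per-site values may be negative.
    """
    if mode not in ("multilocus", "per-site"):
        raise ValueError("mode must be 'multilocus' or 'per-site'")
    g1 = gm.genotypes[gm.group_rows(unit1, grouping)]
    g2 = gm.genotypes[gm.group_rows(unit2, grouping)]
    return _fst_from_dosages(g1, g2, mode)


def site_pattern_stats(gm: GenotypeMatrix, unit: str,
                       grouping: str = "group") -> dict:
    """Folded SFS, Tajima's D and singleton fraction within one unit.

    With no polymorphic site, D is undefined and reported as None.
    """
    sub = gm.genotypes[gm.group_rows(unit, grouping)]
    n, alt, _het = _site_counts(sub)
    ok = n >= 2
    if 2 * int(n[ok].max(initial=0)) < 4:
        raise ValueError("need at least 4 haplotypes")
    minor = np.minimum(alt[ok], 2 * n[ok] - alt[ok])
    poly = minor > 0
    nh = int(round((2 * n[ok][poly]).mean())) if poly.any() else 2 * int(n[ok].max())
    sfs = np.bincount(minor[poly], minlength=nh // 2 + 1)
    sfs[0] = 0
    if not poly.any():
        return {"folded_sfs": sfs, "tajimas_d": None, "singleton_fraction": 0.0}
    two_n = (2.0 * n[ok][poly])
    k2 = alt[ok][poly] * (2.0 * n[ok][poly] - alt[ok][poly])
    pi = float((2.0 * k2 / (two_n * (two_n - 1.0))).sum())
    return {
        "folded_sfs": sfs,
        "tajimas_d": _tajima_d(int(poly.sum()), pi, nh),
        "singleton_fraction": float((minor[poly] == 1).mean()),
    }


def sumstats_from_dosages(gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    """The 22-vector from two dosage submatrices (fast path, no metadata)."""
    blockA, (nA, altA) = _group_block(gA)
    blockB, (nB, altB) = _group_block(gB)
    pnA, pfA = _private_stats(nA, altA, nB, altB)
    pnB, pfB = _private_stats(nB, altB, nA, altA)

    ok = (nA > 0) & (nB > 0)
    pA = altA[ok] / (2.0 * nA[ok])
    pB = altB[ok] / (2.0 * nB[ok])
    afd = float(np.abs(pA - pB).mean()) if ok.any() else 0.0
    polyA = (pA > 0) & (pA < 1)
    polyB = (pB > 0) & (pB < 1)
    shared = float((polyA & polyB).sum())
    fixed = float((((pA == 0) & (pB == 1)) | ((pA == 1) & (pB == 0))).sum())
    dxy = float((pA * (1 - pB) + pB * (1 - pA)).mean()) if ok.any() else 0.0
    try:
        fst = _fst_from_dosages(gA, gB, "multilocus")
        per_site = _fst_from_dosages(gA, gB, "per-site")
        fst_sd = float(np.nanstd(per_site))
    except ValueError:
        logger.debug("F_ST undefined (no usable sites); imputed 0")
        fst, fst_sd = 0.0, 0.0

    vec = np.array(
        [blockA["poly"], blockA["hexp"], blockA["hobs"], blockA["fis"],
         blockA["tajd"], blockA["singleton"], float(pnA), pfA,
         blockB["poly"], blockB["hexp"], blockB["hobs"], blockB["fis"],
         blockB["tajd"], blockB["singleton"], float(pnB), pfB,
         fst, fst_sd, afd, shared, fixed, dxy])
    return vec


def compute_sumstats(gm: GenotypeMatrix, groupA: str, groupB: str,
                     grouping: str = "group") -> pd.Series:
    """The canonical 22 summary statistics for a pair of groups.

    Invariant to individual and site ordering; statistics undefined on
    the input are imputed with 0 (logged at debug level).
    """
    gA = gm.genotypes[gm.group_rows(groupA, grouping)]
    gB = gm.genotypes[gm.group_rows(groupB, grouping)]
    return pd.Series(sumstats_from_dosages(gA, gB), index=list(STAT_NAMES))
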