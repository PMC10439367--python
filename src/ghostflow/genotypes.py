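"""SNP genotype matrices, VCF I/O and the quality-filtering cascade.

Genotypes are diploid allele dosages (count of the alternate allele,
0/1/2) with ``MISSING = -1``; sites are biallelic SNPs with 1-based VCF
coordinates.  Individuals carry a population label and a coarser group
label (e.g. islands nested in the lineages Ryu / TaiA / TaiB).

The filtering cascade reproduces standard ddRAD SNP quality control:
per-genotype depth/quality masking, removal of high-missingness
individuals, then site-level minor-allele-frequency, observed-
heterozygosity and missingness cuts, optionally followed by removal of
sites entirely missing within any one population (or group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterConfig",
    "FilterReport",
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "mask_low_quality",
    "filter_matrix",
    "DATASET_PRESETS",
]

MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (individuals x sites) with site/sample metadata.

    ``genotypes`` is int8 with values in {0, 1, 2, MISSING}. ``sites`` has
    columns (chrom, pos, ref, alt) with positions strictly increasing
    within each chromosome; ``individuals`` has columns
    (id, population, group).  ``depth`` and ``qual`` are optional
    per-genotype integer arrays of the same shape.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    individuals: pd.DataFrame
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        n_ind, n_sites = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals table does not match genotype rows")
        if len(self.sites) != n_sites:
            raise ValueError("sites table does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on {chrom}")
        self.sites = self.sites.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic views -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def unit_indices(self, grouping: str = "group") -> dict[str, np.ndarray]:
        """Row indices per population or per group, in first-seen order."""
        if grouping not in ("population", "group"):
            raise ValueError("grouping must be 'population' or 'group'")
        col = self.individuals[grouping]
        out: dict[str, np.ndarray] = {}
        for name in col.drop_duplicates():
            out[name] = np.flatnonzero((col == name).to_numpy())
        return out

    def group_rows(self, name: str, grouping: str = "group") -> np.ndarray:
        idx = self.unit_indices(grouping)
        if name not in idx:
            raise KeyError(f"no {grouping} named {name!r}")
        return idx[name]

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx].copy(),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            individuals=self.individuals.copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            qual=None if self.qual is None else self.qual[:, idx].copy(),
        )

    def take_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx].copy(),
            sites=self.sites.copy(),
            individuals=self.individuals.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[idx].copy(),
            qual=None if self.qual is None else self.qual[idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotypes=self.genotypes.copy(), sites=self.sites.copy(),
            individuals=self.individuals.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            qual=None if self.qual is None else self.qual.copy())


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP quality-control cascade.

    Site-level cuts keep sites with MAF >= ``maf_min``, observed
    heterozygosity < ``max_obs_het`` and missing rate <= ``max_site_missing``;
    genotypes with depth < ``min_depth`` or quality < ``min_gq`` are masked
    first, then individuals with missing rate > ``max_indiv_missing`` are
    dropped.
    """

    maf_min: float = 0.05
    max_obs_het: float = 0.8
    min_depth: int = 3
    min_gq: int = 10
    max_site_missing: float = 0.60
    max_indiv_missing: float = 0.35
    drop_group_specific_missing: bool = False
    missing_unit: str = "population"  # unit for the all-missing-site cut

    def __post_init__(self):
        for name in ("maf_min", "max_obs_het", "max_site_missing",
                     "max_indiv_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.missing_unit not in ("population", "group"):
            raise ValueError("missing_unit must be 'population' or 'group'")


#: the three canonical dataset configurations, as filter presets:
#: "all" keeps every QC-passing SNP, "neutral" is the same cascade (outlier
#: removal happens upstream), "taiwan" additionally drops sites missing in
#: any one population of the retained (Taiwan-only) individuals.
DATASET_PRESETS: dict[str, FilterConfig] = {
    "all_snps": FilterConfig(),
    "neutral_snps": FilterConfig(),
    "taiwan_all_snps": FilterConfig(drop_group_specific_missing=True,
                                    missing_unit="group"),
}


@dataclass
class FilterReport:
    """Counts removed at each step of the cascade."""

    genotypes_masked: int = 0
    individuals_removed: int = 0
    sites_removed_maf: int = 0
    sites_removed_het: int = 0
    sites_removed_missing: int = 0
    sites_removed_unit_missing: int = 0
    input_sites: int = 0
    output_sites: int = 0
    input_individuals: int = 0
    output_individuals: int = 0

    def sites_removed_total(self) -> int:
        return (self.sites_removed_maf + self.sites_removed_het
                + self.sites_removed_missing + self.sites_removed_unit_missing)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": ["genotypes_masked", "individuals_removed",
                      "sites_removed_maf", "sites_removed_het",
                      "sites_removed_missing", "sites_removed_unit_missing"],
             "count": [self.genotypes_masked, self.individuals_removed,
                       self.sites_removed_maf, self.sites_removed_het,
                       self.sites_removed_missing,
                       self.sites_removed_unit_missing]})


# ---------------------------------------------------------------------------
# VCF / popmap I/O

def read_popmap(path) -> pd.DataFrame:
    """Read a 3-column TSV (individual, population, group); '#' comments."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(
            f"popmap {path} needs 3 columns (individual, population, group)")
    df = df.iloc[:, :3]
    df.columns = ["id", "population", "group"]
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate individual {dup!r} in popmap")
    return df


def read_vcf(path, popmap, drop_non_biallelic: bool = False) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF plus a popmap.

    Dosage is the alternate-allele count; half-calls and uncalled
    genotypes become MISSING.  FORMAT/DP and FORMAT/GQ are carried along
    when present.  Every VCF sample must appear in the popmap.
    """
    from cyvcf2 import VCF

    pm = popmap if isinstance(popmap, pd.DataFrame) else read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    known = set(pm["id"])
    for s in samples:
        if s not in known:
            raise ValueError(f"sample {s!r} in VCF is absent from the popmap")
    fmts = None
    rows = []
    chroms, poss, refs, alts = [], [], [], []
    depth_rows, qual_rows = [], []
    has_depth = has_gq = False
    for line_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or var.REF is None or len(var.REF) != 1 \
                or len(var.ALT[0]) != 1:
            if drop_non_biallelic:
                continue
            raise ValueError(
                f"non-biallelic-SNP record at {var.CHROM}:{var.POS} "
                f"(record {line_no}); pass drop_non_biallelic=True to skip")
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.genotype.array()[:, :2]
        dos = np.where((gt < 0).any(axis=1), MISSING,
                       (gt > 0).sum(axis=1)).astype(np.int8)
        rows.append(dos)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depth_rows.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]))
        else:
            depth_rows.append(np.full(len(samples), -1))
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            has_gq = True
            qual_rows.append(np.where(gq[:, 0] < 0, -1, gq[:, 0]))
        else:
            qual_rows.append(np.full(len(samples), -1))
    if not rows:
        raise ValueError(f"no usable sites in {path}")
    geno = np.stack(rows, axis=1)  # individuals x sites
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                          "alt": alts})
    indiv = pm.set_index("id").loc[samples].reset_index()
    depth = np.stack(depth_rows, axis=1).astype(np.int32) if has_depth else None
    qual = np.stack(qual_rows, axis=1).astype(np.int32) if has_gq else None
    return GenotypeMatrix(genotypes=geno, sites=sites, individuals=indiv,
                          depth=depth, qual=qual)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with unphased GT (and DP/GQ when present)."""
    if gm.n_sites == 0 or gm.n_individuals == 0:
        raise ValueError("cannot write an empty genotype matrix")
    with_depth = gm.depth is not None
    with_qual = gm.qual is not None
    fmt = "GT" + (":DP" if with_depth else "") + (":GQ" if with_qual else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
        if with_qual:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Genotype quality">\n')
        for chrom in gm.sites["chrom"].drop_duplicates():
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + list(gm.individuals["id"])
        fh.write("\t".join(header) + "\n")
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            fields = [str(site["chrom"]), str(site["pos"]), ".",
                      str(site["ref"]), str(site["alt"]), ".", "PASS", ".",
                      fmt]
            for i in range(gm.n_individuals):
                cell = _GT_STR[int(gm.genotypes[i, j])]
                if with_depth:
                    d = int(gm.depth[i, j])
                    cell += ":" + (str(d) if d >= 0 else ".")
                if with_qual:
                    q = int(gm.qual[i, j])
                    cell += ":" + (str(q) if q >= 0 else ".")
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# filtering cascade

def mask_low_quality(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Mask genotypes with depth < min_depth or quality < min_gq.

    Absent depth/quality values (encoded negative) are treated as passing;
    nothing but the failing genotypes changes.
    """
    out = gm.copy()
    mask = np.zeros(out.genotypes.shape, dtype=bool)
    if out.depth is not None:
        mask |= (out.depth >= 0) & (out.depth < cfg.min_depth)
    if out.qual is not None:
        mask |= (out.qual >= 0) & (out.qual < cfg.min_gq)
    out.genotypes[mask] = MISSING
    return out


def _site_stats(geno: np.ndarray):
    """Per-site (alt frequency, observed het, missing rate) over non-missing."""
    miss = geno == MISSING
    n_called = (~miss).sum(axis=0)
    alt = np.where(miss, 0, geno).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        het = np.where(n_called > 0,
                       ((geno == 1).sum(axis=0)) / n_called, np.nan)
    miss_rate = miss.mean(axis=0) if geno.shape[0] else np.ones(geno.shape[1])
    return p, het, miss_rate


def filter_matrix(gm: GenotypeMatrix,
                  cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full cascade; returns the filtered matrix and a report.

    Order: genotype masking -> individual missing-rate removal -> site
    MAF (kept when >= maf_min) / observed-het (< max_obs_het) / missing
    (<= max_site_missing) removal -> optional removal of sites entirely
    missing within any one population or group.
    """
    rep = FilterReport(input_sites=gm.n_sites,
                       input_individuals=gm.n_individuals)
    pre_missing = int((gm.genotypes == MISSING).sum())
    gm = mask_low_quality(gm, cfg)
    rep.genotypes_masked = int((gm.genotypes == MISSING).sum()) - pre_missing

    indiv_miss = (gm.genotypes == MISSING).mean(axis=1)
    keep_ind = indiv_miss <= cfg.max_indiv_missing
    rep.individuals_removed = int((~keep_ind).sum())
    if not keep_ind.any():
        raise ValueError("empty dataset after filtering: no individuals left")
    if rep.individuals_removed:
        gm = gm.take_individuals(keep_ind)

    p, het, miss_rate = _site_stats(gm.genotypes)
    maf = np.minimum(p, 1.0 - p)
    called = ~np.isnan(p)
    drop_maf = called & (maf < cfg.maf_min)
    drop_het = called & ~drop_maf & (het >= cfg.max_obs_het)
    drop_miss = (~called | (miss_rate > cfg.max_site_missing)) \
        & ~drop_maf & ~drop_het
    rep.sites_removed_maf = int(drop_maf.sum())
    rep.sites_removed_het = int(drop_het.sum())
    rep.sites_removed_missing = int(drop_miss.sum())
    keep = ~(drop_maf | drop_het | drop_miss)
    if not keep.any():
        raise ValueError("empty dataset after filtering: no sites left")
    gm = gm.take_sites(keep)

    if cfg.drop_group_specific_missing:
        units = gm.unit_indices(cfg.missing_unit)
        all_missing = np.zeros(gm.n_sites, dtype=bool)
        for rows in units.values():
            all_missing |= (gm.genotypes[rows] == MISSING).all(axis=0)
        rep.sites_removed_unit_missing = int(all_missing.sum())
        if all_missing.all():
            raise ValueError("empty dataset after filtering: no sites left")
        if all_missing.any():
            gm = gm.take_sites(~all_missing)

    rep.output_sites = gm.n_sites
    rep.output_individuals = gm.n_individuals
    return gm, rep
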