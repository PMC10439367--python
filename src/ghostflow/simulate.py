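"""Ascertained SNP-panel simulation and ABC reference tables.

``simulate_snps`` produces a genotype matrix of unlinked biallelic SNPs
for the two sampled lineages under any scenario: each SNP is an
independent coalescent genealogy carrying one mutation, ascertained to
a pooled minor-allele frequency at or above the panel cutoff, with
diploid genotypes formed by pairing haplotypes.  The default backend is
the compiled engine in :mod:`ghostflow.engine`; ``backend="msprime"``
runs the identical event schedule through msprime (slower; used for
cross-validation).

``build_reference_table`` maps prior draws through the simulator and
the 22 summary statistics to the (scenario, parameters, statistics)
table on which ABC random forests are trained.  Per-row seeds are
derived from the master seed by row index, so chunked and single-pass
runs produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine
from .genotypes import MISSING, GenotypeMatrix
from .scenarios import (PriorSpec, ScenarioParams, Schedule, build_schedule,
                        sample_priors, to_msprime_demography)
from .sumstats import STAT_NAMES, sumstats_from_dosages

__all__ = [
    "SampleConfig",
    "simulate_snps",
    "simulate_branch_stats",
    "ReferenceTable",
    "build_reference_table",
    "PARAM_COLUMNS",
]

#: parameter column order of a reference table
PARAM_COLUMNS = ("N_A", "N_B", "N_aA", "N_aB", "N_anc", "N_ghost",
                 "m_A", "m_B", "m_G", "m_AG", "h_frac",
                 "T_m", "T_div", "T_divG", "T_G")

_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 12))
_CHROM_LENGTH = 500_000_000


@dataclass(frozen=True)
class SampleConfig:
    """Sampling and ascertainment design of the SNP panel.

    Defaults mirror the study design this package emulates: 20 + 10
    diploids from the two sampled lineages, ascertainment at pooled
    MAF >= 0.05, and the ghost never sampled.

    Two panel designs exist.  The fixed panel (``design='panel'``)
    returns exactly ``n_snps`` ascertained SNPs, one per genealogy —
    convenient for fixtures, but its statistics are frequency-only and
    carry no absolute-scale information.  The ddRAD emulation
    (``design='ddrad'``) genotypes ``n_loci`` short loci at a fixed
    per-locus mutation rate ``mu_locus`` and keeps at most one
    ascertained SNP per polymorphic locus, so the returned SNP count is
    random; that count anchors the absolute population-size/time scale
    the way real reduced-representation data do.  The defaults are
    calibrated so the expected SNP yield at this system's fitted
    parameters is ~801.
    """

    n_A: int = 20
    n_B: int = 10
    n_snps: int = 801
    maf_asc: float = 0.05
    missing_rate: float = 0.0
    n_loci: int = 2016
    mu_locus: float = 2.5e-6

    def __post_init__(self):
        if self.n_snps <= 0 or self.n_loci <= 0:
            raise ValueError("n_snps and n_loci must be positive")
        if self.mu_locus <= 0:
            raise ValueError("mu_locus must be positive")
        if self.n_A < 1 or self.n_B < 1:
            raise ValueError("need at least one diploid per sampled lineage")
        if not 0.0 <= self.maf_asc < 0.5:
            raise ValueError("maf_asc must be in [0, 0.5)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_hap(self) -> int:
        return 2 * (self.n_A + self.n_B)


def _sample_pops(sc: SampleConfig) -> np.ndarray:
    pop0 = np.zeros(sc.n_hap, dtype=np.int64)
    pop0[2 * sc.n_A:] = 1
    return pop0


def _min_minor(sc: SampleConfig) -> int:
    # MAF >= maf_asc, ties kept (minor copies >= ceil(maf_asc * n_hap))
    return int(np.ceil(sc.maf_asc * sc.n_hap - 1e-9))


def _random_sites(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    """Unlinked SNPs get arbitrary coordinates spread over 11 chromosomes."""
    chrom_idx = rng.integers(0, len(_CHROMOSOMES), n_snps)
    pos = rng.integers(1, _CHROM_LENGTH, n_snps)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    # resolve duplicate positions within a chromosome deterministically
    for i in range(1, n_snps):
        if chrom_idx[i] == chrom_idx[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pd.DataFrame({
        "chrom": [_CHROMOSOMES[i] for i in chrom_idx],
        "pos": pos,
        "ref": "A", "alt": "T",
    })


def _individual_table(sc: SampleConfig) -> pd.DataFrame:
    ids = [f"A{i:03d}" for i in range(sc.n_A)] + \
          [f"B{i:03d}" for i in range(sc.n_B)]
    group = ["TaiA"] * sc.n_A + ["TaiB"] * sc.n_B
    return pd.DataFrame({"id": ids, "population": group, "group": group})


_MAX_TRY_FACTOR = 1000  # ascertainment failure beyond this rejection rate


def simulate_haplotypes(p: ScenarioParams, sc: SampleConfig, seed: int,
                        backend: str = "native",
                        design: str = "panel") -> np.ndarray:
    """Ascertained 0/1 haplotypes, shape (n_hap, n_kept_snps)."""
    schedule = build_schedule(p)
    if design == "ddrad":
        sizes0, mig0, t, kind, ii, jj, val = schedule.to_arrays()
        haps, kept, status = engine.simulate_ddrad_haplotypes(
            sizes0, mig0, t, kind, ii, jj, val, _sample_pops(sc),
            sc.n_loci, sc.mu_locus, _min_minor(sc),
            int(seed) % (2**31 - 1))
        if status != engine.OK:
            raise RuntimeError("malformed schedule: lineages cannot coalesce")
        return haps[:, :kept]
    if design != "panel":
        raise ValueError(f"unknown design {design!r}")
    if backend == "native":
        sizes0, mig0, t, kind, ii, jj, val = schedule.to_arrays()
        haps, tries, status = engine.simulate_dataset_haplotypes(
            sizes0, mig0, t, kind, ii, jj, val, _sample_pops(sc),
            sc.n_snps, _min_minor(sc), _MAX_TRY_FACTOR * sc.n_snps,
            int(seed) % (2**31 - 1))
        if status == engine.ASCERTAINMENT_FAILURE:
            raise RuntimeError(
                "ascertainment failure: almost no realization reaches "
                f"MAF {sc.maf_asc}; check the parameter vector")
        if status != engine.OK:
            raise RuntimeError("malformed schedule: lineages cannot coalesce")
        return haps
    if backend == "msprime":
        return _simulate_haplotypes_msprime(schedule, sc, seed)
    raise ValueError(f"unknown backend {backend!r}")


def _simulate_haplotypes_msprime(schedule: Schedule, sc: SampleConfig,
                                 seed: int) -> np.ndarray:
    """msprime backend: same one-mutation-per-genealogy convention."""
    import msprime

    demog = to_msprime_demography(schedule)
    rng = np.random.default_rng(seed)
    min_minor = _min_minor(sc)
    haps = np.zeros((sc.n_hap, sc.n_snps), dtype=np.int8)
    got = tries = 0
    max_tries = _MAX_TRY_FACTOR * sc.n_snps
    while got < sc.n_snps:
        batch = int(1.5 * (sc.n_snps - got)) + 16
        reps = msprime.sim_ancestry(
            samples={"TaiA": sc.n_A, "TaiB": sc.n_B}, demography=demog,
            sequence_length=1, num_replicates=batch,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            record_provenance=False)
        for ts in reps:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "ascertainment failure: almost no realization reaches "
                    f"MAF {sc.maf_asc}; check the parameter vector")
            parent = ts.edges_parent
            child = ts.edges_child
            time = ts.nodes_time
            bl = time[parent] - time[child]
            cum = np.cumsum(bl)
            target = rng.random() * cum[-1]
            e = int(np.searchsorted(cum, target, side="right"))
            member = np.zeros(ts.num_nodes, dtype=bool)
            member[child[e]] = True
            for k in range(len(parent) - 1, -1, -1):
                if member[parent[k]]:
                    member[child[k]] = True
            derived = member[:sc.n_hap]
            cnt = int(derived.sum())
            if min(cnt, sc.n_hap - cnt) >= min_minor:
                haps[:, got] = derived
                got += 1
                if got == sc.n_snps:
                    break
    return haps


def simulate_snps(p: ScenarioParams, sc: SampleConfig, seed: int,
                  backend: str = "native",
                  design: str = "panel") -> GenotypeMatrix:
    """Simulate an ascertained unlinked-SNP genotype matrix.

    With the default fixed-panel design, exactly ``sc.n_snps`` biallelic
    sites, each an independent coalescent realization with pooled MAF
    >= ``sc.maf_asc``; with ``design='ddrad'`` the SNP count is the
    random yield of ``sc.n_loci`` loci (see SampleConfig).
    Deterministic under ``seed``; optional uniform random missingness at
    ``sc.missing_rate``.
    """
    haps = simulate_haplotypes(p, sc, seed, backend=backend, design=design)
    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD05A]))
    if sc.missing_rate > 0:
        mask = rng.random(dosages.shape) < sc.missing_rate
        dosages[mask] = MISSING
    return GenotypeMatrix(
        genotypes=dosages,
        sites=_random_sites(dosages.shape[1], rng),
        individuals=_individual_table(sc),
    )


def simulate_branch_stats(p: ScenarioParams, sc: SampleConfig, n_loci: int,
                          seed: int):
    """Total branch length and TMRCA for independent genealogies.

    The per-locus segregating-site count under an infinite-sites model
    with per-locus mutation rate ``mu`` is Poisson(mu * total length);
    used by mutation-count oracles and diagnostics.
    """
    schedule = build_schedule(p)
    sizes0, mig0, t, kind, ii, jj, val = schedule.to_arrays()
    return engine.simulate_branch_stats(
        sizes0, mig0, t, kind, ii, jj, val, _sample_pops(sc), n_loci,
        int(seed) % (2**31 - 1))


# ---------------------------------------------------------------------------
# reference tables

@dataclass
class ReferenceTable:
    """Rows of (scenario, parameter vector, 22 summary statistics)."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in ("scenario", *PARAM_COLUMNS, *STAT_NAMES)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"reference table lacks columns: {missing}")
        stats = self.data[list(STAT_NAMES)].to_numpy()
        if not np.all(np.isfinite(stats)):
            raise ValueError("non-finite summary statistics in reference table")

    @property
    def scenarios(self) -> list[str]:
        return list(self.data["scenario"].drop_duplicates())

    def stats_matrix(self) -> np.ndarray:
        return self.data[list(STAT_NAMES)].to_numpy(dtype=float)

    def params_matrix(self) -> pd.DataFrame:
        return self.data[list(PARAM_COLUMNS)]

    def subset_scenario(self, scenario: str) -> "ReferenceTable":
        sub = self.data[self.data["scenario"] == scenario]
        if sub.empty:
            raise ValueError(f"no rows for scenario {scenario!r}")
        return ReferenceTable(sub.reset_index(drop=True), dict(self.meta))

    def save(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta_path = path.with_suffix(path.suffix + ".meta")
        with open(meta_path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"{k}\t{v}\n")

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        path = Path(path)
        data = pd.read_csv(path)
        meta = {}
        meta_path = path.with_suffix(path.suffix + ".meta")
        if meta_path.exists():
            with open(meta_path) as fh:
                for line in fh:
                    if "\t" in line:
                        k, v = line.rstrip("\n").split("\t", 1)
                        meta[k] = v
        return cls(data, meta)


def _row_seed(master_seed: int, scenario_index: int, row: int) -> int:
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(scenario_index, row))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1


def build_reference_table(scenarios, prior: PriorSpec, n_per_scenario: int,
                          sc: SampleConfig, seed: int,
                          backend: str = "native",
                          design: str = "ddrad",
                          row_range: tuple[int, int] | None = None,
                          progress: bool = False) -> ReferenceTable:
    """Simulate an ABC reference table.

    ``n_per_scenario`` rows per scenario; each row draws a parameter
    vector from the prior, simulates an ascertained SNP panel (ddRAD
    emulation by default, so the SNP yield varies with the parameters)
    and computes the 22 summary statistics.  Per-row seeds are derived
    from (seed, scenario index, row index), so a run restricted with
    ``row_range=(lo, hi)`` reproduces exactly those rows of the full
    table.  Rows whose simulation fails ascertainment are redrawn (with
    the redraw count recorded in ``meta``).
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenarios must be nonempty")
    lo, hi = row_range if row_range is not None else (0, n_per_scenario)
    records = []
    n_redraws = 0
    for s_idx, scen in enumerate(scenarios):
        for row in range(lo, hi):
            row_seed = _row_seed(seed, s_idx, row)
            rng = np.random.default_rng(row_seed)
            for attempt in range(100):
                p = sample_priors(prior, scen, 1, rng)[0]
                try:
                    gm = simulate_snps(
                        p, sc, int(rng.integers(1, 2**31 - 1)),
                        backend=backend, design=design)
                except RuntimeError:
                    n_redraws += 1
                    continue
                break
            else:
                raise RuntimeError(
                    f"scenario {scen}: 100 consecutive ascertainment "
                    "failures; check the priors")
            gA = gm.genotypes[:sc.n_A]
            gB = gm.genotypes[sc.n_A:]
            rec = {"scenario": scen}
            rec.update({c: getattr(p, c) for c in PARAM_COLUMNS})
            rec.update(dict(zip(STAT_NAMES, sumstats_from_dosages(gA, gB))))
            records.append(rec)
        if progress:
            print(f"  [{scen}] rows {lo}..{hi - 1} done")
    data = pd.DataFrame.from_records(records)
    meta = {
        "seed": seed, "n_per_scenario": n_per_scenario,
        "row_range": f"{lo}:{hi}", "scenarios": ",".join(scenarios),
        "n_A": sc.n_A, "n_B": sc.n_B, "n_snps": sc.n_snps,
        "maf_asc": sc.maf_asc, "missing_rate": sc.missing_rate,
        "n_loci": sc.n_loci, "mu_locus": sc.mu_locus,
        "backend": backend, "design": design, "n_redraws": n_redraws,
    }
    return ReferenceTable(data, meta)
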