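"""Synthetic pedigree and genotype generation with tracked identity-by-descent.

Two pedigree generators are provided:

* :func:`simulate_pedigree` -- a multi-flock, litter-based generator that
  emulates the structure of a national flock-book population (overlapping
  flocks, per-dam litters, sire progeny caps, optional between-flock ram
  migration, and an ``inbred_line`` scheme of repeated full-sib mating).
* :func:`simulate_wright_fisher_pedigree` -- an idealized discrete-generation
  random-mating population (multinomial family sizes, equal sex pools),
  used to validate effective-size and drift estimators against theory.

:func:`simulate_genotypes` drops genes down a pedigree: founder haplotypes
are drawn per locus from a Beta allele-frequency distribution, each meiosis
recombines under the Haldane (no-interference) map, and every allele
carries its founder-haplotype label. The per-animal fraction of loci where
the two homologs carry the same label is the *true autozygosity*, an exact
realized inbreeding coefficient against which the pedigree and genomic
estimators are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PedigreeError
from .genotypes import GenotypeDataset
from .pedigree import PedigreeTable


@dataclass
class SimConfig:
    """Parameters of the litter-based multi-flock pedigree generator."""
    n_founder_sires: int = 10
    n_founder_dams: int = 50
    n_generations: int = 5
    offspring_per_dam: int = 2
    sire_reuse_max: int = 50          # progeny cap per sire
    n_flocks: int = 4
    migration_rate: float = 0.1       # P(dam mated to a ram from another flock)
    mating_scheme: str = "random"     # random | circular | inbred_line
    birth_year_start: int = 2000
    generation_span_years: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founder_sires", "n_founder_dams", "offspring_per_dam",
                     "sire_reuse_max", "n_flocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.mating_scheme not in ("random", "circular", "inbred_line"):
            raise ValueError(f"unknown mating_scheme {self.mating_scheme!r}")


@dataclass
class GenomeConfig:
    """Genome and array parameters for gene dropping."""
    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    snps_per_chrom: int = 100
    cM_per_Mb: float = 1.0
    maf_beta: tuple[float, float] = (0.5, 0.5)   # founder MAF ~ Beta(a, b)
    maf_range: tuple[float, float] = (0.01, 0.5)
    missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.snps_per_chrom < 2:
            raise ValueError("snps_per_chrom must be >= 2")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for r in (self.missing_rate, self.genotyping_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SimTruth:
    """Founder-haplotype origins and realized autozygosity per animal.

    ``founder_origin`` has shape (n_animals, 2, n_loci); each entry labels
    the founder haplotype from which that allele descends.
    ``true_autozygosity`` is the per-animal fraction of loci at which the
    two homologs carry the same label (exactly 0 for founders).
    """
    ids: list[str]
    founder_origin: np.ndarray
    true_autozygosity: pd.Series = field(init=False)

    def __post_init__(self):
        eq = self.founder_origin[:, 0, :] == self.founder_origin[:, 1, :]
        self.true_autozygosity = pd.Series(eq.mean(axis=1), index=self.ids,
                                           name="true_autozygosity")

    def write_tsv(self, path) -> None:
        self.true_autozygosity.rename_axis("id").to_frame().to_csv(path, sep="\t")


def true_autozygosity(truth: SimTruth) -> pd.Series:
    """Per-animal fraction of loci identical by descent (same founder label)."""
    return truth.true_autozygosity


# ---------------------------------------------------------------------------
# Pedigree generators
# ---------------------------------------------------------------------------

def _make_frame(rows) -> PedigreeTable:
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex",
                                     "birth_year", "flock"])
    return PedigreeTable(df)


def simulate_pedigree(config: SimConfig) -> PedigreeTable:
    """Generate a multi-flock litter-based pedigree; see module docstring."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.mating_scheme == "inbred_line" and cfg.offspring_per_dam < 2:
        raise ValueError("inbred_line requires offspring_per_dam >= 2 "
                         "(a full-sib pair per litter)")

    rows = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"A{counter:06d}"

    jitter_ok = cfg.generation_span_years >= 3

    # founders, distributed round-robin over flocks
    males: dict[str, list[str]] = {str(f): [] for f in range(1, cfg.n_flocks + 1)}
    females: dict[str, list[str]] = {str(f): [] for f in range(1, cfg.n_flocks + 1)}
    flocks = sorted(males)
    for k in range(cfg.n_founder_sires):
        fid = flocks[k % cfg.n_flocks]
        a = new_id()
        males[fid].append(a)
        rows.append((a, None, None, "M", cfg.birth_year_start, fid))
    for k in range(cfg.n_founder_dams):
        fid = flocks[k % cfg.n_flocks]
        a = new_id()
        females[fid].append(a)
        rows.append((a, None, None, "F", cfg.birth_year_start, fid))

    # for the inbred_line scheme, one line per (sire, dam) founder pair
    lines: list[tuple[str, str, str]] = []   # (sire, dam, flock)
    if cfg.mating_scheme == "inbred_line":
        for fid in flocks:
            for s, d in zip(males[fid], females[fid]):
                lines.append((s, d, fid))
        if not lines:
            raise ValueError("inbred_line needs at least one founder pair "
                             "in some flock")

    for g in range(1, cfg.n_generations + 1):
        year0 = cfg.birth_year_start + g * cfg.generation_span_years
        new_males = {f: [] for f in flocks}
        new_females = {f: [] for f in flocks}

        if cfg.mating_scheme == "inbred_line":
            next_lines = []
            for s, d, fid in lines:
                kids = []
                for j in range(cfg.offspring_per_dam):
                    a = new_id()
                    sex = "M" if j % 2 == 0 else "F"
                    yr = year0 + (int(rng.integers(-1, 2)) if jitter_ok else 0)
                    rows.append((a, s, d, sex, yr, fid))
                    kids.append((a, sex))
                    (new_males if sex == "M" else new_females)[fid].append(a)
                son = next(a for a, sx in kids if sx == "M")
                dau = next(a for a, sx in kids if sx == "F")
                next_lines.append((son, dau, fid))
            lines = next_lines
        else:
            progeny_count: dict[str, int] = {}
            for fid in flocks:
                dams = females[fid]
                if not dams:
                    continue
                for di, dam in enumerate(dams):
                    # choose the ram pool (same flock, or migrant ram)
                    pool_flock = fid
                    if cfg.n_flocks > 1 and rng.random() < cfg.migration_rate:
                        others = [f for f in flocks if f != fid and males[f]]
                        if others:
                            pool_flock = others[int(rng.integers(len(others)))]
                    pool = males[pool_flock] or [s for f in flocks for s in males[f]]
                    if not pool:
                        raise ValueError("no sires available for mating")
                    open_pool = [s for s in pool
                                 if progeny_count.get(s, 0) +
                                 cfg.offspring_per_dam <= cfg.sire_reuse_max]
                    pool = open_pool or pool   # relax the cap if saturated
                    if cfg.mating_scheme == "circular":
                        sire = pool[di % len(pool)]
                    else:
                        sire = pool[int(rng.integers(len(pool)))]
                    for _ in range(cfg.offspring_per_dam):
                        a = new_id()
                        sex = "M" if rng.random() < 0.5 else "F"
                        yr = year0 + (int(rng.integers(-1, 2)) if jitter_ok else 0)
                        rows.append((a, sire, dam, sex, yr, fid))
                        progeny_count[sire] = progeny_count.get(sire, 0) + 1
                        (new_males if sex == "M" else new_females)[fid].append(a)
        males, females = new_males, new_females

    return _make_frame(rows)


def simulate_wright_fisher_pedigree(n_males: int, n_females: int,
                                    n_generations: int,
                                    n_offspring: int | None = None,
                                    birth_year_start: int = 2000,
                                    seed: int = 0,
                                    id_prefix: str = "A") -> PedigreeTable:
    """Idealized discrete-generation random-mating pedigree.

    Every offspring draws its sire uniformly (with replacement) from the
    previous generation's males and its dam from its females, giving
    multinomial family sizes: the realized effective size approximates
    4*Nm*Nf/(Nm+Nf).
    """
    rng = np.random.default_rng(seed)
    if n_offspring is None:
        n_offspring = n_males + n_females
    rows = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:06d}"

    males = [new_id() for _ in range(n_males)]
    females = [new_id() for _ in range(n_females)]
    for a in males:
        rows.append((a, None, None, "M", birth_year_start, "1"))
    for a in females:
        rows.append((a, None, None, "F", birth_year_start, "1"))

    for g in range(1, n_generations + 1):
        nm = n_offspring // 2
        new_m, new_f = [], []
        for j in range(n_offspring):
            a = new_id()
            sex = "M" if j < nm else "F"
            s = males[int(rng.integers(len(males)))]
            d = females[int(rng.integers(len(females)))]
            rows.append((a, s, d, sex, birth_year_start + g, "1"))
            (new_m if sex == "M" else new_f).append(a)
        males, females = new_m, new_f
        if not males or not females:
            raise ValueError("a generation ended up single-sexed; "
                             "increase n_offspring")
    return _make_frame(rows)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _founder_freqs(gcfg: GenomeConfig, n_loci: int, rng) -> np.ndarray:
    a, b = gcfg.maf_beta
    lo, hi = gcfg.maf_range
    p = np.empty(n_loci)
    need = np.ones(n_loci, dtype=bool)
    # rejection sampling of the truncated Beta
    while need.any():
        draw = rng.beta(a, b, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)
        p[idx[ok]] = draw[ok]
        need[idx[ok]] = False
    return p


def simulate_genotypes(ped: PedigreeTable, gcfg: GenomeConfig
                       ) -> tuple[GenotypeDataset, SimTruth]:
    """Drop genes down ``ped`` and return genotypes plus IBD truth.

    Founder haplotypes are independent across loci with allele-1 frequency
    drawn once per locus from the truncated Beta spectrum. Any animal with
    an unknown parent is treated as a genetic founder. Recombination
    follows the Haldane map (recombination fraction (1-exp(-2d))/2 over
    d Morgans). Genotyping errors flip one allele symmetrically and,
    together with missingness, are applied after the truth is recorded.
    """
    rng = np.random.default_rng(gcfg.seed)
    sex = ped.df["sex"].to_numpy()
    for i in range(ped.n_animals):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0 and sex[p] == "U":
                raise PedigreeError(
                    f"parent {ped.ids[p]} has unknown sex; cannot simulate")

    C = gcfg.n_chromosomes
    L = gcfg.snps_per_chrom
    n = ped.n_animals
    spacing = gcfg.chrom_length_bp / (L + 1)
    bp = np.round((np.arange(L) + 1) * spacing).astype(np.int64)
    bp = np.maximum.accumulate(bp + np.arange(L) * 0)  # already increasing
    d_morgan = np.diff(bp) / 1e6 * gcfg.cM_per_Mb / 100.0
    rec_frac = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))

    n_loci_total = C * L
    freqs = _founder_freqs(gcfg, n_loci_total, rng)

    alleles = np.zeros((n, 2, n_loci_total), dtype=np.int8)
    origin = np.zeros((n, 2, n_loci_total), dtype=np.int32)

    is_genetic_founder = (ped.sire_idx < 0) | (ped.dam_idx < 0)
    next_label = 1

    def meiosis(parent: int) -> tuple[np.ndarray, np.ndarray]:
        """One gamete from `parent`, concatenated across chromosomes."""
        gam_a = np.empty(n_loci_total, dtype=np.int8)
        gam_o = np.empty(n_loci_total, dtype=np.int32)
        for c in range(C):
            sl = slice(c * L, (c + 1) * L)
            cross = rng.random(L - 1) < rec_frac
            start = rng.integers(2)
            which = np.empty(L, dtype=np.int64)
            which[0] = start
            which[1:] = (start + np.cumsum(cross)) % 2
            ha = alleles[parent, :, sl]
            ho = origin[parent, :, sl]
            gam_a[sl] = ha[which, np.arange(L)]
            gam_o[sl] = ho[which, np.arange(L)]
        return gam_a, gam_o

    for i in range(n):
        if is_genetic_founder[i]:
            alleles[i, 0] = rng.random(n_loci_total) < freqs
            alleles[i, 1] = rng.random(n_loci_total) < freqs
            origin[i, 0] = next_label
            origin[i, 1] = next_label + 1
            next_label += 2
        else:
            alleles[i, 0], origin[i, 0] = meiosis(ped.sire_idx[i])
            alleles[i, 1], origin[i, 1] = meiosis(ped.dam_idx[i])

    truth = SimTruth(ids=ped.ids, founder_origin=origin)

    geno = (alleles[:, 0, :].astype(np.int8) + alleles[:, 1, :]).astype(np.int8)

    if gcfg.genotyping_error_rate > 0:
        err = rng.random(geno.shape) < gcfg.genotyping_error_rate
        if err.any():
            up = rng.random(geno.shape) < 0.5  # which allele flips a het
            g = geno.copy()
            g[err & (geno == 0)] = 1
            g[err & (geno == 2)] = 1
            g[err & (geno == 1) & up] = 2
            g[err & (geno == 1) & ~up] = 0
            geno = g
    if gcfg.missing_rate > 0:
        miss = rng.random(geno.shape) < gcfg.missing_rate
        geno[miss] = -1

    markers = pd.DataFrame({
        "chrom": np.repeat(np.arange(1, C + 1), L),
        "snp_id": [f"snp{c}_{j}" for c in range(1, C + 1) for j in range(1, L + 1)],
        "cM": np.tile(bp / 1e6 * gcfg.cM_per_Mb, C),
        "bp": np.tile(bp, C),
        "a1": "A",
        "a2": "B",
    })
    samples = ped.df[["id", "sex", "birth_year", "flock"]].copy().reset_index(drop=True)
    gd = GenotypeDataset(samples=samples, markers=markers, geno=geno)
    return gd, truth
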