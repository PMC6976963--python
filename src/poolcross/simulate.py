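"""Forward simulation of the cross/selection design and pooled capture sequencing.

The design: virgin females of a multi-resistant composite founder population
(F0) are exposed to an LD80 dose of one of three insecticides; 100 surviving
females are mass-crossed with 100 susceptible males; F1 reproduce freely; F2
females are exposed to LD25 and LD75 doses of the same insecticide. Thirteen
pools of 100 females (shared F0 plus four stages per line) are sequenced by
targeted capture.

Phenotype model: an individual's log10-tolerance is Normal(mu0 + sum of
allelic effects, sigma); it survives a dose d when its tolerance exceeds
log10 d, so P(survive) = Phi((mu0 + sum(beta*g) - log10 d) / sigma) — the
individual-level counterpart of the probit dose-mortality curves used to
calibrate LD doses in bioassays. Effects are additive across loci by
default (dominance h = 0.5, configurable).

Gene amplifications segregate as single Mendelian alleles carrying a fixed
number of gene copies k >= 2, so an individual with allele dosage g has
copy number 2 + g*(k - 1); capture coverage scales with the pool mean copy
number (gene-dosage effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .conditions import (
    ALL_LABELS,
    Condition,
    Line,
    SELECTED_LINES,
    Stage,
    line_conditions,
)
from .tables import AlleleCountTable, CoverageTable, Effect, GeneAnnotation, GeneFamily

SNP = "snp"
CNV_GENE = "cnv_gene"


@dataclass
class LocusSpec:
    """Ground-truth specification of one simulated locus.

    ``beta`` maps an insecticide line to the shift of log10-tolerance per
    allele copy. For ``cnv_gene`` loci the segregating allele is a gene
    amplification of ``cnv_copies`` tandem copies.
    """

    chrom: str
    pos: int  # 0-based
    locus_class: str = SNP
    founder_freq: float = 0.0
    susceptible_freq: float = 0.0
    beta: dict[Line, float] = field(default_factory=dict)
    cnv_copies: int = 2
    effect: Effect = Effect.UNKNOWN
    ref: str = "A"
    alt: str = "T"
    gene_id: str | None = None
    #: loci sharing a haplotype_group segregate on one founder haplotype
    #: (e.g. co-occurring target-site mutations); they must share founder_freq
    haplotype_group: str | None = None
    #: recombination fraction to the previous locus in the list (same
    #: chromosome only); None falls back to the config-wide fraction
    recomb_to_prev: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.founder_freq <= 1 and 0 <= self.susceptible_freq <= 1):
            raise ValueError(f"{self.chrom}:{self.pos}: frequencies must lie in [0,1]")
        if any(not np.isfinite(b) for b in self.beta.values()):
            raise ValueError(f"{self.chrom}:{self.pos}: beta must be finite")
        if self.locus_class == CNV_GENE and self.cnv_copies < 2:
            raise ValueError(f"{self.chrom}:{self.pos}: cnv_copies must be >= 2")

    def beta_for(self, line: Line) -> float:
        return self.beta.get(line, 0.0)

    @property
    def causal_line(self) -> Line | None:
        for line, b in self.beta.items():
            if b != 0:
                return line
        return None


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated experiment.

    Defaults mirror the design: pools of 100 females, 100 survivor females
    crossed with 100 susceptible males, ~100x sequencing depth. Census sizes
    of the unstated F1/F2 generations default to 2,000.
    """

    pool_size: int = 100
    n_cross: int = 100
    f0_census: int = 4000
    f1_census: int = 2000
    f2_census: int = 2000
    mu0: float = 0.0
    sigma: float = 0.15
    dominance: float = 0.5
    recomb_fraction: float = 0.5  # between adjacent same-chromosome loci
    depth_mean: float = 100.0
    depth_dispersion: float = 30.0
    error_rate: float = 0.001
    coverage_mean: float = 100.0
    coverage_dispersion: float = 400.0  # residual capture noise of region means
    read_length: float = 75.0
    library_sigma: float = 0.10
    region_sigma: float = 0.15
    exons_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pool_size", "n_cross", "f0_census", "f1_census", "f2_census"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recomb_fraction must lie in [0, 0.5]")


@dataclass
class Population:
    """Diploid individuals: haplotype array (n, L, 2) of 0/1 alleles."""

    haplotypes: np.ndarray
    female: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n, L, 2)")
        if self.female.shape[0] != self.haplotypes.shape[0]:
            raise ValueError("female flags must match individuals")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=2, dtype=np.int16)

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 2))

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(self.haplotypes[idx], self.female[idx])

    def females(self) -> "Population":
        return self.subset(np.flatnonzero(self.female))

    def males(self) -> "Population":
        return self.subset(np.flatnonzero(~self.female))


@dataclass
class ToleranceModel:
    """Probit liability model of insecticide tolerance for one line."""

    betas: np.ndarray
    mu0: float = 0.0
    sigma: float = 0.15
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def for_line(cls, loci: list[LocusSpec], line: Line, config: SimConfig) -> "ToleranceModel":
        betas = np.array([l.beta_for(line) for l in loci], dtype=float)
        return cls(betas=betas, mu0=config.mu0, sigma=config.sigma, dominance=config.dominance)

    def tolerance(self, dosage: np.ndarray) -> np.ndarray:
        """Mean log10-tolerance per individual from allele dosages (n, L)."""
        h = self.dominance
        # genotype values 0 / 2h / 2 per locus, times beta
        value = np.where(dosage == 1, 2 * h, dosage.astype(float))
        return self.mu0 + value @ self.betas

    def survival(self, dosage: np.ndarray, dose: float) -> np.ndarray:
        if dose <= 0:
            raise ValueError("dose must be positive")
        return norm.cdf((self.tolerance(dosage) - np.log10(dose)) / self.sigma)


def survival_probability(
    dosage: np.ndarray, dose: float, model: ToleranceModel
) -> np.ndarray:
    """P(survive dose) for allele-dosage rows; vectorized over individuals."""
    dosage = np.atleast_2d(dosage)
    return model.survival(dosage, dose)


def find_ld(pop: Population, model: ToleranceModel, mortality: float) -> float:
    """Dose at which expected population mortality equals ``mortality``.

    Monotone root-finding on log10 dose; mortality strictly increases with
    dose, so the bracket spans the tolerance range +/- 10 sigma.
    """
    if not 0 < mortality < 1:
        raise ValueError("target mortality must lie in (0, 1)")
    t = model.tolerance(pop.dosage())

    def excess(y: float) -> float:
        return float(np.mean(norm.cdf((y - t) / model.sigma))) - mortality

    lo = float(t.min() - 10 * model.sigma)
    hi = float(t.max() + 10 * model.sigma)
    if excess(lo) > 0 or excess(hi) < 0:
        raise RuntimeError("target mortality unattainable within dose bracket")
    y = brentq(excess, lo, hi, xtol=1e-9)
    return float(10**y)


def select_survivors(
    pop: Population, dose: float, model: ToleranceModel, rng: np.random.Generator
) -> Population:
    """Expose a cohort: each individual survives independently with its
    probit survival probability."""
    p = model.survival(pop.dosage(), dose)
    alive = rng.random(pop.n) < p
    if not alive.any():
        raise RuntimeError(
            "no survivors at this dose; increase the census size or lower the dose"
        )
    return pop.subset(np.flatnonzero(alive))


def _recomb_vector(loci: list[LocusSpec], r: float) -> np.ndarray:
    """Recombination fraction between adjacent loci (0.5 across chromosomes)."""
    rvec = np.full(len(loci), 0.5)
    for i in range(1, len(loci)):
        if loci[i].chrom == loci[i - 1].chrom:
            ri = loci[i].recomb_to_prev
            rvec[i] = r if ri is None else ri
    return rvec


def _gametes(
    pop: Population, parent_idx: np.ndarray, rvec: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per chosen parent, with crossovers at the given fractions."""
    n, L = parent_idx.shape[0], pop.haplotypes.shape[1]
    switch = rng.random((n, L)) < rvec
    switch[:, 0] = rng.random(n) < 0.5
    which = np.cumsum(switch, axis=1) % 2
    return pop.haplotypes[parent_idx[:, None], np.arange(L)[None, :], which]


def cross(
    mothers: Population,
    fathers: Population,
    n_offspring: int,
    loci: list[LocusSpec],
    rng: np.random.Generator,
    recomb_fraction: float = 0.5,
) -> Population:
    """Mendelian cross: each offspring draws a random mother and father and
    one recombinant gamete from each."""
    if mothers.n == 0 or fathers.n == 0:
        raise ValueError("both parent sets must be non-empty")
    rvec = _recomb_vector(loci, recomb_fraction)
    mi = rng.integers(0, mothers.n, n_offspring)
    fi = rng.integers(0, fathers.n, n_offspring)
    hap = np.stack(
        [_gametes(mothers, mi, rvec, rng), _gametes(fathers, fi, rvec, rng)], axis=2
    )
    female = rng.random(n_offspring) < 0.5
    return Population(hap.astype(np.uint8), female)


def _draw_haplotypes(
    n: int, loci: list[LocusSpec], freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-haplotype allele draws; loci in a haplotype_group co-occur
    (perfect founder linkage disequilibrium), others are independent."""
    hap = (rng.random((n, len(loci), 2)) < freqs[None, :, None]).astype(np.uint8)
    groups: dict[str, list[int]] = {}
    for i, l in enumerate(loci):
        if l.haplotype_group:
            groups.setdefault(l.haplotype_group, []).append(i)
    for name, idx in groups.items():
        f = {float(freqs[i]) for i in idx}
        if len(f) > 1:
            raise ValueError(f"haplotype group {name!r} mixes frequencies")
        carrier = rng.random((n, 1, 2)) < freqs[idx[0]]
        hap[:, idx, :] = carrier.astype(np.uint8)
    return hap


def simulate_founders(
    config: SimConfig, loci: list[LocusSpec], rng: np.random.Generator
) -> Population:
    """Founder composite population: Hardy-Weinberg at each locus, linkage
    equilibrium between loci except within haplotype groups."""
    freqs = np.array([l.founder_freq for l in loci])
    hap = _draw_haplotypes(config.f0_census, loci, freqs, rng)
    female = np.zeros(config.f0_census, dtype=bool)
    female[: config.f0_census // 2] = True
    return Population(hap, female)


def susceptible_strain(
    n: int, loci: list[LocusSpec], rng: np.random.Generator, female: bool = False
) -> Population:
    freqs = np.array([l.susceptible_freq for l in loci])
    hap = _draw_haplotypes(n, loci, freqs, rng)
    return Population(hap, np.full(n, female))


@dataclass
class DesignResult:
    """The 13 sequenced pools plus ground truth of the simulated experiment."""

    loci: list[LocusSpec]
    config: SimConfig
    pools: dict[str, np.ndarray]  # condition label -> dosage matrix (pool, L)
    doses: dict[str, float]  # "<line>_<stage>" exposure doses
    truth: pd.DataFrame  # per locus: class, betas, true pool frequencies

    def pool_freq(self, label: str) -> np.ndarray:
        return self.pools[label].mean(axis=0) / 2.0

    def pool_copy_number(self, label: str) -> np.ndarray:
        """Mean diploid copy number per locus (2 + g*(k-1) for cnv genes)."""
        k = np.array(
            [l.cnv_copies if l.locus_class == CNV_GENE else 2 for l in self.loci]
        )
        g = self.pools[label]
        return (2 + g * (k - 1)[None, :]).mean(axis=0).astype(float)


def _sample_pool(
    pop: Population, size: int, rng: np.random.Generator
) -> np.ndarray:
    if pop.n < size:
        raise RuntimeError(
            f"pool of {size} requested but only {pop.n} individuals available"
        )
    idx = rng.choice(pop.n, size=size, replace=False)
    return pop.dosage()[idx]


def run_design(loci: list[LocusSpec], config: SimConfig) -> DesignResult:
    """Execute the full design: F0 -> LD80 selection -> cross with the
    susceptible strain -> free F1 mating -> F2 -> LD25/LD75 selections per
    line; sample the 13 pools of 100 females and record ground truth."""
    root = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(root))

    founders = simulate_founders(config, loci, rng)
    pools: dict[str, np.ndarray] = {}
    doses: dict[str, float] = {}
    pools["F0"] = _sample_pool(founders.females(), config.pool_size, rng)

    for line in SELECTED_LINES:
        model = ToleranceModel.for_line(loci, line, config)
        f0_females = founders.females()
        d80 = find_ld(f0_females, model, 0.80)
        doses[f"{line.value}_F0_LD80"] = d80
        survivors = select_survivors(f0_females, d80, model, rng)
        if survivors.n < config.n_cross:
            raise RuntimeError(
                f"{line.value}: only {survivors.n} LD80 survivors for "
                f"{config.n_cross} crosses; increase f0_census"
            )
        if config.pool_size > config.n_cross:
            raise RuntimeError("pool_size exceeds the number of crossed survivors")
        midx = rng.choice(survivors.n, size=config.n_cross, replace=False)
        mothers = survivors.subset(midx)
        pool_idx = (
            rng.choice(config.n_cross, size=config.pool_size, replace=False)
            if config.n_cross > config.pool_size
            else np.arange(config.pool_size)
        )
        pools[Condition(line, Stage.F0_LD80).label] = mothers.dosage()[pool_idx]

        fathers = susceptible_strain(config.n_cross, loci, rng, female=False)
        f1 = cross(mothers, fathers, config.f1_census, loci, rng, config.recomb_fraction)
        f2 = cross(
            f1.females(), f1.males(), config.f2_census, loci, rng, config.recomb_fraction
        )
        f2_females = f2.females()
        pools[Condition(line, Stage.F2).label] = _sample_pool(
            f2_females, config.pool_size, rng
        )
        for stage, mort in ((Stage.F2_LD25, 0.25), (Stage.F2_LD75, 0.75)):
            dose = find_ld(f2_females, model, mort)
            doses[f"{line.value}_{stage.value}"] = dose
            surv = select_survivors(f2_females, dose, model, rng)
            pools[Condition(line, stage).label] = _sample_pool(
                surv, config.pool_size, rng
            )

    truth = _truth_table(loci, pools)
    return DesignResult(loci=loci, config=config, pools=pools, doses=doses, truth=truth)


def _truth_table(loci: list[LocusSpec], pools: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for i, locus in enumerate(loci):
        row: dict[str, object] = {
            "chrom": locus.chrom,
            "pos": locus.pos,
            "locus_class": locus.locus_class,
            "gene_id": locus.gene_id or "",
            "causal_line": locus.causal_line.value if locus.causal_line else "none",
        }
        for line in SELECTED_LINES:
            row[f"beta_{line.value}"] = locus.beta_for(line)
        for label in ALL_LABELS:
            row[f"freq_{label}"] = pools[label][:, i].mean() / 2.0
        rows.append(row)
    return pd.DataFrame(rows)


def _negbin(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative binomial draws with var = mean + mean^2/dispersion."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(
    design: DesignResult, rng: np.random.Generator | None = None
) -> AlleleCountTable:
    """Pooled read counts at SNP loci: depth ~ NegBin(mean, dispersion),
    alt reads ~ Binomial(depth, f') with f' = f(1-e) + (1-f)e."""
    config = design.config
    if rng is None:
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, 1]))
        )
    snp_idx = [i for i, l in enumerate(design.loci) if l.locus_class == SNP]
    loci = [design.loci[i] for i in snp_idx]
    data: dict[str, object] = {
        "chrom": [l.chrom for l in loci],
        "pos": [l.pos for l in loci],
        "ref": [l.ref for l in loci],
        "alt": [l.alt for l in loci],
        "effect": [l.effect.value for l in loci],
    }
    e = config.error_rate
    for label in ALL_LABELS:
        f = design.pool_freq(label)[snp_idx]
        depth = _negbin(
            np.full(len(loci), config.depth_mean), config.depth_dispersion, rng
        )
        alt = rng.binomial(depth, f * (1 - e) + (1 - f) * e)
        data[f"{label}:ref"] = depth - alt
        data[f"{label}:alt"] = alt
    return AlleleCountTable(pd.DataFrame(data))


def build_gene_panel(
    loci: list[LocusSpec], rng: np.random.Generator | None = None, seed: int = 0
) -> tuple[pd.DataFrame, list[GeneAnnotation]]:
    """Exon regions and annotations for the cnv_gene loci of a scenario.

    Each gene receives three exons of 60-400 bp near its locus position;
    the gene span covers its exons.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 2])))
    regions = []
    genes = []
    # host gene annotations for genic SNPs (one gene per gene_id, spanning
    # all of its SNPs; no coverage regions)
    hosts: dict[str, list[LocusSpec]] = {}
    for locus in loci:
        if locus.locus_class == SNP and locus.gene_id:
            hosts.setdefault(locus.gene_id, []).append(locus)
    for gid, members in hosts.items():
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                name=gid,
                family=GeneFamily.TARGET
                if any(m.causal_line for m in members)
                else GeneFamily.OTHER,
                chrom=members[0].chrom,
                start=max(0, min(m.pos for m in members) - 2000),
                end=max(m.pos for m in members) + 2000,
            )
        )
    for locus in loci:
        if locus.locus_class != CNV_GENE:
            continue
        gid = locus.gene_id or f"gene_{locus.chrom}_{locus.pos}"
        start = locus.pos
        cursor = start
        for e in range(3):
            length = int(rng.integers(60, 401))
            regions.append(
                {
                    "region_id": f"{gid}_ex{e + 1}",
                    "chrom": locus.chrom,
                    "start": cursor,
                    "end": cursor + length,
                    "kind": "exon",
                    "gene_id": gid,
                    "length": length,
                }
            )
            cursor += length + int(rng.integers(50, 500))
        family = GeneFamily.P450 if locus.causal_line else GeneFamily.OTHER
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                name=gid,
                family=family,
                chrom=locus.chrom,
                start=start,
                end=cursor,
            )
        )
    return pd.DataFrame(regions), genes


def simulate_coverage(
    design: DesignResult,
    regions: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> CoverageTable:
    """Capture coverage over exon regions with a gene-dosage effect.

    The read count over a region is NegBin with mean proportional to
    library factor x region capture factor x (pool mean copy number / 2);
    mean depth (reads/bp) is the read count scaled by read length over
    region length. Region capture factors are shared across samples, so the
    common-reference normalization removes them.
    """
    config = design.config
    if rng is None:
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, 3]))
        )
    gene_of_locus = {
        l.gene_id: i for i, l in enumerate(design.loci) if l.locus_class == CNV_GENE
    }
    lib_factor = {
        label: float(np.exp(rng.normal(0.0, config.library_sigma)))
        for label in ALL_LABELS
    }
    region_factor = np.exp(rng.normal(0.0, config.region_sigma, size=len(regions)))
    lengths = regions["length"].to_numpy(dtype=float)

    depth = pd.DataFrame(index=pd.Index(regions["region_id"], name="region_id"))
    copy_cache = {label: design.pool_copy_number(label) for label in ALL_LABELS}
    gene_idx = regions["gene_id"].map(gene_of_locus).to_numpy()
    for label in ALL_LABELS:
        copy = copy_cache[label][gene_idx]
        mean_depth = (
            config.coverage_mean * lib_factor[label] * region_factor * copy / 2.0
        )
        mean_reads = mean_depth * lengths / config.read_length
        reads = _negbin(mean_reads, config.coverage_dispersion, rng)
        depth[label] = reads * config.read_length / lengths

    library_sizes = {
        label: int(round((depth[label].to_numpy() * lengths).sum() / config.read_length))
        for label in ALL_LABELS
    }
    return CoverageTable(
        regions=regions.copy(), depth=depth, library_sizes=library_sizes
    )


def simulate_experiment(
    loci: list[LocusSpec], config: SimConfig
) -> tuple[DesignResult, AlleleCountTable, CoverageTable]:
    """Run the full design and sequencing with independent seeded streams."""
    design = run_design(loci, config)
    counts = simulate_counts(design)
    regions, _ = build_gene_panel(loci, seed=config.seed)
    coverage = (
        simulate_coverage(design, regions)
        if len(regions)
        else CoverageTable(
            regions=pd.DataFrame(
                columns=["region_id", "chrom", "start", "end", "kind", "gene_id", "length"]
            ),
            depth=pd.DataFrame(columns=list(ALL_LABELS)),
            library_sizes={lbl: 1 for lbl in ALL_LABELS},
        )
    )
    return design, counts, coverage
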