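"""Canonical synthetic scenarios mirroring the study conditions.

The default scenario places a handful of causal resistance loci — SNPs whose
alleles shift the LD50 about 3-fold per copy, and amplified detoxification
genes carrying a 3-copy allele — among thousands of neutral SNPs and a
couple of hundred neutral genes, then runs the full cross/selection design
with pools of 100 females at ~100x depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditions import Line, SELECTED_LINES
from .simulate import CNV_GENE, SNP, LocusSpec
from .tables import Effect

#: log10-tolerance shift per allele copy giving a ~3-fold LD50 shift
THREEFOLD_BETA = math.log10(3.0)

#: effect of an amplification allele (~10-fold LD50 shift): strong metabolic
#: resistance driven by gene dosage, as seen for amplified P450/CCE clusters
CNV_BETA = 1.0

_CHROMS = ("chr1", "chr2", "chr3")


def study_loci(
    n_neutral_snps: int = 5000,
    n_causal_snps: int = 10,
    n_neutral_genes: int = 200,
    n_causal_genes: int = 5,
    causal_snp_freq: float = 0.4,
    causal_gene_freq: float = 0.3,
    causal_snp_beta: float = THREEFOLD_BETA,
    causal_gene_beta: float = CNV_BETA,
    cnv_copies: int = 3,
    neutral_freq_range: tuple[float, float] = (0.05, 0.95),
    snp_spacing: int = 25_000,
    seed: int = 0,
) -> list[LocusSpec]:
    """Build the locus list of a study-like scenario.

    Causal loci are assigned to the three insecticide lines round-robin.
    Neutral SNP founder frequencies are uniform over ``neutral_freq_range``;
    neutral genes carry no segregating amplification. Loci are laid out on
    three chromosomes at fixed spacing; each causal SNP sits inside a host
    candidate gene so that selection regions can anchor to annotation.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 17])))
    loci: list[LocusSpec] = []
    cursors = {c: 100_000 for c in _CHROMS}

    def place(chrom_i: int, advance: int) -> tuple[str, int]:
        chrom = _CHROMS[chrom_i % len(_CHROMS)]
        pos = cursors[chrom]
        cursors[chrom] += advance
        return chrom, pos

    # Each line's causal SNPs form one tightly linked cluster segregating on
    # a single resistant founder haplotype, emulating co-occurring resistance
    # mutations in a gene or gene cluster under selection.
    per_line = [
        n_causal_snps // 3 + (1 if i < n_causal_snps % 3 else 0) for i in range(3)
    ]
    for li, line in enumerate(SELECTED_LINES):
        chrom = _CHROMS[li]
        for j in range(per_line[li]):
            pos = cursors[chrom]
            cursors[chrom] += 1_000 if j < per_line[li] - 1 else snp_spacing
            loci.append(
                LocusSpec(
                    chrom=chrom,
                    pos=pos,
                    locus_class=SNP,
                    founder_freq=causal_snp_freq,
                    beta={line: causal_snp_beta},
                    effect=Effect.NONSYNONYMOUS,
                    gene_id=f"host_{line.value}",
                    haplotype_group=f"res_{line.value}",
                    recomb_to_prev=0.0 if j > 0 else None,
                )
            )

    neutral_effects = (
        Effect.INTERGENIC,
        Effect.SYNONYMOUS,
        Effect.INTERGENIC,
        Effect.UPSTREAM,
    )
    freqs = rng.uniform(*neutral_freq_range, size=n_neutral_snps)
    for i in range(n_neutral_snps):
        chrom, pos = place(i, snp_spacing)
        loci.append(
            LocusSpec(
                chrom=chrom,
                pos=pos,
                locus_class=SNP,
                founder_freq=float(freqs[i]),
                effect=neutral_effects[i % len(neutral_effects)],
            )
        )

    # Causal amplified genes: each line's genes form one co-amplified
    # cluster segregating on a single founder haplotype (tandem-duplicated
    # detoxification gene clusters co-amplify in the field).
    genes_per_line = [
        n_causal_genes // 3 + (1 if i < n_causal_genes % 3 else 0) for i in range(3)
    ]
    for li, line in enumerate(SELECTED_LINES):
        chrom = _CHROMS[li]
        for j in range(genes_per_line[li]):
            pos = cursors[chrom]
            cursors[chrom] += 5_000 if j < genes_per_line[li] - 1 else 60_000
            loci.append(
                LocusSpec(
                    chrom=chrom,
                    pos=pos,
                    locus_class=CNV_GENE,
                    founder_freq=causal_gene_freq,
                    beta={line: causal_gene_beta},
                    cnv_copies=cnv_copies,
                    gene_id=f"cyp_amp_{line.value}_{j}",
                    haplotype_group=f"amp_{line.value}",
                    recomb_to_prev=0.0 if j > 0 else None,
                )
            )
    for i in range(n_neutral_genes):
        chrom, pos = place(i, 60_000)
        loci.append(
            LocusSpec(
                chrom=chrom,
                pos=pos,
                locus_class=CNV_GENE,
                founder_freq=0.0,
                cnv_copies=2,
                gene_id=f"gene_{i:04d}",
            )
        )
    return loci


@dataclass
class ScenarioSpec:
    """Serializable scenario sizes for the pipeline entry points."""

    n_neutral_snps: int = 400
    n_causal_snps: int = 10
    n_neutral_genes: int = 200
    n_causal_genes: int = 5
    causal_snp_freq: float = 0.4
    causal_gene_freq: float = 0.3
    causal_snp_beta: float = THREEFOLD_BETA
    causal_gene_beta: float = CNV_BETA
    cnv_copies: int = 3

    def build(self, seed: int = 0) -> list[LocusSpec]:
        return study_loci(
            n_neutral_snps=self.n_neutral_snps,
            n_causal_snps=self.n_causal_snps,
            n_neutral_genes=self.n_neutral_genes,
            n_causal_genes=self.n_causal_genes,
            causal_snp_freq=self.causal_snp_freq,
            causal_gene_freq=self.causal_gene_freq,
            causal_snp_beta=self.causal_snp_beta,
            causal_gene_beta=self.causal_gene_beta,
            cnv_copies=self.cnv_copies,
            seed=seed,
        )


def neutral_loci(n_snps: int = 1000, seed: int = 0, **kwargs) -> list[LocusSpec]:
    """A no-selection scenario: every locus has beta = 0."""
    return study_loci(
        n_neutral_snps=n_snps,
        n_causal_snps=0,
        n_neutral_genes=kwargs.pop("n_neutral_genes", 50),
        n_causal_genes=0,
        seed=seed,
        **kwargs,
    )
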