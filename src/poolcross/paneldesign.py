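"""Design of intergenic capture targets spread evenly over a genome.

Regions of exactly 220 bp are placed greedily left-to-right on each
contig, aiming for 150 kb between consecutive regions with a +/- 10 kb
search window, preferring the position closest to the ideal. A candidate
is rejected when it lies within 5 kb of an annotated gene, exceeds 70% GC
or 50% of a single nucleotide, contains an N, or sits within 75.5 kb of a
contig end; contigs shorter than 150 kb are skipped entirely. When no
position in the window passes, the slot is skipped and the next ideal
advances by 150 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .tables import GeneAnnotation, RegionKind, TargetRegion


@dataclass
class PanelDesignSpec:
    region_size: int = 220
    ideal_spacing: int = 150_000
    spacing_tol: int = 10_000
    min_gene_distance: int = 5_000
    max_gc: float = 0.70
    max_single_nt: float = 0.50
    min_contig: int = 150_000
    edge_margin: int = 75_500
    search_step: int = 1


def _load_genome(genome) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        return {name: str(fa[name][:]) for name in fa.keys()}
    return genome


class _SeqIndex:
    """O(1) window composition via cumulative base counts."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        self.n = len(arr)
        self.cum = {
            base: np.concatenate([[0], np.cumsum(arr == ord(base))])
            for base in "ACGTN"
        }

    def counts(self, start: int, end: int) -> dict[str, int]:
        return {b: int(c[end] - c[start]) for b, c in self.cum.items()}


def design_intergenic_targets(
    genome,
    genes: list[GeneAnnotation],
    spec: PanelDesignSpec | None = None,
) -> list[TargetRegion]:
    """Greedy placement of 220 bp intergenic regions every ~150 kb.

    ``genome`` is a FASTA path or a mapping contig -> sequence; ``genes``
    provides spans to keep clear of. Contigs named by the annotation but
    absent from the genome are a fatal mismatch.
    """
    spec = spec or PanelDesignSpec()
    seqs = _load_genome(genome)
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.chrom not in seqs:
            raise ValueError(f"annotation contig {g.chrom!r} absent from genome")
        by_contig.setdefault(g.chrom, []).append(g)

    offsets = sorted(
        range(-spec.spacing_tol, spec.spacing_tol + 1, spec.search_step),
        key=lambda d: (abs(d), d),
    )

    regions: list[TargetRegion] = []
    for contig in seqs:
        seq = seqs[contig]
        n = len(seq)
        if n < spec.min_contig:
            continue
        index = _SeqIndex(seq)
        contig_genes = by_contig.get(contig, [])
        last_start = spec.edge_margin - spec.region_size  # region ends before limit
        max_start = n - spec.edge_margin - spec.region_size

        def acceptable(s: int) -> bool:
            if s < spec.edge_margin or s > max_start:
                return False
            e = s + spec.region_size
            counts = index.counts(s, e)
            if counts["N"] > 0:
                return False
            size = spec.region_size
            if (counts["G"] + counts["C"]) / size > spec.max_gc:
                return False
            if max(counts[b] for b in "ACGT") / size > spec.max_single_nt:
                return False
            for g in contig_genes:
                # too close unless the gap to the gene span exceeds 5 kb
                if (g.start - e) <= spec.min_gene_distance and (
                    s - g.end
                ) <= spec.min_gene_distance:
                    return False
            return True

        ideal = spec.edge_margin
        k = 0
        while ideal <= max_start + spec.spacing_tol:
            placed = None
            for d in offsets:
                s = ideal + d
                if acceptable(s):
                    placed = s
                    break
            if placed is not None:
                k += 1
                regions.append(
                    TargetRegion(
                        region_id=f"{contig}_ig{k:05d}",
                        chrom=contig,
                        start=placed,
                        end=placed + spec.region_size,
                        kind=RegionKind.INTERGENIC,
                    )
                )
                ideal = placed + spec.ideal_spacing
            else:
                ideal += spec.ideal_spacing
    return regions
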