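"""Readers and writers for the pipeline's tabular formats.

Counts and coverage travel as TSV with one pair (or one) of columns per
condition label; a minimal VCF with per-sample AD fields is also accepted
for counts. External positions are 1-based (TSV/VCF) and converted to the
internal 0-based convention; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import ALL_LABELS
from .tables import AlleleCountTable, CoverageTable, GeneAnnotation, frame_to_genes, genes_to_frame

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def read_counts(path: str | Path) -> AlleleCountTable:
    """Read an allele-count table from TSV or minimal VCF.

    TSV columns: ``chrom pos ref alt effect`` then ``<label>:ref``
    ``<label>:alt`` for all 13 condition labels; ``pos`` 1-based.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_counts_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for label in ALL_LABELS:
        for suffix in ("ref", "alt"):
            if f"{label}:{suffix}" not in df.columns:
                raise ValueError(
                    f"{path}: missing count column for condition {label!r}"
                )
    if len(df):
        df["pos"] = df["pos"].astype(np.int64) - 1
    else:
        df["pos"] = df["pos"].astype(np.int64)
    if "effect" not in df.columns:
        df["effect"] = "unknown"
    return AlleleCountTable(df)


def write_counts(counts: AlleleCountTable, path: str | Path) -> None:
    df = counts.df.copy()
    df["pos"] = df["pos"] + 1  # back to 1-based
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_counts_vcf(path: Path) -> AlleleCountTable:
    """Minimal VCF: 13 samples named by condition label, AD per sample.

    Multi-allelic records keep the two alleles with the most supporting
    reads summed over conditions (logged)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [lbl for lbl in ALL_LABELS if lbl not in samples]
    if missing:
        raise ValueError(f"{path}: VCF missing sample(s) {', '.join(missing)}")
    col = {lbl: samples.index(lbl) for lbl in ALL_LABELS}
    rows: dict[str, list] = {c: [] for c in ("chrom", "pos", "ref", "alt", "effect")}
    counts_cols: dict[str, list] = {
        f"{lbl}:{sfx}": [] for lbl in ALL_LABELS for sfx in ("ref", "alt")
    }
    for rec in vcf:
        ad = np.asarray(rec.format("AD"), dtype=np.int64)
        ad = np.maximum(ad, 0)  # missing AD encoded negative
        alleles = [rec.REF] + list(rec.ALT)
        if len(alleles) > 2:
            totals = ad.sum(axis=0)
            top = np.argsort(-totals, kind="mergesort")[:2]
            top = np.sort(top)
            logger.warning(
                "%s:%d multi-allelic; keeping alleles %s",
                rec.CHROM,
                rec.POS,
                [alleles[i] for i in top],
            )
        else:
            top = np.array([0, 1])
        rows["chrom"].append(rec.CHROM)
        rows["pos"].append(rec.POS - 1)
        rows["ref"].append(alleles[top[0]])
        rows["alt"].append(alleles[top[1]])
        rows["effect"].append("unknown")
        for lbl in ALL_LABELS:
            counts_cols[f"{lbl}:ref"].append(int(ad[col[lbl], top[0]]))
            counts_cols[f"{lbl}:alt"].append(int(ad[col[lbl], top[1]]))
    return AlleleCountTable(pd.DataFrame({**rows, **counts_cols}))


def read_coverage(path: str | Path) -> CoverageTable:
    """Coverage TSV: region metadata columns then one depth column per label;
    library sizes on a leading comment line ``#library_sizes label=size ...``."""
    path = Path(path)
    lib_sizes: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#library_sizes"):
        for tok in first.split()[1:]:
            lbl, _, size = tok.partition("=")
            lib_sizes[lbl] = int(size)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    meta_cols = ["region_id", "chrom", "start", "end", "kind", "gene_id", "length"]
    regions = df[[c for c in meta_cols if c in df.columns]].copy()
    if "length" not in regions.columns:
        regions["length"] = regions["end"] - regions["start"]
    depth = df.set_index("region_id")[list(ALL_LABELS)]
    return CoverageTable(regions=regions, depth=depth, library_sizes=lib_sizes)


def write_coverage(cov: CoverageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if cov.library_sizes:
            libs = " ".join(f"{k}={v}" for k, v in cov.library_sizes.items())
            fh.write(f"#library_sizes {libs}\n")
        df = cov.regions.merge(
            cov.depth.reset_index(), on="region_id", how="right"
        )
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    return frame_to_genes(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_genes(genes: list[GeneAnnotation], path: str | Path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write chrom/start/end (+ optional name) as BED, 0-based half-open."""
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table as ``<name>.tsv`` in ``out_dir``; tables with
    chrom/start/end also get a BED. Values round-trip to 6+ significant
    digits."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written.append(path)
        if {"chrom", "start", "end"}.issubset(df.columns) and len(df):
            bed = out_dir / f"{name}.bed"
            write_bed(df, bed)
            written.append(bed)
    return written
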