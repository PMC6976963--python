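"""CNV detection from capture coverage.

Exon regions pass a depth/length QC, depths are normalized for library size
and expressed relative to a common reference built from all 13 samples,
averaged per gene, centre-reduced across conditions, and screened per line
with the dosage trajectory condition

    (F0_LD80 - F0) > t1  AND  (F0_LD80 - F2) > 0
    AND  [ (F2_LD25 - F2) > t2  OR  (F2_LD75 - F2) > t2 ]

with defaults t1 = 0.3, t2 = 0.2 on the normalized copy-number (ratio)
scale, where 0.3 means a 15% gain over the diploid baseline: copy number
should rise in founder survivors, drop after outcrossing to the susceptible
strain, and rise again in selected F2 survivors. The thresholds can instead
be applied to the centre-reduced (z) values, but a copy-neutral gene's z
profile is standardized noise, so fixed thresholds lose specificity there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import ALL_LABELS, Condition, Line, Stage, line_conditions
from .tables import CoverageTable

logger = logging.getLogger(__name__)


@dataclass
class RegionQcSpec:
    """Depth/length QC for exon regions (bounds inclusive, length strict)."""

    min_depth: float = 30.0
    max_depth: float = 800.0
    min_length: int = 45  # exclusive: keep length > 45 bp

    def __post_init__(self) -> None:
        if not (0 < self.min_depth < self.max_depth):
            raise ValueError("require 0 < min_depth < max_depth")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass
class CnvFilterSpec:
    """Thresholds of the CNV-association condition, on the ratio scale by
    default ("z" applies them to the centre-reduced values instead)."""

    t1: float = 0.3
    t2: float = 0.2
    scale: str = "ratio"  # "ratio" (normalized values) or "z" (centre-reduced)

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.scale not in ("z", "ratio"):
            raise ValueError("scale must be 'z' or 'ratio'")


@dataclass
class CopyNumberProfile:
    """Per-gene normalized and centre-reduced copy-number values.

    Non-degenerate z values have mean 0 and population sd 1 across the 13
    conditions; a gene flat across conditions is flagged degenerate and its
    z values are all zero.
    """

    gene_id: str
    normalized: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class RegionQcReport:
    kept: int = 0
    dropped_length: int = 0
    dropped_low: int = 0
    dropped_high: int = 0


def filter_regions(
    cov: CoverageTable, spec: RegionQcSpec | None = None
) -> tuple[list[str], RegionQcReport]:
    """Retain regions with length > 45 bp and depth in [30, 800] in all samples."""
    spec = spec or RegionQcSpec()
    lengths = cov.region_lengths().to_numpy()
    depths = cov.depth[list(ALL_LABELS)].to_numpy(dtype=float)

    ok_len = lengths > spec.min_length
    low = (depths < spec.min_depth).any(axis=1)
    high = (depths > spec.max_depth).any(axis=1)
    keep = ok_len & ~low & ~high

    report = RegionQcReport(
        kept=int(keep.sum()),
        dropped_length=int((~ok_len).sum()),
        dropped_low=int((ok_len & low).sum()),
        dropped_high=int((ok_len & ~low & high).sum()),
    )
    return list(cov.region_ids[keep]), report


def normalize_copy_number(cov: CoverageTable, retained: list[str]) -> pd.DataFrame:
    """Library-size normalization then common-reference ratio per region.

    Each sample's depths are scaled by (mean library size / sample library
    size); each region's scaled depths are then divided by their across-sample
    mean, so every region's normalized values average to 1 by construction.
    """
    if not retained:
        raise ValueError("no retained regions to normalize")
    missing = [lbl for lbl in ALL_LABELS if lbl not in cov.library_sizes]
    if missing:
        raise ValueError(f"library size missing for condition(s): {', '.join(missing)}")
    depths = cov.depth.loc[retained, list(ALL_LABELS)].astype(float)
    lib = np.array([cov.library_sizes[lbl] for lbl in ALL_LABELS], dtype=float)
    scaled = depths * (lib.mean() / lib)
    ref = scaled.mean(axis=1)
    if (ref <= 0).any():
        rid = ref.index[(ref <= 0).to_numpy().argmax()]
        raise ValueError(f"zero common-reference coverage for retained region {rid!r}")
    return scaled.div(ref, axis=0)


def gene_profiles(
    normalized: pd.DataFrame,
    cov: CoverageTable,
    degenerate_tol: float = 1e-12,
) -> list[CopyNumberProfile]:
    """Average normalized region values per gene and centre-reduce across
    the 13 conditions (population sd, denominator n)."""
    meta = cov.regions.set_index("region_id").loc[normalized.index]
    gene_ids = meta["gene_id"]
    if gene_ids.isna().any():
        bad = normalized.index[gene_ids.isna()][0]
        raise ValueError(f"retained region {bad!r} has no gene mapping")
    per_gene = normalized.groupby(gene_ids).mean()

    all_genes = set(cov.regions["gene_id"].dropna())
    for gid in sorted(all_genes - set(per_gene.index)):
        logger.info("gene %s excluded: no retained regions", gid)

    profiles: list[CopyNumberProfile] = []
    vals = per_gene.to_numpy(dtype=float)
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, keepdims=True)  # population sd
    for i, gid in enumerate(per_gene.index):
        degenerate = sds[i, 0] < degenerate_tol
        z = np.zeros(vals.shape[1]) if degenerate else (vals[i] - means[i]) / sds[i]
        profiles.append(
            CopyNumberProfile(
                gene_id=str(gid),
                normalized=dict(zip(ALL_LABELS, vals[i])),
                z=dict(zip(ALL_LABELS, z)),
                degenerate=bool(degenerate),
            )
        )
    return profiles


def call_cnv_association(
    profile: CopyNumberProfile, line: Line, spec: CnvFilterSpec | None = None
) -> bool:
    """Apply the per-line CNV-association pass condition (strict inequalities)."""
    spec = spec or CnvFilterSpec()
    if profile.degenerate:
        return False
    values = profile.z if spec.scale == "z" else profile.normalized
    conds = line_conditions(line)
    missing = [c.label for c in conds if c.label not in values]
    if missing:
        raise ValueError(
            f"profile {profile.gene_id} missing condition(s): {', '.join(missing)}"
        )

    def v(stage: Stage) -> float:
        cond = conds[0] if stage is Stage.F0 else Condition(line, stage)
        return values[cond.label]

    return (
        (v(Stage.F0_LD80) - v(Stage.F0)) > spec.t1
        and (v(Stage.F0_LD80) - v(Stage.F2)) > 0
        and (
            (v(Stage.F2_LD25) - v(Stage.F2)) > spec.t2
            or (v(Stage.F2_LD75) - v(Stage.F2)) > spec.t2
        )
    )


def cnv_scan(
    cov: CoverageTable,
    qc: RegionQcSpec | None = None,
    filt: CnvFilterSpec | None = None,
) -> tuple[list[CopyNumberProfile], dict[Line, list[str]], RegionQcReport]:
    """Full coverage -> per-line CNV pass lists stage."""
    retained, report = filter_regions(cov, qc)
    if not retained:
        return [], {line: [] for line in (Line.DELT, Line.BEND, Line.FENI)}, report
    normalized = normalize_copy_number(cov, retained)
    profiles = gene_profiles(normalized, cov)
    hits = {
        line: [p.gene_id for p in profiles if call_cnv_association(p, line, filt)]
        for line in (Line.DELT, Line.BEND, Line.FENI)
    }
    return profiles, hits, report


def profiles_to_frame(profiles: list[CopyNumberProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {"gene_id": p.gene_id, "degenerate": p.degenerate}
        for lbl in ALL_LABELS:
            row[f"norm:{lbl}"] = p.normalized[lbl]
            row[f"z:{lbl}"] = p.z[lbl]
        rows.append(row)
    return pd.DataFrame(rows)
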