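"""In-memory containers shared by all pipeline stages.

Coordinates are 0-based half-open internally; TSV/VCF inputs use 1-based
positions and BED output is 0-based, following the standard dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .conditions import ALL_LABELS, Condition


class RegionKind(str, Enum):
    EXON = "exon"
    UPSTREAM = "upstream"
    INTERGENIC = "intergenic"


class GeneFamily(str, Enum):
    P450 = "P450"
    GST = "GST"
    CCE = "CCE"
    UDPGT = "UDPGT"
    SULT = "SULT"
    ABC = "ABC"
    ADH = "ADH"
    TARGET = "target"
    OTHER = "other"


#: families counted as resistance candidates when anchoring selection regions
CANDIDATE_FAMILIES = frozenset(f for f in GeneFamily if f is not GeneFamily.OTHER)


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    FRAMESHIFT = "frameshift"
    UPSTREAM = "upstream"
    INTERGENIC = "intergenic"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TargetRegion:
    """A captured region: exon, gene-upstream, or intergenic spacer."""

    region_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    kind: RegionKind
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: start must be < end")
        if self.kind is RegionKind.INTERGENIC:
            if self.gene_id is not None:
                raise ValueError(f"{self.region_id}: intergenic regions carry no gene_id")
        elif self.gene_id is None:
            raise ValueError(f"{self.region_id}: {self.kind.value} regions require gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    name: str
    family: GeneFamily
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: gene span must be positive")


class AlleleCountTable:
    """Per-locus ref/alt read counts across the 13 conditions.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt, effect`` plus
    ``<label>:ref`` / ``<label>:alt`` count columns for every condition label.
    ``pos`` is 0-based internally.
    """

    META_COLS = ("chrom", "pos", "ref", "alt", "effect")

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def _validate(self) -> None:
        for col in self.META_COLS:
            if col not in self.df.columns:
                raise ValueError(f"count table missing column {col!r}")
        for label in ALL_LABELS:
            for suffix in ("ref", "alt"):
                col = f"{label}:{suffix}"
                if col not in self.df.columns:
                    raise ValueError(f"count table missing condition column {col!r}")
                vals = self.df[col]
                bad = vals.isna() | (vals < 0) | (vals != vals.astype(np.int64))
                if bad.any():
                    row = self.df.loc[bad.idxmax()]
                    raise ValueError(
                        "negative or non-integer count at "
                        f"{row['chrom']}:{int(row['pos']) + 1} ({col})"
                    )
                self.df[col] = vals.astype(np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> pd.Series:
        return self.df["chrom"].astype(str) + ":" + (self.df["pos"] + 1).astype(str)

    def ref_counts(self, cond: Condition | str) -> np.ndarray:
        label = cond.label if isinstance(cond, Condition) else cond
        return self.df[f"{label}:ref"].to_numpy()

    def alt_counts(self, cond: Condition | str) -> np.ndarray:
        label = cond.label if isinstance(cond, Condition) else cond
        return self.df[f"{label}:alt"].to_numpy()

    def depth(self, cond: Condition | str) -> np.ndarray:
        return self.ref_counts(cond) + self.alt_counts(cond)

    def frequency(self, cond: Condition | str) -> np.ndarray:
        """Alt-allele frequency alt/(ref+alt); NaN where depth is zero."""
        alt = self.alt_counts(cond).astype(float)
        dep = self.depth(cond).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(dep > 0, alt / dep, np.nan)

    def subset(self, mask: np.ndarray | pd.Series) -> "AlleleCountTable":
        return AlleleCountTable(self.df.loc[np.asarray(mask)].copy(), validate=False)


@dataclass
class CoverageTable:
    """Mean read depth (reads/bp) per target region and condition.

    ``regions`` holds region metadata (``region_id, chrom, start, end, kind,
    gene_id, length``); ``depth`` is a DataFrame indexed by region_id with one
    column per condition label; ``library_sizes`` maps labels to total
    filtered read counts.
    """

    regions: pd.DataFrame
    depth: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [lbl for lbl in ALL_LABELS if lbl not in self.depth.columns]
        if missing:
            raise ValueError(f"coverage table missing condition(s): {', '.join(missing)}")
        vals = self.depth[list(ALL_LABELS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            bad = np.argwhere(~np.isfinite(vals) | (vals < 0))[0]
            rid = self.depth.index[bad[0]]
            raise ValueError(f"non-finite or negative depth for region {rid!r}")
        for lbl, size in self.library_sizes.items():
            if size <= 0:
                raise ValueError(f"library size for {lbl} must be positive")
        if "length" not in self.regions.columns:
            self.regions = self.regions.assign(
                length=self.regions["end"] - self.regions["start"]
            )

    @property
    def region_ids(self) -> pd.Index:
        return self.depth.index

    def region_lengths(self) -> pd.Series:
        return self.regions.set_index("region_id")["length"].loc[self.depth.index]


def genes_to_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "family": g.family.value,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
            }
            for g in genes
        ]
    )


def frame_to_genes(df: pd.DataFrame) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            name=str(r.name_),
            family=GeneFamily(r.family),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
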