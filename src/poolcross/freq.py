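"""Allele-frequency estimation, variant QC, and the trajectory filter.

Pool allele frequencies are read-count ratios alt/(ref+alt). A locus is a
resistance-associated hit in a line when its frequency rises from the
unexposed founders (F0) to the LD80 survivors by at least a band-specific
minimum, falls after outcrossing to the susceptible strain (F2), and rises
again with dose in F2 survivors. Deleterious alleles are required to behave
reciprocally: the complement trajectory (1 - f at every stage) must pass the
same conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .conditions import Condition, Line, Stage, SELECTED_LINES, line_conditions
from .tables import AlleleCountTable, Effect

logger = logging.getLogger(__name__)

STAGES = (Stage.F0, Stage.F0_LD80, Stage.F2, Stage.F2_LD25, Stage.F2_LD75)


@dataclass
class VariantQcSpec:
    """Locus-level QC: depth, minor-allele support, and polymorphism."""

    min_depth: int = 30  # exclusive: keep depth > 30 in every condition
    min_support: float = 0.04  # minor allele >= 4% reads in >= 1 condition
    min_variation: float = 0.05  # >= 5% difference between some condition pair

    def __post_init__(self) -> None:
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")
        if not (0 < self.min_support < 1 and 0 < self.min_variation < 1):
            raise ValueError("support and variation fractions must lie in (0,1)")


@dataclass(frozen=True)
class Band:
    """Initial-frequency band with its minimum F0 -> F0_LD80 increase.

    ``delta`` is None for the top band, where any strict increase counts.
    Bands are left-closed right-open except the top band, which is closed.
    """

    lo: float
    hi: float
    delta: float | None

    def contains(self, f: float) -> bool:
        if self.delta is None:
            return self.lo <= f <= self.hi
        return self.lo <= f < self.hi


_UPPER_BANDS = (Band(0.85, 0.90, 0.10), Band(0.90, 0.95, 0.05), Band(0.95, 1.0, None))


@dataclass
class TrajectoryFilterSpec:
    """Frequency bands and deltas of the trajectory filter, per line.

    The deltamethrin line uses a 30% initial-frequency floor; bendiocarb and
    fenitrothion use 15%, reflecting the founder population's weaker
    resistance to those insecticides. The band's delta also sets the minimum
    F2 -> F2_LD75 increase.
    """

    bands: dict[Line, tuple[Band, ...]] = field(
        default_factory=lambda: {
            Line.DELT: (Band(0.30, 0.85, 0.15),) + _UPPER_BANDS,
            Line.BEND: (Band(0.15, 0.85, 0.15),) + _UPPER_BANDS,
            Line.FENI: (Band(0.15, 0.85, 0.15),) + _UPPER_BANDS,
        }
    )
    reciprocal: bool = True  # also search for deleterious alleles

    def __post_init__(self) -> None:
        for line, bands in self.bands.items():
            los = [b.lo for b in bands]
            if los != sorted(los):
                raise ValueError(f"{line.value}: bands must be ordered")
            for a, b in zip(bands, bands[1:]):
                if a.hi > b.lo:
                    raise ValueError(f"{line.value}: bands overlap")
                if a.delta is not None and b.delta is not None and b.delta > a.delta:
                    raise ValueError(f"{line.value}: deltas must be non-increasing")

    def band_for(self, line: Line, f0: float) -> Band | None:
        for band in self.bands[line]:
            if band.contains(f0):
                return band
        return None


class Verdict(str, Enum):
    RESISTANCE = "resistance-associated"
    DELETERIOUS = "deleterious"
    NONE = "none"


@dataclass
class FrequencyTrajectory:
    """Alt-allele frequencies of one locus over a line's five stages.

    Stages with read depth below 30 are flagged low-coverage; zero-depth
    stages have frequency NaN and are always flagged. Flagged trajectories
    are excluded from filtering rather than imputed.
    """

    locus_id: str
    line: Line
    f: dict[Stage, float]
    low_coverage: dict[Stage, bool]

    @property
    def usable(self) -> bool:
        return not any(self.low_coverage.values()) and all(
            np.isfinite(self.f[s]) for s in STAGES
        )


def estimate_frequencies(
    counts: AlleleCountTable, low_cov_depth: int = 30
) -> dict[Line, list[FrequencyTrajectory]]:
    """Per-locus, per-line frequency trajectories with low-coverage flags."""
    out: dict[Line, list[FrequencyTrajectory]] = {}
    ids = counts.locus_ids.tolist()
    for line in SELECTED_LINES:
        conds = line_conditions(line)
        freqs = {c.stage: counts.frequency(c) for c in conds}
        depths = {c.stage: counts.depth(c) for c in conds}
        trajs = [
            FrequencyTrajectory(
                locus_id=ids[i],
                line=line,
                f={s: float(freqs[s][i]) for s in STAGES},
                low_coverage={s: bool(depths[s][i] < low_cov_depth) for s in STAGES},
            )
            for i in range(len(counts))
        ]
        out[line] = trajs
    return out


def qc_filter_variants(
    counts: AlleleCountTable, spec: VariantQcSpec | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean keep-mask over loci plus a tally of drop reasons.

    Keep iff depth > 30 in all 13 conditions, the minor allele reaches 4%
    supporting reads in at least one condition, and the largest pairwise
    frequency difference between conditions is >= 5%.
    """
    spec = spec or VariantQcSpec()
    from .conditions import ALL_CONDITIONS

    depth = np.stack([counts.depth(c) for c in ALL_CONDITIONS], axis=1)
    freq = np.stack([counts.frequency(c) for c in ALL_CONDITIONS], axis=1)

    deep = (depth > spec.min_depth).all(axis=1)
    with np.errstate(invalid="ignore"):
        minor = np.minimum(freq, 1 - freq)
        supported = np.nanmax(minor, axis=1) >= spec.min_support
        spread = np.nanmax(freq, axis=1) - np.nanmin(freq, axis=1)
        polymorphic = spread >= spec.min_variation
    keep = deep & supported & polymorphic
    reasons = {
        "low_depth": int((~deep).sum()),
        "low_support": int((deep & ~supported).sum()),
        "not_polymorphic": int((deep & supported & ~polymorphic).sum()),
        "kept": int(keep.sum()),
    }
    return keep, reasons


def _passes(f: dict[Stage, float], band: Band) -> bool:
    rise = f[Stage.F0_LD80] - f[Stage.F0]
    if band.delta is None:
        if rise <= 0:
            return False
    elif rise < band.delta:
        return False
    if not (f[Stage.F2] < f[Stage.F0_LD80]):
        return False
    if not (f[Stage.F2_LD25] > f[Stage.F2]):
        return False
    if not (f[Stage.F2_LD75] > f[Stage.F2_LD25]):
        return False
    rise2 = f[Stage.F2_LD75] - f[Stage.F2]
    if band.delta is None:
        return rise2 > 0
    return rise2 >= band.delta


def trajectory_filter(
    traj: FrequencyTrajectory, spec: TrajectoryFilterSpec | None = None
) -> tuple[Verdict, Band | None]:
    """Classify a trajectory as resistance-associated, deleterious, or none.

    The two verdicts are mutually exclusive by construction: a trajectory
    rising F0 -> F0_LD80 cannot have its complement also rising.
    """
    spec = spec or TrajectoryFilterSpec()
    if not traj.usable:
        return Verdict.NONE, None

    band = spec.band_for(traj.line, traj.f[Stage.F0])
    if band is not None and _passes(traj.f, band):
        return Verdict.RESISTANCE, band

    if spec.reciprocal:
        comp = {s: 1.0 - traj.f[s] for s in STAGES}
        band = spec.band_for(traj.line, comp[Stage.F0])
        if band is not None and _passes(comp, band):
            return Verdict.DELETERIOUS, band

    return Verdict.NONE, None


def scan_trajectories(
    counts: AlleleCountTable,
    qc: VariantQcSpec | None = None,
    spec: TrajectoryFilterSpec | None = None,
) -> pd.DataFrame:
    """QC-filter loci then run the trajectory filter for every line.

    Returns one row per retained locus x line with the verdict, matched band
    and the five stage frequencies.
    """
    keep, _ = qc_filter_variants(counts, qc)
    retained = counts.subset(keep)
    trajectories = estimate_frequencies(retained)
    effects = retained.df["effect"].tolist()
    rows = []
    for line in SELECTED_LINES:
        for i, traj in enumerate(trajectories[line]):
            verdict, band = trajectory_filter(traj, spec)
            row: dict[str, object] = {
                "locus_id": traj.locus_id,
                "line": line.value,
                "verdict": verdict.value,
                "band_lo": band.lo if band else np.nan,
                "effect": effects[i],
            }
            for s in STAGES:
                row[f"f_{s.value}"] = traj.f[s]
            rows.append(row)
    return pd.DataFrame(rows)


def kdr_report(
    counts: AlleleCountTable,
    named_loci: dict[str, str],
    low_cov_depth: int = 30,
) -> pd.DataFrame:
    """Frequency table for named target-site loci (e.g. the kdr mutations
    V410L, V1016I, F1534C), one row per locus x line x stage.

    ``named_loci`` maps a mutation name to a "chrom:pos" locus id (1-based).
    Absent loci are logged and omitted.
    """
    ids = counts.locus_ids
    rows = []
    for name, locus_id in named_loci.items():
        hit = np.flatnonzero(ids == locus_id)
        if hit.size == 0:
            logger.warning("named locus %s (%s) absent from counts", name, locus_id)
            continue
        i = int(hit[0])
        for line in SELECTED_LINES:
            for cond in line_conditions(line):
                dep = int(counts.depth(cond)[i])
                freq = float(counts.frequency(cond)[i])
                rows.append(
                    {
                        "name": name,
                        "locus_id": locus_id,
                        "line": line.value,
                        "stage": cond.stage.value,
                        "frequency": freq,
                        "depth": dep,
                        "low_coverage": dep < low_cov_depth,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "locus_id",
            "line",
            "stage",
            "frequency",
            "depth",
            "low_coverage",
        ],
    )


@dataclass(frozen=True)
class CodingSequence:
    """One gene's CDS: genomic interval, strand, and reference sequence.

    ``seq`` is the spliced CDS in reading-frame order (starts at codon 1);
    ``start`` is the 0-based genomic start of the interval. Only single-exon
    CDS models are supported, which suffices for effect annotation of
    capture-panel loci.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    seq: str
    strand: str = "+"


def annotate_effect(
    chrom: str, pos: int, ref: str, alt: str, cds_models: list[CodingSequence] | None
) -> Effect:
    """Label a variant's genic effect via codon translation.

    ``pos`` is 0-based. Length-changing variants inside a CDS are frameshift
    when the length change is not a multiple of 3; substitutions are
    translated with the standard genetic code. Without a coding model the
    label is unknown.
    """
    from Bio.Seq import Seq

    if not cds_models:
        return Effect.UNKNOWN
    for cds in cds_models:
        if cds.chrom != chrom or not (cds.start <= pos < cds.end):
            continue
        if len(cds.seq) % 3 != 0:
            logger.warning("CDS of %s has length not a multiple of 3; skipped", cds.gene_id)
            continue
        if len(ref) != len(alt):
            return (
                Effect.FRAMESHIFT
                if (len(alt) - len(ref)) % 3 != 0
                else Effect.UNKNOWN
            )
        offset = pos - cds.start
        if cds.strand == "-":
            offset = (cds.end - cds.start) - offset - len(ref)
            ref = str(Seq(ref).reverse_complement())
            alt = str(Seq(alt).reverse_complement())
        if cds.seq[offset : offset + len(ref)].upper() != ref.upper():
            logger.warning(
                "reference mismatch at %s:%d in %s", chrom, pos + 1, cds.gene_id
            )
            continue
        mutated = cds.seq[:offset] + alt + cds.seq[offset + len(ref) :]
        aa_ref = str(Seq(cds.seq).translate())
        aa_alt = str(Seq(mutated).translate())
        return Effect.SYNONYMOUS if aa_ref == aa_alt else Effect.NONSYNONYMOUS
    return Effect.INTERGENIC
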