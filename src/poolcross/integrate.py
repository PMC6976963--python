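"""Evidence integration: selection regions, Venn overlaps, nonsynonymous hits.

A genomic region is called under selection for a line when a
trajectory-filter hit locus also shows a low q-value in BOTH the F0 and F2
outlier-scan contrasts; hit-centred +/- 50 kb windows are merged per
chromosome and anchored to nearby candidate (detoxification/target) genes,
or reported as anonymous when none lies within the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .conditions import Line, SELECTED_LINES
from .tables import CANDIDATE_FAMILIES, GeneAnnotation
from .freq import Verdict


def _parse_locus(locus_id: str) -> tuple[str, int]:
    chrom, _, pos1 = locus_id.rpartition(":")
    return chrom, int(pos1) - 1


@dataclass
class SelectionRegion:
    chrom: str
    start: int
    end: int
    line: Line
    loci: list[str] = field(default_factory=list)
    min_q_f0: float = np.nan
    min_q_f2: float = np.nan
    genes: list[str] = field(default_factory=list)

    @property
    def anonymous(self) -> bool:
        return not self.genes

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region span must be positive")


def select_regions(
    traj_hits: pd.DataFrame,
    scan_f0: pd.DataFrame,
    scan_f2: pd.DataFrame,
    genes: list[GeneAnnotation],
    line: Line,
    window: int = 50_000,
    q_threshold: float = 0.05,
) -> list[SelectionRegion]:
    """Selection regions for one line.

    Seeds are trajectory-filter hit loci with q < threshold in both
    contrasts; each seed spawns a +/- window interval, overlapping intervals
    merge, and candidate genes overlapping the merged interval anchor it.
    """
    hits = traj_hits[
        (traj_hits["line"] == line.value)
        & (traj_hits["verdict"] != Verdict.NONE.value)
    ]
    q0 = scan_f0.set_index("locus_id")["q_value"]
    q2 = scan_f2.set_index("locus_id")["q_value"]

    seeds = []
    for locus_id in hits["locus_id"]:
        a = q0.get(locus_id, np.nan)
        b = q2.get(locus_id, np.nan)
        if np.isfinite(a) and np.isfinite(b) and a < q_threshold and b < q_threshold:
            chrom, pos = _parse_locus(locus_id)
            seeds.append((chrom, pos, locus_id, float(a), float(b)))
    if not seeds:
        return []

    seeds.sort()
    regions: list[SelectionRegion] = []
    for chrom, pos, locus_id, qa, qb in seeds:
        start, end = max(0, pos - window), pos + window + 1
        if regions and regions[-1].chrom == chrom and start <= regions[-1].end:
            reg = regions[-1]
            reg.end = max(reg.end, end)
            reg.loci.append(locus_id)
            reg.min_q_f0 = min(reg.min_q_f0, qa)
            reg.min_q_f2 = min(reg.min_q_f2, qb)
        else:
            regions.append(
                SelectionRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    line=line,
                    loci=[locus_id],
                    min_q_f0=qa,
                    min_q_f2=qb,
                )
            )
    for reg in regions:
        reg.genes = sorted(
            g.gene_id
            for g in genes
            if g.chrom == reg.chrom
            and g.family in CANDIDATE_FAMILIES
            and g.start < reg.end
            and g.end > reg.start
        )
    return regions


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "line": r.line.value,
                "n_loci": len(r.loci),
                "loci": ",".join(r.loci),
                "min_q_F0": r.min_q_f0,
                "min_q_F2": r.min_q_f2,
                "genes": ",".join(r.genes),
                "anonymous": r.anonymous,
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "line",
            "n_loci",
            "loci",
            "min_q_F0",
            "min_q_F2",
            "genes",
            "anonymous",
        ],
    )


def venn_counts(sets: dict[Line, set]) -> pd.DataFrame:
    """Counts of the 7 non-empty membership classes of three per-line sets."""
    lines = list(SELECTED_LINES)
    rows = []
    for r in (1, 2, 3):
        for combo in combinations(lines, r):
            inside = set.intersection(*(set(sets.get(l, set())) for l in combo))
            outside = set.union(
                *(set(sets.get(l, set())) for l in lines if l not in combo), set()
            )
            rows.append(
                {
                    "members": "&".join(l.value for l in combo),
                    "count": len(inside - outside),
                }
            )
    return pd.DataFrame(rows)


def nonsyn_table(
    traj: pd.DataFrame,
    genes: list[GeneAnnotation],
    regions: dict[Line, list[SelectionRegion]] | None = None,
) -> pd.DataFrame:
    """Nonsynonymous/frameshift trajectory hits on candidate-family genes,
    with their five-stage frequency profiles and selection-region flags."""
    regions = regions or {}
    hits = traj[
        (traj["verdict"] != Verdict.NONE.value)
        & traj["effect"].isin(["nonsynonymous", "frameshift"])
    ]
    rows = []
    for _, row in hits.iterrows():
        chrom, pos = _parse_locus(row["locus_id"])
        line = Line(row["line"])
        host = [
            g
            for g in genes
            if g.chrom == chrom
            and g.start <= pos < g.end
            and g.family in CANDIDATE_FAMILIES
        ]
        if not host:
            continue
        in_region = any(
            r.chrom == chrom and r.start <= pos < r.end
            for r in regions.get(line, [])
        )
        out = dict(row)
        out["gene_id"] = host[0].gene_id
        out["family"] = host[0].family.value
        out["in_selection_region"] = in_region
        rows.append(out)
    cols = list(traj.columns) + ["gene_id", "family", "in_selection_region"]
    return pd.DataFrame(rows, columns=cols)


def evidence_matrix(
    cnv_hits: dict[Line, list[str]],
    nonsyn: pd.DataFrame,
    regions: dict[Line, list[SelectionRegion]],
    genes: list[GeneAnnotation],
) -> pd.DataFrame:
    """Per gene x line boolean flags for the three evidence streams."""
    known = {g.gene_id: g for g in genes}
    rows = []
    for line in SELECTED_LINES:
        flagged: dict[str, dict[str, bool]] = {}
        for gid in cnv_hits.get(line, []):
            flagged.setdefault(gid, {})["cnv_pass"] = True
        if len(nonsyn):
            for gid in nonsyn.loc[nonsyn["line"] == line.value, "gene_id"]:
                flagged.setdefault(gid, {})["nonsyn_hit"] = True
        for reg in regions.get(line, []):
            for gid in reg.genes:
                flagged.setdefault(gid, {})["in_selection_region"] = True
        for gid, flags in sorted(flagged.items()):
            if gid not in known:
                raise ValueError(f"gene {gid!r} absent from annotation")
            rows.append(
                {
                    "gene_id": gid,
                    "line": line.value,
                    "family": known[gid].family.value,
                    "cnv_pass": flags.get("cnv_pass", False),
                    "nonsyn_hit": flags.get("nonsyn_hit", False),
                    "in_selection_region": flags.get("in_selection_region", False),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "line",
            "family",
            "cnv_pass",
            "nonsyn_hit",
            "in_selection_region",
        ],
    )


def truth_eval(
    truth: pd.DataFrame,
    cnv_hits: dict[Line, list[str]],
    traj: pd.DataFrame,
    regions: dict[Line, list[SelectionRegion]],
) -> pd.DataFrame:
    """Sensitivity / false-positive report per evidence stream against the
    simulator's ground truth."""
    rows = []

    causal_genes = {
        (Line(r.causal_line), r.gene_id)
        for r in truth.itertuples()
        if r.locus_class == "cnv_gene" and r.causal_line != "none"
    }
    cnv_calls = {(line, gid) for line, gids in cnv_hits.items() for gid in gids}
    tp = len(causal_genes & cnv_calls)
    rows.append(
        {
            "stream": "cnv",
            "n_causal": len(causal_genes),
            "true_positives": tp,
            "false_positives": len(cnv_calls - causal_genes),
            "sensitivity": tp / len(causal_genes) if causal_genes else np.nan,
        }
    )

    truth_snp = truth[truth["locus_class"] == "snp"]
    locus_ids = truth_snp["chrom"].astype(str) + ":" + (truth_snp["pos"] + 1).astype(str)
    causal_loci = {
        (Line(cl), lid)
        for cl, lid in zip(truth_snp["causal_line"], locus_ids)
        if cl != "none"
    }
    hit_rows = traj[traj["verdict"] != Verdict.NONE.value]
    traj_calls = {
        (Line(l), lid) for l, lid in zip(hit_rows["line"], hit_rows["locus_id"])
    }
    tp = len(causal_loci & traj_calls)
    n_neutral_tests = max(1, len(traj) - len(causal_loci))
    neutral_rate = len(traj_calls - causal_loci) / n_neutral_tests
    causal_rate = tp / len(causal_loci) if causal_loci else np.nan
    rows.append(
        {
            "stream": "trajectory",
            "n_causal": len(causal_loci),
            "true_positives": tp,
            "false_positives": len(traj_calls - causal_loci),
            "sensitivity": causal_rate,
            "neutral_hit_rate": neutral_rate,
            "enrichment": (causal_rate / neutral_rate)
            if causal_loci and neutral_rate > 0
            else np.inf,
        }
    )

    region_tp = 0
    n_regions = sum(len(v) for v in regions.values())
    covered = set()
    for line, regs in regions.items():
        for lid in {l for ln, l in causal_loci if ln == line}:
            chrom, pos = _parse_locus(lid)
            if any(
                r.chrom == chrom and r.start <= pos < r.end for r in regs
            ):
                covered.add((line, lid))
    region_tp = len(covered)
    fp_regions = 0
    causal_pos = {
        line: [( _parse_locus(lid)) for ln, lid in causal_loci if ln == line]
        for line in SELECTED_LINES
    }
    for line, regs in regions.items():
        for r in regs:
            if not any(
                c == r.chrom and r.start <= p < r.end for c, p in causal_pos.get(line, [])
            ):
                fp_regions += 1
    rows.append(
        {
            "stream": "region",
            "n_causal": len(causal_loci),
            "true_positives": region_tp,
            "false_positives": fp_regions,
            "sensitivity": region_tp / len(causal_loci) if causal_loci else np.nan,
            "n_regions": n_regions,
        }
    )
    return pd.DataFrame(rows)
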