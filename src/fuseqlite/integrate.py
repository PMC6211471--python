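"""Pipeline orchestration: run both evidence pipelines over a read stream,
merge mapped-read and split-read candidates, score, threshold, rank, export.

The final score of a fusion gene is the sum of the corrected mapped-read
count and the corrected split-read count; candidates scoring below the
minimum (default 3) are removed, and the rest are ranked by score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import filters as flt
from .feq import FusionGeneCandidate, build_feq_table, candidates_from_feq
from .filters import FilterConfig
from .quasimap import KmerIndex, MappingParams, build_index, map_pair
from .read_classes import MAPPED_READ, SPLIT_READ, classify_pair, extract_split_info
from .reference import Transcriptome
from .splitread import (JunctionBreak, call_junctions, misalignment_screen,
                        overlap_screen, splice_motif)

logger = logging.getLogger(__name__)

EXPORT_COLUMNS = [
    "gene5", "gene3", "symbol5", "symbol3", "chrom5", "brpos5", "chrom3",
    "brpos3", "mr_support", "mr_corrected", "sr_support", "score", "motif",
    "flags",
]


@dataclass
class DetectResult:
    candidates: list[FusionGeneCandidate]
    stage_counts: dict[str, int] = field(default_factory=dict)
    filter_log: list[tuple[str, str, str]] = field(default_factory=list)

    def as_frame(self, t: Transcriptome) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            bp = c.breakpoint
            rows.append({
                "gene5": c.gene5,
                "gene3": c.gene3,
                "symbol5": t.genes[c.gene5].symbol,
                "symbol3": t.genes[c.gene3].symbol,
                "chrom5": bp.chrom5 if bp else t.genes[c.gene5].chrom,
                "brpos5": bp.genomic_pos5 if bp else 0,
                "chrom3": bp.chrom3 if bp else t.genes[c.gene3].chrom,
                "brpos3": bp.genomic_pos3 if bp else 0,
                "mr_support": c.support_count,
                "mr_corrected": round(c.corrected_count, 6),
                "sr_support": c.sr_count,
                "score": round(c.score, 6),
                "motif": bp.motif if bp else "unknown",
                "flags": ";".join(sorted(c.flags)),
            })
        return pd.DataFrame(rows, columns=EXPORT_COLUMNS)


def merge_and_score(
    mr_cands: list[FusionGeneCandidate],
    sr_cands: list[FusionGeneCandidate],
    min_score: float = 3.0,
) -> list[FusionGeneCandidate]:
    """Merge the two filtered candidate lists by ordered gene pair and rank.

    Either evidence type may be absent for a candidate. Ties rank the
    candidate with more split-read support first, then lexicographic ids.
    """
    merged: dict[tuple[str, str], FusionGeneCandidate] = {}
    for c in mr_cands:
        merged[c.pair] = c
    for s in sr_cands:
        c = merged.get(s.pair)
        if c is None:
            merged[s.pair] = s
        else:
            c.sr_count = s.sr_count
            c.sr_corrected = s.sr_corrected
            if c.breakpoint is None:
                c.breakpoint = s.breakpoint
            c.flags |= s.flags
    out = []
    for c in merged.values():
        c.score = c.corrected_count + c.sr_corrected
        if c.score >= min_score:
            out.append(c)
    out.sort(key=lambda c: (-c.score, -c.sr_count, c.gene5, c.gene3))
    return out


def export(result: DetectResult, t: Transcriptome, out_path: str | Path) -> Path:
    """Write the ranked candidate table as TSV (deterministic ordering)."""
    out_path = Path(out_path)
    result.as_frame(t).to_csv(out_path, sep="\t", index=False)
    return out_path


def read_candidates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom5": str, "chrom3": str},
                       keep_default_na=False)


def detect(
    t: Transcriptome,
    read_pairs,
    params: MappingParams,
    cfg: FilterConfig | None = None,
    idx: KmerIndex | None = None,
    genome=None,
    similarity_reference: set[frozenset[str]] | None = None,
    paralog_db: set[frozenset[str]] | None = None,
    readthrough_db: set[frozenset[str]] | None = None,
    special_db: dict[str, set[str]] | None = None,
) -> DetectResult:
    """Full fusion detection over an iterable of (read_id, mate1, mate2).

    Filter order: general -> positional (duplicate collapse, fragment-length
    outliers, junction distance) -> similarity (simulated reference, paralog
    and read-through databases, shared-support screen) -> inverted-fusion
    resolution -> consistency flagging and special-gene annotation; the
    minimum-score rule is applied last, during merging.
    """
    cfg = cfg or FilterConfig()
    if idx is None:
        idx = build_index(t, params)
    if similarity_reference is None:
        similarity_reference = flt.build_similarity_reference(t, cfg, idx=idx)

    mr_pairs = []
    split_evidence = []
    counts = {"pairs": 0, "concordant": 0, MAPPED_READ: 0, SPLIT_READ: 0, "other": 0}
    for rid, s1, s2 in read_pairs:
        counts["pairs"] += 1
        pm = map_pair(s1, s2, idx, rid)
        pc = classify_pair(pm, params, t)
        if pc.label == MAPPED_READ:
            counts[MAPPED_READ] += 1
            mr_pairs.append(pm)
        elif pc.label == SPLIT_READ:
            counts[SPLIT_READ] += 1
            rm = pm.mapping1 if pc.split_mate == 1 else pm.mapping2
            mate = pm.mapping2 if pc.split_mate == 1 else pm.mapping1
            split_evidence.append(extract_split_info(rm, mate, pm, params, t))
        elif pc.label == "concordant":
            counts["concordant"] += 1
        else:
            counts["other"] += 1

    log: list[tuple[str, str, str]] = []

    # ---- mapped-read pipeline -------------------------------------------
    tbl = build_feq_table(mr_pairs, t)
    mr_cands = candidates_from_feq(tbl, t)
    counts["mr_candidates_raw"] = len(mr_cands)
    mr_kept = []
    for c in mr_cands:
        ok, reasons = flt.general_filter(c, t, cfg, is_mr=True)
        if not ok:
            log.append(("mr", f"{c.gene5}-{c.gene3}", ",".join(reasons)))
            continue
        pd_ = flt.positional_distribution(c, t, params.r)
        ok, reasons = flt.positional_filter(c, pd_, cfg, is_mr=True)
        if reasons:
            log.append(("mr", f"{c.gene5}-{c.gene3}", ",".join(reasons)))
        if not ok:
            continue
        ok, reasons = flt.similarity_filter(c, similarity_reference, paralog_db, readthrough_db)
        if not ok:
            log.append(("mr", f"{c.gene5}-{c.gene3}", ",".join(reasons)))
            continue
        mr_kept.append(c)
    mr_kept = flt.shared_support_screen(mr_kept, cfg.shared_support_frac)
    counts["mr_candidates_filtered"] = len(mr_kept)

    # ---- split-read pipeline --------------------------------------------
    screened = [
        e for e in split_evidence
        if misalignment_screen(e, t) and overlap_screen(e, cfg.max_overlap)
    ]
    counts["split_reads_screened"] = len(screened)
    junctions = call_junctions(screened, t)
    sr_kept = []
    for j in junctions:
        j.motif = splice_motif(j, genome, t)
        c = FusionGeneCandidate(
            gene5=j.gene5, gene3=j.gene3,
            sr_count=j.sr_support, sr_corrected=float(j.sr_support),
            breakpoint=j,
        )
        if j.motif in ("GT-AG", "GC-AG", "AT-AC"):
            c.flags.add(f"splice:{j.motif}")
        ok, reasons = flt.general_filter(c, t, cfg, is_mr=False)
        if not ok:
            log.append(("sr", f"{c.gene5}-{c.gene3}", ",".join(reasons)))
            continue
        if j.chrom5 == j.chrom3 and \
                abs(j.genomic_pos5 - j.genomic_pos3) < cfg.min_junction_distance:
            log.append(("sr", f"{c.gene5}-{c.gene3}", "junction_distance"))
            continue
        ok, reasons = flt.similarity_filter(c, similarity_reference, paralog_db, readthrough_db)
        if not ok:
            log.append(("sr", f"{c.gene5}-{c.gene3}", ",".join(reasons)))
            continue
        sr_kept.append(c)
    counts["sr_candidates_filtered"] = len(sr_kept)

    # ---- merge, invert, score, annotate ---------------------------------
    # score both partial lists first so the inverted-direction comparison
    # sees the combined evidence
    prelim = merge_and_score(mr_kept, sr_kept, min_score=0.0)
    prelim = flt.inverted_fusion_filter(prelim)
    final = [c for c in prelim if c.score >= cfg.min_score]
    final.sort(key=lambda c: (-c.score, -c.sr_count, c.gene5, c.gene3))
    for c in final:
        flt.mr_sr_consistency(c, cfg)
        if special_db:
            flt.annotate_special_genes(c, special_db)
    counts["final_candidates"] = len(final)
    for stage, n in counts.items():
        logger.info("stage %s: %d", stage, n)
    return DetectResult(final, counts, log)
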