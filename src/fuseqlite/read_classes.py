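"""Read-pair classification: concordant, mapped read (spanning pair),
split read, or unusable.

A mapped read is a pair whose mates each match (near-)fully — at least
r - k - 1 bases — to transcripts of two different genes; its fragment spans
the fusion junction. A split read is a single read matching >= k bases on
transcripts of each of two genes, with its mate anchored inside one of them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quasimap import MappingParams, PairMapping, ReadMapping, near_full_threshold
from .reference import Transcriptome
from .splitread import SplitReadEvidence

CONCORDANT = "concordant"
MAPPED_READ = "mapped_read"
SPLIT_READ = "split_read"
OTHER = "unmapped/other"


@dataclass
class PairClass:
    label: str
    detail: str = ""
    split_mate: int = 0  # 1 or 2 when label == split_read


def _split_candidate(rm: ReadMapping, k: int, t: Transcriptome) -> bool:
    """Does this mate carry a qualifying chimeric split (two genes, >=k each side)?"""
    if len(rm.segments) < 2:
        return False
    first, last = rm.segments[0], rm.segments[-1]
    if first.length < k or last.length < k:
        return False
    genes_first = {t.gene_of(tid) for tid, _ in first.hits}
    genes_last = {t.gene_of(tid) for tid, _ in last.hits}
    return len(genes_first | genes_last) >= 2


def classify_pair(pm: PairMapping, params: MappingParams, t: Transcriptome) -> PairClass:
    """Classify one mapped pair. Precedence: concordant, mapped read, split read."""
    if pm.S:
        return PairClass(CONCORDANT, "shared transcript between mates")
    genes1 = {t.gene_of(tid) for tid in pm.T1}
    genes2 = {t.gene_of(tid) for tid in pm.T2}
    if genes1 and genes2 and not (len(genes1 | genes2) == 1):
        return PairClass(MAPPED_READ, "mates near-fully mapped to different genes")
    if params.split_capable:
        for mate, rm, other in ((1, pm.mapping1, pm.mapping2), (2, pm.mapping2, pm.mapping1)):
            if not _split_candidate(rm, params.k, t):
                continue
            first, last = rm.segments[0], rm.segments[-1]
            split_genes = {t.gene_of(tid) for tid, _ in first.hits} | {
                t.gene_of(tid) for tid, _ in last.hits
            }
            anchor_t = pm.T2 if mate == 1 else pm.T1
            anchor_genes = {t.gene_of(tid) for tid in anchor_t}
            if anchor_genes & split_genes:
                return PairClass(SPLIT_READ, "chimeric mate with anchored pair", mate)
    return PairClass(OTHER, "no qualifying configuration")


def extract_split_info(
    rm: ReadMapping, mate_rm: ReadMapping, pm: PairMapping,
    params: MappingParams, t: Transcriptome,
) -> SplitReadEvidence:
    """Build the first/last-segment evidence record for a split mate.

    Only the first and last match segments are used; any middle segments are
    ignored. Raises if the mate does not carry a qualifying split.
    """
    if not _split_candidate(rm, params.k, t):
        raise ValueError(f"read {rm.read_id}: not a qualifying split mate")
    first, last = rm.segments[0], rm.segments[-1]
    genes5 = frozenset(t.gene_of(tid) for tid, _ in first.hits)
    genes3 = frozenset(t.gene_of(tid) for tid, _ in last.hits)
    anchor_t = pm.T2 if rm.mate == 1 else pm.T1
    anchor = None
    for tid in sorted(anchor_t):
        if t.gene_of(tid) in (genes5 | genes3):
            pos = mate_rm.segments[0].hits[0][1] if mate_rm.segments else 0
            for seg in mate_rm.segments:
                for htid, hpos in seg.hits:
                    if htid == tid:
                        pos = hpos
                        break
            anchor = (tid, pos)
            break
    return SplitReadEvidence(
        read_id=rm.read_id,
        direction=rm.orientation,
        qstart5=first.query_start, qend5=first.query_end,
        qstart3=last.query_start, qend3=last.query_end,
        tx5_hits=sorted(first.hits), tx3_hits=sorted(last.hits),
        genes5=genes5, genes3=genes3,
        mate_anchor=anchor,
        query=rm.query,
        k=params.k,
    )
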