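"""Split-read junction calling and split-read-specific screens.

A split read partially matches transcripts of two different genes; the end of
its first match segment and the start of its last segment pinpoint the fusion
junction at base resolution. Evidence records are grouped per gene pair and
the modal breakpoint is reported, optionally annotated with the splice motif
read from a genome FASTA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .reference import Transcriptome, revcomp

SPLICE_MOTIFS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}


@dataclass
class SplitReadEvidence:
    """First/last match-segment records for one split read.

    Query coordinates refer to the read in its mapped (sense) orientation, so
    the first segment is always the 5' side of the implied fusion product.
    ``tx5_hits``/``tx3_hits`` are (transcript_id, transcript_start) lists.
    """

    read_id: str
    direction: str  # mapped orientation of the split mate: 'fwd' or 'rc'
    qstart5: int
    qend5: int  # half-open query interval of the first segment
    qstart3: int
    qend3: int
    tx5_hits: list[tuple[str, int]]
    tx3_hits: list[tuple[str, int]]
    genes5: frozenset[str]
    genes3: frozenset[str]
    mate_anchor: tuple[str, int] | None  # (transcript, start) of the other mate
    query: str = ""  # split-mate sequence in mapped orientation
    k: int = 0


@dataclass
class JunctionBreak:
    """A called fusion junction between two genes."""

    gene5: str
    gene3: str
    tx5: str
    tx3: str
    chrom5: str
    chrom3: str
    genomic_pos5: int  # 1-based last genomic base of the 5' part
    genomic_pos3: int  # 1-based first genomic base of the 3' part
    tx_pos5: int  # 1-based last transcript base retained from the 5' transcript
    tx_pos3: int  # 1-based first transcript base retained from the 3' transcript
    sr_support: int = 1
    motif: str = "unknown"


def _breakpoint_of(e: SplitReadEvidence, t: Transcriptome, g5: str, g3: str):
    """Per-read breakpoint for one gene pair, on representative transcripts."""
    for tid5, tstart5 in e.tx5_hits:
        if t.gene_of(tid5) == g5:
            break
    else:
        return None
    for tid3, tstart3 in e.tx3_hits:
        if t.gene_of(tid3) == g3:
            break
    else:
        return None
    # end of the first segment on the 5' transcript (1-based inclusive)
    tx_pos5 = tstart5 + (e.qend5 - e.qstart5)
    tx_pos3 = tstart3 + 1
    chrom5, gpos5 = t.tx_to_genome(tid5, tx_pos5 - 1)
    chrom3, gpos3 = t.tx_to_genome(tid3, tx_pos3 - 1)
    return tid5, tid3, tx_pos5, tx_pos3, chrom5, gpos5, chrom3, gpos3


def call_junctions(
    evidence: list[SplitReadEvidence], t: Transcriptome
) -> list[JunctionBreak]:
    """Group evidence by gene pair and call the modal breakpoint per pair.

    Ties on the mode are broken toward the smaller genomic coordinate pair;
    support is the number of distinct reads in the group.
    """
    groups: dict[tuple[str, str], list[tuple]] = {}
    readsets: dict[tuple[str, str], set[str]] = {}
    for e in evidence:
        for g5 in sorted(e.genes5):
            for g3 in sorted(e.genes3):
                if g5 == g3:
                    continue
                bp = _breakpoint_of(e, t, g5, g3)
                if bp is None:
                    continue
                groups.setdefault((g5, g3), []).append(bp)
                readsets.setdefault((g5, g3), set()).add(e.read_id)
    out = []
    for (g5, g3), bps in sorted(groups.items()):
        counts = Counter(bps)
        top = max(counts.values())
        tid5, tid3, tx5p, tx3p, c5, gp5, c3, gp3 = min(
            bp for bp, n in counts.items() if n == top
        )
        out.append(
            JunctionBreak(
                gene5=g5, gene3=g3, tx5=tid5, tx3=tid3,
                chrom5=c5, chrom3=c3, genomic_pos5=gp5, genomic_pos3=gp3,
                tx_pos5=tx5p, tx_pos3=tx3p,
                sr_support=len(readsets[(g5, g3)]),
            )
        )
    return out


def _contiguous_match(query: str, tseq: str, qpos: int, tpos: int) -> int:
    """Length of the maximal exact match through the anchor (qpos, tpos)."""
    left = 0
    while qpos - left - 1 >= 0 and tpos - left - 1 >= 0 and \
            query[qpos - left - 1] == tseq[tpos - left - 1]:
        left += 1
    right = 0
    n, m = len(query), len(tseq)
    while qpos + right < n and tpos + right < m and \
            query[qpos + right] == tseq[tpos + right]:
        right += 1
    return left + right


def misalignment_screen(
    e: SplitReadEvidence, t: Transcriptome, frac: float = 0.85
) -> bool:
    """Keep (True) unless > ``frac`` of the read matches a single constituent
    transcript contiguously — such "splits" are misalignments of an ordinary read."""
    limit = frac * len(e.query)
    for qpos, hits in ((e.qstart5, e.tx5_hits), (e.qstart3, e.tx3_hits)):
        for tid, tstart in hits:
            tseq = t.transcripts[tid].sequence
            if _contiguous_match(e.query, tseq, qpos, tstart) > limit:
                return False
    return True


def overlap_screen(e: SplitReadEvidence, max_overlap: int = 10) -> bool:
    """Keep (True) unless the two sides dual-map more than ``max_overlap``
    query bases — long overlaps indicate paralog-like similarity, not a fusion."""
    overlap = e.qend5 - e.qstart3
    return overlap <= max_overlap


def _fetch(genome, chrom: str, start1: int, end1: int) -> str:
    """1-based inclusive fetch from a dict of sequences or a pyfaidx.Fasta."""
    if isinstance(genome, dict):
        return genome[chrom][start1 - 1 : end1].upper()
    return str(genome[chrom][start1 - 1 : end1]).upper()


def splice_motif(j: JunctionBreak, genome, t: Transcriptome) -> str:
    """Classify the donor/acceptor dinucleotides flanking the junction.

    The donor is the 2-base intronic sequence just 3' of the 5' breakpoint and
    the acceptor the 2 bases just 5' of the 3' breakpoint, read strand-aware
    from the genome. Returns 'GT-AG', 'GC-AG', 'AT-AC', 'none', or 'unknown'
    when no genome is available.
    """
    if genome is None:
        return "unknown"
    strand5 = t.genes[j.gene5].strand
    strand3 = t.genes[j.gene3].strand
    try:
        if strand5 == "+":
            donor = _fetch(genome, j.chrom5, j.genomic_pos5 + 1, j.genomic_pos5 + 2)
        else:
            donor = revcomp(_fetch(genome, j.chrom5, j.genomic_pos5 - 2, j.genomic_pos5 - 1))
        if strand3 == "+":
            acceptor = _fetch(genome, j.chrom3, j.genomic_pos3 - 2, j.genomic_pos3 - 1)
        else:
            acceptor = revcomp(_fetch(genome, j.chrom3, j.genomic_pos3 + 1, j.genomic_pos3 + 2))
    except (KeyError, IndexError):
        return "unknown"
    return SPLICE_MOTIFS.get((donor, acceptor), "none")
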