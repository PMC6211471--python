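"""Transcriptome annotation model: spliced transcript sequences tied to gene
structure from a FASTA/GTF pair.

All coordinates read from or written to GTF are 1-based inclusive; internal
arithmetic on transcript sequences is 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

INF = math.inf

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptRecord:
    """A spliced transcript: exon structure on the genome plus its 5'->3' sequence."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted by genomic start
    sequence: str

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]  # 1-based inclusive genomic interval
    biotype: str = "protein_coding"
    transcripts: list[str] = field(default_factory=list)
    name: str | None = None

    @property
    def symbol(self) -> str:
        return self.name or self.gene_id


class Transcriptome:
    """In-memory annotation: transcripts, genes, and the transcript->gene map."""

    def __init__(
        self,
        transcripts: dict[str, TranscriptRecord],
        genes: dict[str, GeneRecord],
    ) -> None:
        self.transcripts = transcripts
        self.genes = genes
        self.tx2gene = {tid: tx.gene_id for tid, tx in transcripts.items()}
        for tid, gid in self.tx2gene.items():
            if gid not in genes:
                raise ValueError(f"transcript {tid} refers to unknown gene {gid}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def gene_of(self, transcript_id: str) -> str:
        return self.tx2gene[transcript_id]

    def tx_to_genome(self, transcript_id: str, tpos: int) -> tuple[str, int]:
        """Map a 0-based transcript position to a 1-based genomic coordinate.

        Walks the exon chain; for '-' strand transcripts position 0 is the
        3'-most genomic base of the last exon.
        """
        tx = self.transcripts[transcript_id]
        if not 0 <= tpos < tx.exon_length:
            raise ValueError(
                f"position {tpos} outside transcript {transcript_id} "
                f"(length {tx.exon_length})"
            )
        if tx.strand == "+":
            remaining = tpos
            for start, end in tx.exons:
                exon_len = end - start + 1
                if remaining < exon_len:
                    return tx.chrom, start + remaining
                remaining -= exon_len
        else:
            remaining = tpos
            for start, end in reversed(tx.exons):
                exon_len = end - start + 1
                if remaining < exon_len:
                    return tx.chrom, end - remaining
                remaining -= exon_len
        raise AssertionError("unreachable: position checked against exon length")


def strip_version(identifier: str) -> str:
    """Drop a trailing '.N' version suffix (Ensembl id convention)."""
    head, dot, tail = identifier.rpartition(".")
    if dot and tail.isdigit():
        return head
    return identifier


def gene_distance(a: str, b: str, t: Transcriptome) -> float:
    """Genomic gap between two gene spans; INF across chromosomes, 0 on overlap."""
    ga, gb = t.genes[a], t.genes[b]
    if ga.chrom != gb.chrom:
        return INF
    (s1, e1), (s2, e2) = ga.span, gb.span
    if s1 > s2:
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
    return float(max(0, s2 - e1 - 1))


def _parse_gtf(gtf_path: str | Path):
    """Exon/gene structure from a GTF, grouped by transcript_id."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_exons: dict[str, dict] = {}
    gene_meta: dict[str, dict] = {}
    missing_biotype = False
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        info = tx_exons.setdefault(
            tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        info["exons"].append((feat.start, feat.end))
        meta = gene_meta.setdefault(gid, {"biotype": None, "name": None})
        if "gene_biotype" in feat.attributes:
            meta["biotype"] = feat.attributes["gene_biotype"][0]
        else:
            missing_biotype = True
        if "gene_name" in feat.attributes:
            meta["name"] = feat.attributes["gene_name"][0]
    try:
        for feat in db.features_of_type("gene"):
            gid = feat.attributes["gene_id"][0]
            meta = gene_meta.setdefault(gid, {"biotype": None, "name": None})
            if "gene_biotype" in feat.attributes:
                meta["biotype"] = feat.attributes["gene_biotype"][0]
            if "gene_name" in feat.attributes:
                meta["name"] = feat.attributes["gene_name"][0]
    except gffutils.exceptions.FeatureNotFoundError:  # pragma: no cover
        pass
    if missing_biotype and all(m["biotype"] is None for m in gene_meta.values()):
        logger.warning("GTF has no gene_biotype attributes; treating all genes as protein_coding")
    return tx_exons, gene_meta


def load_annotation(fasta_path: str | Path, gtf_path: str | Path) -> Transcriptome:
    """Build a :class:`Transcriptome` from a transcript FASTA and a GTF.

    FASTA ids are matched to GTF transcript_ids exactly, or after stripping a
    trailing version suffix. Transcripts present in the FASTA but absent from
    the GTF are dropped with a warning; zero matches is fatal.
    """
    fasta_path, gtf_path = Path(fasta_path), Path(gtf_path)
    for p in (fasta_path, gtf_path):
        if not p.exists():
            raise FileNotFoundError(p)

    tx_exons, gene_meta = _parse_gtf(gtf_path)
    stripped = {strip_version(tid): tid for tid in tx_exons}

    transcripts: dict[str, TranscriptRecord] = {}
    dropped = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        fid = rec.id
        tid = fid if fid in tx_exons else stripped.get(strip_version(fid))
        if tid is None:
            dropped.append(fid)
            continue
        info = tx_exons[tid]
        tx = TranscriptRecord(
            transcript_id=tid,
            gene_id=info["gene_id"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=info["exons"],
            sequence=str(rec.seq).upper(),
        )
        if tx.length != tx.exon_length:
            logger.warning(
                "transcript %s: sequence length %d != exon total %d",
                tid, tx.length, tx.exon_length,
            )
        transcripts[tid] = tx
    if dropped:
        logger.warning("%d FASTA records had no GTF annotation and were dropped "
                       "(first: %s)", len(dropped), dropped[0])
    if not transcripts:
        raise ValueError("annotation/sequence mismatch: no FASTA id matched the GTF")

    genes: dict[str, GeneRecord] = {}
    for tid, tx in transcripts.items():
        gid = tx.gene_id
        if gid not in genes:
            meta = gene_meta.get(gid, {"biotype": None, "name": None})
            genes[gid] = GeneRecord(
                gene_id=gid,
                chrom=tx.chrom,
                strand=tx.strand,
                span=(tx.exons[0][0], tx.exons[-1][1]),
                biotype=meta["biotype"] or "protein_coding",
                name=meta["name"],
            )
        g = genes[gid]
        g.transcripts.append(tid)
        g.span = (min(g.span[0], tx.exons[0][0]), max(g.span[1], tx.exons[-1][1]))
    return Transcriptome(transcripts, genes)


def write_annotation(t: Transcriptome, fasta_path: str | Path, gtf_path: str | Path) -> None:
    """Write the transcriptome back out as a FASTA/GTF pair (round-trippable)."""
    with open(fasta_path, "w") as fh:
        for tid in sorted(t.transcripts):
            seq = Seq(t.transcripts[tid].sequence)
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(str(seq[i : i + 70]) + "\n")
    with open(gtf_path, "w") as fh:
        for gid in sorted(t.genes):
            g = t.genes[gid]
            attrs = f'gene_id "{gid}"; gene_biotype "{g.biotype}";'
            if g.name:
                attrs += f' gene_name "{g.name}";'
            fh.write(
                f"{g.chrom}\tfuseqlite\tgene\t{g.span[0]}\t{g.span[1]}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid in sorted(g.transcripts):
                tx = t.transcripts[tid]
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write(
                    f"{tx.chrom}\tfuseqlite\ttranscript\t{tx.exons[0][0]}\t{tx.exons[-1][1]}"
                    f"\t.\t{tx.strand}\t.\t{tattrs}\n"
                )
                for start, end in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tfuseqlite\texon\t{start}\t{end}\t.\t{tx.strand}\t.\t{tattrs}\n"
                    )
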