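"""Synthetic transcriptomes, implanted fusions and paired-end read simulation.

Sequences are i.i.d. random nucleotides, so cross-gene k-mer collisions are
negligible at k >= 21; genes are laid out on chromosomes 1-22 with wide
spacing and multi-exon structures recorded in GTF coordinates. Implanted
fusion transcripts join a 5' transcript prefix to a 3' transcript suffix at
known breakpoints, mirroring a spike-in design with configurable abundances.
Reads are error-free by construction: the detection thresholds are defined on
exactly matched bases, so sequencing errors are a configuration extension,
not part of the core model.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reference import GeneRecord, TranscriptRecord, Transcriptome, revcomp

BASES = np.array(list("ACGT"))


@dataclass
class FusionTruth:
    """Ground truth for one implanted fusion."""

    gene5: str
    gene3: str
    tx5: str
    tx3: str
    breakpoint5: int  # 1-based last transcript base retained from tx5
    breakpoint3: int  # 1-based first transcript base retained from tx3
    fusion_sequence: str
    abundance: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def simulate_transcriptome(
    n_genes: int = 20,
    tx_per_gene: int = 2,
    length_range: tuple[int, int] = (1500, 3000),
    gc: float = 0.5,
    seed: int = 0,
    n_exons_range: tuple[int, int] = (3, 8),
    intron_range: tuple[int, int] = (200, 2000),
    intergenic_gap: int = 1_000_000,
    shared_exon_len: int = 0,
    emit_genome: bool = False,
    out_dir: str | Path | None = None,
):
    """Random multi-gene, multi-isoform transcriptome.

    Isoform 1 of each gene uses all exons; further isoforms each skip one
    internal exon. When ``shared_exon_len`` > 0 the first two genes carry an
    identical extra exon of that length (a planted paralog-like pair for
    similarity screening). With ``emit_genome`` the per-chromosome sequence is
    materialised (use a small ``intergenic_gap``). Returns the Transcriptome,
    or (Transcriptome, genome dict) when the genome is materialised.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    transcripts: dict[str, TranscriptRecord] = {}
    genes: dict[str, GeneRecord] = {}
    chrom_cursor = {str(c): intergenic_gap for c in range(1, 23)}
    genome_parts: dict[str, list[tuple[int, str]]] = {}
    shared_seq = _random_seq(rng, shared_exon_len, gc) if shared_exon_len else None

    for gi in range(n_genes):
        gid = f"GENE{gi + 1:04d}"
        chrom = str(gi % 22 + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        total_len = int(rng.integers(length_range[0], length_range[1] + 1))
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1, replace=False))
        exon_lens = np.diff(np.concatenate(([0], cuts, [total_len]))).tolist()
        exon_lens = [max(int(x), 30) for x in exon_lens]
        exon_seqs = [_random_seq(rng, L, gc) for L in exon_lens]
        if shared_seq is not None and gi in (0, 1):
            exon_seqs.insert(1, shared_seq)
            exon_lens.insert(1, shared_exon_len)
            n_exons += 1
        start = chrom_cursor[chrom]
        exons = []
        pos = start
        intron_seqs = []
        for L in exon_lens:
            exons.append((pos, pos + L - 1))
            intron_len = int(rng.integers(intron_range[0], intron_range[1] + 1))
            intron_seqs.append(_random_seq(rng, intron_len, gc))
            pos += L + intron_len
        gene_end = exons[-1][1]
        chrom_cursor[chrom] = gene_end + intergenic_gap
        genes[gid] = GeneRecord(
            gene_id=gid, chrom=chrom, strand=strand,
            span=(exons[0][0], gene_end), biotype="protein_coding", name=gid,
        )
        if emit_genome:
            parts = genome_parts.setdefault(chrom, [])
            for (s, _), seq in zip(exons, exon_seqs):
                parts.append((s, seq))
            for (s, e), iseq in zip(exons, intron_seqs):
                parts.append((e + 1, iseq))

        iso_exon_sets = [list(range(n_exons))]
        internal = list(range(1, n_exons - 1))
        for j in range(1, tx_per_gene):
            if internal:
                skip = internal[int(rng.integers(len(internal)))]
                iso_exon_sets.append([x for x in range(n_exons) if x != skip])
            else:
                iso_exon_sets.append(list(range(n_exons)))
        for j, exon_idx in enumerate(iso_exon_sets):
            tid = f"TX{gi + 1:04d}_{j + 1}"
            sel = sorted(set(exon_idx))
            spliced = "".join(exon_seqs[x] for x in sel)
            if strand == "-":
                spliced = revcomp(spliced)
            transcripts[tid] = TranscriptRecord(
                transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
                exons=[exons[x] for x in sel], sequence=spliced,
            )
            genes[gid].transcripts.append(tid)

    t = Transcriptome(transcripts, genes)
    genome = None
    if emit_genome:
        genome = {}
        for chrom, parts in genome_parts.items():
            end = max(s + len(seq) for s, seq in parts)
            arr = np.frombuffer(
                _random_seq(np.random.default_rng(seed * 100 + int(chrom)), end, gc).encode(),
                dtype="S1",
            ).copy()
            for s, seq in parts:
                arr[s - 1 : s - 1 + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
            genome[chrom] = arr.tobytes().decode()
    if out_dir is not None:
        from .reference import write_annotation

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_annotation(t, out_dir / "transcripts.fa", out_dir / "annotation.gtf")
        if genome is not None:
            with open(out_dir / "genome.fa", "w") as fh:
                for chrom in sorted(genome):
                    fh.write(f">{chrom}\n{genome[chrom]}\n")
    return (t, genome) if emit_genome else t


def implant_fusions(
    t: Transcriptome,
    n_fusions: int,
    seed: int = 0,
    abundances: list[int] | None = None,
    out_path: str | Path | None = None,
) -> list[FusionTruth]:
    """Pick inter-chromosomal gene pairs and join transcript prefix/suffix.

    Breakpoints are uniform within the middle 60% of each transcript. Each
    gene participates in at most one fusion. An optional truth TSV is written.
    """
    rng = np.random.default_rng(seed)
    gids = sorted(t.genes)
    order = list(rng.permutation(len(gids)))
    truths: list[FusionTruth] = []
    used: set[str] = set()
    i = 0
    while len(truths) < n_fusions and i < len(order):
        g5 = gids[order[i]]
        i += 1
        if g5 in used:
            continue
        partner = None
        for j in order[i:]:
            g3 = gids[j]
            if g3 not in used and t.genes[g3].chrom != t.genes[g5].chrom:
                partner = g3
                break
        if partner is None:
            break
        used |= {g5, partner}
        tx5 = t.transcripts[t.genes[g5].transcripts[0]]
        tx3 = t.transcripts[t.genes[partner].transcripts[0]]
        b5 = int(rng.integers(int(0.2 * tx5.length), int(0.8 * tx5.length)))
        b3 = int(rng.integers(int(0.2 * tx3.length), int(0.8 * tx3.length)))
        # a breakpoint inside junction microhomology is positionally
        # undefined; shift until the first 3' base differs from the 5'
        # continuation so the implanted coordinate is the unique call
        while tx5.sequence[b5] == tx3.sequence[b3] and b3 < int(0.8 * tx3.length):
            b3 += 1
        fusion_seq = tx5.sequence[:b5] + tx3.sequence[b3:]
        abundance = abundances[len(truths)] if abundances else 0
        truths.append(
            FusionTruth(
                gene5=g5, gene3=partner,
                tx5=tx5.transcript_id, tx3=tx3.transcript_id,
                breakpoint5=b5, breakpoint3=b3 + 1,
                fusion_sequence=fusion_seq, abundance=abundance,
            )
        )
    if len(truths) < n_fusions:
        raise ValueError(
            f"could only place {len(truths)} of {n_fusions} fusions under the "
            "inter-chromosomal constraint"
        )
    if out_path is not None:
        write_truth(truths, out_path)
    return truths


def write_truth(truths: list[FusionTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene5", "gene3", "tx5", "tx3", "breakpoint5", "breakpoint3", "abundance"])
        for tr in truths:
            w.writerow([tr.gene5, tr.gene3, tr.tx5, tr.tx3,
                        tr.breakpoint5, tr.breakpoint3, tr.abundance])


def read_truth(path: str | Path) -> list[tuple[str, str]]:
    """Gene pairs from a truth TSV (first two columns)."""
    pairs = []
    with open(path) as fh:
        rd = csv.reader(fh, delimiter="\t")
        header = next(rd, None)
        for row in rd:
            if len(row) >= 2:
                pairs.append((row[0], row[1]))
    return pairs


def _truncnorm_fraglen(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    """Normal fragment length truncated to [lo, hi] by resampling."""
    if hi <= lo:
        return lo
    for _ in range(100):
        fl = int(round(rng.normal(mean, sd)))
        if lo <= fl <= hi:
            return fl
    return int(min(max(mean, lo), hi))


def _fragment_reads(seq: str, start: int, fraglen: int, r: int) -> tuple[str, str]:
    frag = seq[start : start + fraglen]
    return frag[:r], revcomp(frag[-r:])


def simulate_reads(
    t: Transcriptome,
    truths: list[FusionTruth] | None = None,
    abundances: dict[str, int] | None = None,
    r: int = 100,
    fraglen_mean: float = 250.0,
    fraglen_sd: float = 25.0,
    n_background: int = 0,
    seed: int = 0,
    stranded: str = "no",
    dup_rate: float = 0.0,
    junction_spanning: bool = True,
    out_prefix: str | Path | None = None,
):
    """Paired-end fragment simulation.

    Yields (read_id, mate1, mate2) triples; exact fragment counts per source
    (abundance-proportional), truncated-normal fragment lengths, error-free
    bases. Fusion fragments are constrained to span the junction when
    ``junction_spanning``. ``stranded='no'`` randomly swaps mate roles per
    fragment; 'fr' keeps mate 1 on the sense strand, 'rf' the opposite.
    ``dup_rate`` duplicates that fraction of fragments exactly, for
    duplicate-collapse testing. Optionally writes a FASTQ pair.
    """
    rng = np.random.default_rng(seed)
    sources: list[tuple[str, str, int, int | None]] = []  # (name, seq, count, junction)
    if n_background > 0:
        tids = sorted(t.transcripts)
        base = n_background // len(tids)
        extra = n_background % len(tids)
        for i, tid in enumerate(tids):
            count = base + (1 if i < extra else 0)
            if count:
                sources.append((tid, t.transcripts[tid].sequence, count, None))
    if abundances:
        for tid in sorted(abundances):
            if tid not in t.transcripts:
                raise KeyError(f"unknown transcript {tid}")
            sources.append((tid, t.transcripts[tid].sequence, abundances[tid], None))
    for tr in truths or []:
        name = f"fusion|{tr.gene5}|{tr.gene3}"
        junction = tr.breakpoint5 if junction_spanning else None
        sources.append((name, tr.fusion_sequence, tr.abundance, junction))

    reads: list[tuple[str, str, str]] = []
    n = 0
    for name, seq, count, junction in sources:
        L = len(seq)
        if L < r:
            raise ValueError(f"source {name} shorter than read length")
        for _ in range(count):
            fl = _truncnorm_fraglen(rng, fraglen_mean, fraglen_sd, r, L)
            if junction is not None:
                lo = max(0, junction - fl + 1)
                hi = min(junction - 1, L - fl)
                if hi < lo:
                    start = max(0, min(junction - fl // 2, L - fl))
                else:
                    start = int(rng.integers(lo, hi + 1))
            else:
                start = int(rng.integers(0, L - fl + 1))
            m1, m2 = _fragment_reads(seq, start, fl, r)
            if stranded == "rf" or (stranded == "no" and rng.random() < 0.5):
                m1, m2 = m2, m1
            n += 1
            reads.append((f"frag{n}|{name}", m1, m2))
    n_dup = int(round(dup_rate * len(reads)))
    for i in range(n_dup):
        rid, m1, m2 = reads[i]
        reads.append((rid + "|dup", m1, m2))
    if out_prefix is not None:
        write_fastq_pair(reads, out_prefix)
    return reads


def simulate_uniform_pairs(
    t: Transcriptome,
    count_per_tx: int = 1000,
    r: int = 100,
    fraglen_mean: float = 250.0,
    fraglen_sd: float = 25.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Uniform-abundance sample: the same expected fragment count for every
    transcript (the similarity-reference input)."""
    abundances = {tid: count_per_tx for tid in t.transcripts}
    return simulate_reads(
        t, abundances=abundances, r=r, fraglen_mean=fraglen_mean,
        fraglen_sd=fraglen_sd, seed=seed, stranded="fr",
    )


def write_fastq_pair(
    reads: list[tuple[str, str, str]], out_prefix: str | Path, compress: bool = False
) -> tuple[Path, Path]:
    out_prefix = Path(out_prefix)
    suffix = ".fastq.gz" if compress else ".fastq"
    p1 = out_prefix.parent / (out_prefix.name + "_1" + suffix)
    p2 = out_prefix.parent / (out_prefix.name + "_2" + suffix)
    op = gzip.open if compress else open
    with op(p1, "wt") as f1, op(p2, "wt") as f2:
        for rid, m1, m2 in reads:
            f1.write(f"@{rid}\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}\n{m2}\n+\n{'I' * len(m2)}\n")
    return p1, p2
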