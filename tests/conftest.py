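"""Shared fixtures and small construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from fuseqlite.feq import FragmentRecord
from fuseqlite.quasimap import (KmerIndex, MappingParams, MatchSegment,
                                PairMapping, ReadMapping, build_index)
from fuseqlite.reference import GeneRecord, TranscriptRecord, Transcriptome
from fuseqlite.simdata import simulate_transcriptome


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def make_transcriptome(specs: list[tuple]) -> Transcriptome:
    """Build a transcriptome from (tid, gid, chrom, strand, exons, seq) tuples.

    ``exons`` may be None, in which case a single exon of the sequence length
    is placed at position 1001.
    """
    transcripts, genes = {}, {}
    for tid, gid, chrom, strand, exons, seq in specs:
        if exons is None:
            exons = [(1001, 1000 + len(seq))]
        transcripts[tid] = TranscriptRecord(tid, gid, chrom, strand, exons, seq)
        if gid not in genes:
            genes[gid] = GeneRecord(gid, chrom, strand,
                                    (exons[0][0], exons[-1][1]))
        g = genes[gid]
        g.transcripts.append(tid)
        g.span = (min(g.span[0], exons[0][0]), max(g.span[1], exons[-1][1]))
    return Transcriptome(transcripts, genes)


def fake_read_mapping(read_id: str, mate: int, hits: list[str], length: int = 100,
                      orientation: str | None = None, start: int = 0) -> ReadMapping:
    """A single full-length segment hitting the given transcripts."""
    if orientation is None:
        orientation = "fwd" if mate == 1 else "rc"
    seg = MatchSegment(0, length, [(tid, start) for tid in hits])
    return ReadMapping(read_id, mate, orientation, [seg], "A" * length)


def fake_pair(read_id: str, T1: set[str], T2: set[str],
              start1: int = 0, start2: int = 0) -> PairMapping:
    """A PairMapping with prescribed hit sets (mate 1 sense, mate 2 antisense)."""
    return PairMapping(
        read_id,
        fake_read_mapping(read_id, 1, sorted(T1), start=start1),
        fake_read_mapping(read_id, 2, sorted(T2), start=start2),
        frozenset(T1), frozenset(T2),
    )


@pytest.fixture(scope="session")
def toy_t() -> Transcriptome:
    """5 transcripts / 4 genes with unique random sequences."""
    return make_transcriptome([
        ("tx1", "gA", "1", "+", None, random_seq(600, 101)),
        ("tx2", "gA", "1", "+", None, random_seq(500, 102)),
        ("tx3", "gB", "2", "+", None, random_seq(700, 103)),
        ("tx4", "gC", "3", "-", None, random_seq(650, 104)),
        ("tx5", "gD", "4", "+", None, random_seq(550, 105)),
    ])


@pytest.fixture(scope="session")
def toy_idx(toy_t) -> KmerIndex:
    return build_index(toy_t, MappingParams(k=21, r=50))


@pytest.fixture(scope="session")
def sim_t() -> Transcriptome:
    return simulate_transcriptome(n_genes=10, seed=1)


def frag(rid: str, s5: int = 0, s3: int = 0) -> FragmentRecord:
    return FragmentRecord(rid, s5, s3, "tx", "tx")
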