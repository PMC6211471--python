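"""Lightweight transcriptome quasi-mapping.

A k-mer hash index over the transcript sequences supports greedy
maximal-extension mapping: from the leftmost read position whose k-mer is
indexed, the match is extended base-by-base along each candidate transcript,
yielding ordered match segments without base-level alignment scores. This is
deliberately a simple hash-based mapper; downstream code depends only on the
segment/hit-set structure it reports, not on any particular indexing scheme.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

from .reference import Transcriptome, revcomp

logger = logging.getLogger(__name__)

#: transcripts supporting a mate are those with matched length >= r - k - 1
def near_full_threshold(read_len: int, k: int) -> int:
    return read_len - k - 1


@dataclass
class MappingParams:
    """k-mer and read-length parameters governing mapping and classification."""

    k: int
    r: int
    max_postings: int = 200  # skip k-mers occurring more often than this

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError(f"k-mer length {self.k} < 11")
        if not self.split_capable:
            logger.warning(
                "k=%d >= r/2=%.1f: split-read detection disabled", self.k, self.r / 2
            )

    @property
    def split_capable(self) -> bool:
        # a split read needs >= k matched bases on each side of the junction
        return self.k < self.r / 2


def choose_k(r: int) -> int:
    """Default k-mer length for a given read length: 21 short, 31 long."""
    if r < 25:
        raise ValueError(f"read length {r} too short: no k >= 11 satisfies k < r/2")
    return 21 if r < 70 else 31


@dataclass
class MatchSegment:
    """A maximal contiguous exact match on the query.

    ``hits`` lists (transcript_id, transcript_start) pairs supporting the
    segment, all in the forward orientation of the query as mapped.
    """

    query_start: int
    query_end: int  # 0-based half-open on the query
    hits: list[tuple[str, int]]

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ReadMapping:
    read_id: str
    mate: int
    orientation: str  # 'fwd' if the read itself matched transcript sense, else 'rc'
    segments: list[MatchSegment]
    query: str  # the read in its mapped orientation

    @property
    def total_matched(self) -> int:
        return sum(s.length for s in self.segments)

    def matched_per_transcript(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg in self.segments:
            for tid, _ in seg.hits:
                out[tid] = out.get(tid, 0) + seg.length
        return out


@dataclass
class PairMapping:
    """Per-pair transcript hit sets: concordant S and discordant S1/S2."""

    read_id: str
    mapping1: ReadMapping
    mapping2: ReadMapping
    T1: frozenset[str]
    T2: frozenset[str]

    @property
    def S(self) -> frozenset[str]:
        return self.T1 & self.T2

    @property
    def S1(self) -> frozenset[str]:
        return self.T1 - self.T2

    @property
    def S2(self) -> frozenset[str]:
        return self.T2 - self.T1


class KmerIndex:
    """Canonical k-mer postings over a transcriptome.

    Each posting records (transcript_id, offset, transcript_kmer_is_canonical);
    hyper-repetitive k-mers beyond ``max_postings`` occurrences are masked and
    behave as mismatches during mapping.
    """

    def __init__(self, k: int, max_postings: int = 200) -> None:
        self.k = k
        self.max_postings = max_postings
        self.postings: dict[str, list[tuple[str, int, bool]] | None] = {}
        self.sequences: dict[str, str] = {}

    def add_transcript(self, transcript_id: str, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        self.sequences[transcript_id] = seq
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            canon, is_canon = (km, True) if km <= rc else (rc, False)
            lst = self.postings.get(canon)
            if lst is None:
                if canon in self.postings:  # masked
                    continue
                self.postings[canon] = lst = []
            lst.append((transcript_id, i, is_canon))
            if len(lst) > self.max_postings:
                self.postings[canon] = None

    def lookup(self, kmer: str) -> list[tuple[str, int, bool]]:
        """Occurrences of ``kmer``; third element True for a sense match."""
        rc = revcomp(kmer)
        canon, query_is_canon = (kmer, True) if kmer <= rc else (rc, False)
        entries = self.postings.get(canon)
        if not entries:
            return []
        return [(tid, off, fwd == query_is_canon) for tid, off, fwd in entries]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"k": self.k, "max_postings": self.max_postings,
                         "postings": self.postings, "sequences": self.sequences}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        idx = cls(d["k"], d["max_postings"])
        idx.postings = d["postings"]
        idx.sequences = d["sequences"]
        return idx


def build_index(t: Transcriptome, params: MappingParams) -> KmerIndex:
    """Index every transcript of length >= k; shorter ones are skipped."""
    if len(t) == 0:
        raise ValueError("empty transcriptome")
    idx = KmerIndex(params.k, params.max_postings)
    skipped = 0
    for tid, tx in t.transcripts.items():
        if tx.length < params.k:
            skipped += 1
            continue
        idx.add_transcript(tid, tx.sequence)
    if skipped:
        logger.warning("%d transcripts shorter than k=%d skipped", skipped, params.k)
    if not idx.sequences:
        raise ValueError("no transcript long enough to index")
    return idx


def _map_query(query: str, idx: KmerIndex) -> list[MatchSegment]:
    """Greedy left-to-right segmentation of one query orientation."""
    k = idx.k
    n = len(query)
    segments: list[MatchSegment] = []
    i = 0
    while i + k <= n:
        hits = [(tid, off) for tid, off, fwd in idx.lookup(query[i : i + k]) if fwd]
        if not hits:
            i += 1
            continue
        rest = query[i + k :]
        best_ext = -1
        best_hits: list[tuple[str, int]] = []
        for tid, off in hits:
            tseq = idx.sequences[tid]
            p = off + k
            # fast path: the whole remainder matches this transcript
            if tseq[p : p + len(rest)] == rest and p + len(rest) <= len(tseq):
                ext = len(rest)
            else:
                ext = 0
                while ext < len(rest) and p + ext < len(tseq) and rest[ext] == tseq[p + ext]:
                    ext += 1
            if ext > best_ext:
                best_ext, best_hits = ext, [(tid, off)]
            elif ext == best_ext:
                best_hits.append((tid, off))
        end = i + k + best_ext
        segments.append(MatchSegment(i, end, best_hits))
        i = end
    return segments


def map_read(seq: str, idx: KmerIndex, read_id: str = "", mate: int = 1) -> ReadMapping:
    """Map one read in both orientations; the higher-coverage one wins (tie: fwd).

    Reverse-orientation mapping is performed on the reverse complement of the
    read, so reported segments are always sense-ordered: the first segment is
    the 5'-most part of the originating fragment strand.
    """
    seq = seq.upper()
    fwd_segs = _map_query(seq, idx) if len(seq) >= idx.k else []
    fwd_total = sum(s.length for s in fwd_segs)
    if fwd_total == len(seq):  # perfect forward mapping cannot be beaten
        return ReadMapping(read_id, mate, "fwd", fwd_segs, seq)
    rc = revcomp(seq)
    rc_segs = _map_query(rc, idx) if len(seq) >= idx.k else []
    rc_total = sum(s.length for s in rc_segs)
    if rc_total > fwd_total:
        return ReadMapping(read_id, mate, "rc", rc_segs, rc)
    return ReadMapping(read_id, mate, "fwd", fwd_segs, seq)


def near_full_hits(seq: str, idx: KmerIndex) -> frozenset[str]:
    """Transcripts matched >= r - k - 1 bases in either read orientation.

    Unlike :func:`map_read` this does not pick a winning orientation: a read
    lying in a region two transcripts share on opposite strands is credited
    to both (used by the sequence-similarity probe).
    """
    seq = seq.upper()
    if len(seq) < idx.k:
        return frozenset()
    thr = near_full_threshold(len(seq), idx.k)
    hits: set[str] = set()
    for query in (seq, revcomp(seq)):
        per: dict[str, int] = {}
        for seg in _map_query(query, idx):
            for tid, _ in seg.hits:
                per[tid] = per.get(tid, 0) + seg.length
        hits |= {tid for tid, n in per.items() if n >= thr}
    return frozenset(hits)


def map_pair(
    seq1: str, seq2: str, idx: KmerIndex, read_id: str = ""
) -> PairMapping:
    """Map both mates and derive the concordant/discordant transcript sets.

    A transcript enters T1/T2 only when the mate's matched bases on it reach
    the near-full threshold r - k - 1; partial split hits stay out.
    """
    m1 = map_read(seq1, idx, read_id, mate=1)
    m2 = map_read(seq2, idx, read_id, mate=2)
    t1 = frozenset(
        tid
        for tid, n in m1.matched_per_transcript().items()
        if n >= near_full_threshold(len(seq1), idx.k)
    )
    t2 = frozenset(
        tid
        for tid, n in m2.matched_per_transcript().items()
        if n >= near_full_threshold(len(seq2), idx.k)
    )
    return PairMapping(read_id, m1, m2, t1, t2)
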