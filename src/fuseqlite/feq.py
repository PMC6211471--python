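"""Fusion equivalence classes.

Each discordant read pair generates an ordered set of candidate fusion
transcripts — the cross product of the discordant transcript sets of its two
mates. Pairs generating the identical set form one fusion equivalence class
(feq) with fragment count c_j. Gene-level support is aggregated over classes:

    supportCount(fge)  = sum_j c_j            over classes supporting the gene pair
    correctedCount(fge) = sum_j c_j * w_j,    w_j = 1 / (number of fusion
                                              transcripts in class j)

A class whose transcript sides share a gene is evidence of intra-gene
ambiguity, not fusion, and its fragments are discarded entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .quasimap import PairMapping
from .reference import Transcriptome

#: an ordered fusion transcript: (5' transcript, 3' transcript)
FusionTranscript = tuple[str, str]


@dataclass
class FragmentRecord:
    """Minimal per-fragment info kept for positional filtering."""

    read_id: str
    start5: int  # 0-based start of the 5'-side mate on its transcript
    start3: int
    tx5: str
    tx3: str


@dataclass
class FusionEquivalenceClass:
    ftx_set: frozenset[FusionTranscript]
    count: int
    fragments: list[FragmentRecord] = field(default_factory=list)


@dataclass
class FeqTable:
    """Fusion equivalence classes with their fragment counts and incidence."""

    classes: list[FusionEquivalenceClass]
    n_discarded: int = 0  # fragments dropped for same-gene ambiguity

    @property
    def ftx_universe(self) -> set[FusionTranscript]:
        out: set[FusionTranscript] = set()
        for c in self.classes:
            out |= c.ftx_set
        return out

    def fge_universe(self, t: Transcriptome) -> set[tuple[str, str]]:
        return {
            (t.gene_of(a), t.gene_of(b)) for a, b in self.ftx_universe
        }

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.classes)


@dataclass
class FusionGeneCandidate:
    """A candidate fusion between an ordered gene pair, with its evidence."""

    gene5: str
    gene3: str
    support_count: int = 0
    corrected_count: float = 0.0
    sr_count: int = 0
    sr_corrected: float = 0.0
    score: float = 0.0
    breakpoint: object | None = None  # JunctionBreak once SR evidence is merged
    flags: set[str] = field(default_factory=set)
    fragments: list[FragmentRecord] = field(default_factory=list)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


def fusion_transcripts(
    S1: frozenset[str] | set[str], S2: frozenset[str] | set[str]
) -> set[FusionTranscript]:
    """Ordered cross product of the two discordant transcript sets."""
    if S1 & S2:
        raise ValueError("discordant sets must be disjoint")
    return set(itertools.product(sorted(S1), sorted(S2)))


def oriented_sides(pm: PairMapping) -> tuple[frozenset[str], frozenset[str], int]:
    """Canonical (5' side, 3' side) discordant sets for a pair.

    The sense mate (mapped in forward orientation) carries the 5' part of the
    fusion product, so orientation decides sides regardless of which file a
    mate came from; when orientations are uninformative mate 1 is the 5' side.
    Returns (S5, S3, mate index of the 5' mate).
    """
    o1, o2 = pm.mapping1.orientation, pm.mapping2.orientation
    if o1 == "rc" and o2 == "fwd":
        return pm.S2, pm.S1, 2
    return pm.S1, pm.S2, 1


def build_feq_table(pairs: list[PairMapping], t: Transcriptome) -> FeqTable:
    """Partition mapped-read pairs into fusion equivalence classes.

    Pairs with the identical fusion-transcript set share one class; a pair
    whose two sides contain transcripts of the same gene is discarded.
    """
    groups: dict[frozenset[FusionTranscript], list[FragmentRecord]] = {}
    discarded = 0
    for pm in pairs:
        s5, s3, mate5 = oriented_sides(pm)
        if not s5 or not s3:
            discarded += 1
            continue
        genes5 = {t.gene_of(x) for x in s5}
        genes3 = {t.gene_of(x) for x in s3}
        if genes5 & genes3:
            discarded += 1
            continue
        ftx = frozenset(fusion_transcripts(s5, s3))
        rm5 = pm.mapping1 if mate5 == 1 else pm.mapping2
        rm3 = pm.mapping2 if mate5 == 1 else pm.mapping1
        tx5, tx3 = min(s5), min(s3)
        start5 = _start_on(rm5, tx5)
        start3 = _start_on(rm3, tx3)
        groups.setdefault(ftx, []).append(
            FragmentRecord(pm.read_id, start5, start3, tx5, tx3)
        )
    classes = [
        FusionEquivalenceClass(ftx, len(frags), frags)
        for ftx, frags in sorted(groups.items(), key=lambda kv: sorted(kv[0]))
    ]
    return FeqTable(classes, discarded)


def _start_on(rm, tid: str) -> int:
    for seg in rm.segments:
        for htid, hpos in seg.hits:
            if htid == tid:
                return hpos
    return 0


def _class_supports(c: FusionEquivalenceClass, fge: tuple[str, str], t: Transcriptome) -> bool:
    return any((t.gene_of(a), t.gene_of(b)) == fge for a, b in c.ftx_set)


def support_count(fge: tuple[str, str], tbl: FeqTable, t: Transcriptome) -> int:
    """Fragments supporting the gene pair: sum of c_j over supporting classes."""
    return sum(c.count for c in tbl.classes if _class_supports(c, fge, t))


def support_count_ftx(ftx: FusionTranscript, tbl: FeqTable) -> int:
    """Fragments supporting a single fusion transcript."""
    return sum(c.count for c in tbl.classes if ftx in c.ftx_set)


def corrected_count(fge: tuple[str, str], tbl: FeqTable, t: Transcriptome) -> float:
    """Multiplicity-weighted support: each supporting class contributes
    c_j / |class| once, however many of its members map to this gene pair."""
    return sum(
        c.count / len(c.ftx_set) for c in tbl.classes if _class_supports(c, fge, t)
    )


def candidates_from_feq(tbl: FeqTable, t: Transcriptome) -> list[FusionGeneCandidate]:
    """One mapped-read candidate per distinct ordered gene pair in the table."""
    out: dict[tuple[str, str], FusionGeneCandidate] = {}
    for c in tbl.classes:
        fges = {(t.gene_of(a), t.gene_of(b)) for a, b in c.ftx_set}
        w = 1.0 / len(c.ftx_set)
        for fge in fges:
            cand = out.setdefault(fge, FusionGeneCandidate(*fge))
            cand.support_count += c.count
            cand.corrected_count += c.count * w
            cand.fragments.extend(c.fragments)
    return sorted(out.values(), key=lambda x: x.pair)
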