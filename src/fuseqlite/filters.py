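"""False-positive filters for fusion-gene candidates.

Three families: general gene features (chromosome, biotype, distance,
support), sequence similarity of the constituent genes (paralog/read-through
databases plus a simulation-derived similarity reference), and positional
distribution of the supporting reads (duplicate collapse, fragment-length
outliers, junction distance). Applied in the fixed order
general -> positional -> similarity -> inverted -> consistency/annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import binomtest

from .feq import FusionGeneCandidate
from .quasimap import KmerIndex, near_full_hits
from .reference import INF, Transcriptome, gene_distance

logger = logging.getLogger(__name__)

DEFAULT_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade; defaults are the standard run settings."""

    allowed_chroms: frozenset[str] = DEFAULT_CHROMS
    require_protein_coding: bool = True
    min_gene_distance: int = 100_000
    min_mr_support: int = 2
    min_sr_support: int = 1
    min_score: float = 3.0
    dup_collapse: bool = True
    fraglen_z_max: float = 5.0
    min_junction_distance: int = 100_000
    sim_read_count: int = 1000
    sim_seed: int = 2018
    max_overlap: int = 10
    shared_support_frac: float = 0.5
    consistency_p0: float = 0.5
    consistency_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_gene_distance", "min_mr_support", "min_sr_support",
                     "min_score", "fraglen_z_max", "min_junction_distance",
                     "sim_read_count", "max_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def general_filter(
    c: FusionGeneCandidate, t: Transcriptome, cfg: FilterConfig,
    is_mr: bool = True,
) -> tuple[bool, list[str]]:
    """Chromosome, biotype, inter-gene distance and minimum-support screen."""
    reasons = []
    g5, g3 = t.genes[c.gene5], t.genes[c.gene3]
    for g in (g5, g3):
        if _norm_chrom(g.chrom) not in cfg.allowed_chroms:
            reasons.append(f"chromosome:{g.chrom}")
        if cfg.require_protein_coding and g.biotype != "protein_coding":
            reasons.append(f"biotype:{g.gene_id}={g.biotype}")
    d = gene_distance(c.gene5, c.gene3, t)
    if d is not INF and d < cfg.min_gene_distance:
        reasons.append(f"distance:{int(d)}")
    if is_mr and c.support_count < cfg.min_mr_support:
        reasons.append(f"mr_support:{c.support_count}")
    if not is_mr and c.sr_count < cfg.min_sr_support:
        reasons.append(f"sr_support:{c.sr_count}")
    return (not reasons, reasons)


def inverted_fusion_filter(
    cands: list[FusionGeneCandidate],
) -> list[FusionGeneCandidate]:
    """Resolve (A,B) vs (B,A): keep the higher-scoring direction.

    A circular fusion pattern (both directions, tied scores) is likely
    artifactual; both directions are dropped and flagged.
    """
    by_pair = {c.pair: c for c in cands}
    out = []
    for c in cands:
        inv = by_pair.get((c.gene3, c.gene5))
        if inv is None:
            out.append(c)
        elif c.score > inv.score:
            out.append(c)
        elif c.score == inv.score:
            c.flags.add("circular")
    return out


def transcript_equivalence_classes(
    pairs_iter, idx: KmerIndex
) -> set[frozenset[str]]:
    """Concordant-hit-set classes of a read-pair stream (similarity probe).

    Hits are collected in both read orientations so that regions shared
    between opposite-strand transcripts also surface.
    """
    classes: set[frozenset[str]] = set()
    for rid, s1, s2 in pairs_iter:
        shared = near_full_hits(s1, idx) & near_full_hits(s2, idx)
        if len(shared) >= 2:
            classes.add(shared)
    return classes


def build_similarity_reference(
    t: Transcriptome, cfg: FilterConfig, idx: KmerIndex | None = None,
) -> set[frozenset[str]]:
    """Gene pairs with detectable sequence similarity.

    Simulates a uniform-abundance paired-end sample (``sim_read_count``
    fragments per transcript, seeded), maps it back, and records every gene
    pair whose transcripts co-occur in a concordant equivalence class: with
    all transcripts expressed, similar sequence regions must surface as
    shared mappings.
    """
    from .quasimap import MappingParams, build_index
    from .simdata import simulate_uniform_pairs

    if idx is None:
        k = min(31, min(tx.length for tx in t.transcripts.values()) // 2)
        idx = build_index(t, MappingParams(k=max(k, 11), r=100))
    pairs = simulate_uniform_pairs(
        t, count_per_tx=cfg.sim_read_count, seed=cfg.sim_seed
    )
    ref: set[frozenset[str]] = set()
    for cls in transcript_equivalence_classes(pairs, idx):
        genes = sorted({t.gene_of(tid) for tid in cls})
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                ref.add(frozenset((genes[i], genes[j])))
    return ref


def load_gene_pairs(path: str | Path) -> set[frozenset[str]]:
    """Read a 2-column TSV of gene pairs (paralogs, read-throughs)."""
    out: set[frozenset[str]] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and not parts[0].startswith("#"):
                out.add(frozenset(parts[:2]))
    return out


def similarity_filter(
    c: FusionGeneCandidate,
    simref: set[frozenset[str]],
    paralog_db: set[frozenset[str]] | None = None,
    readthrough_db: set[frozenset[str]] | None = None,
) -> tuple[bool, list[str]]:
    """Drop candidates whose gene pair shows known or simulated similarity."""
    pair = frozenset((c.gene5, c.gene3))
    reasons = []
    if pair in simref:
        reasons.append("similarity:simulated")
    if paralog_db and pair in paralog_db:
        reasons.append("similarity:paralog")
    if readthrough_db and pair in readthrough_db:
        reasons.append("similarity:readthrough")
    return (not reasons, reasons)


def shared_support_screen(
    cands: list[FusionGeneCandidate], frac: float = 0.5
) -> list[FusionGeneCandidate]:
    """Drop the lower-scoring of two candidates sharing most of their fragments.

    Mapped-read candidates carry no junction information, so heavy sharing of
    supporting fragments between two gene pairs indicates multi-mapping, not
    two real fusions.
    """
    frag_sets = {c.pair: {f.read_id for f in c.fragments} for c in cands}
    dropped: set[tuple[str, str]] = set()
    ranked = sorted(cands, key=lambda c: (-c.score, c.pair))
    for i, hi in enumerate(ranked):
        if hi.pair in dropped:
            continue
        for lo in ranked[i + 1:]:
            if lo.pair in dropped or lo.pair == (hi.gene3, hi.gene5):
                continue
            own = frag_sets[lo.pair]
            if own and len(own & frag_sets[hi.pair]) / len(own) > frac:
                dropped.add(lo.pair)
    return [c for c in cands if c.pair not in dropped]


def robust_z(values: np.ndarray) -> np.ndarray:
    """|x - median| / (1.4826 * MAD); zeros when MAD degenerates."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values, dtype=float)
    return np.abs(values - med) / (1.4826 * mad)


@dataclass
class PositionalDistribution:
    """Start positions and implied fragment lengths of the supporting pairs."""

    starts5: list[int]
    starts3: list[int]
    implied_fragment_lengths: list[float] = field(default_factory=list)


def positional_distribution(
    c: FusionGeneCandidate, t: Transcriptome, read_len: int
) -> PositionalDistribution:
    """Per-candidate start-position collection, with fragment lengths implied
    by the junction when a breakpoint is known."""
    starts5 = [f.start5 for f in c.fragments]
    starts3 = [f.start3 for f in c.fragments]
    lengths: list[float] = []
    if c.breakpoint is not None:
        b5, b3 = c.breakpoint.tx_pos5, c.breakpoint.tx_pos3
        for f in c.fragments:
            lengths.append((b5 - f.start5) + (f.start3 + read_len - (b3 - 1)))
    return PositionalDistribution(starts5, starts3, lengths)


def positional_filter(
    c: FusionGeneCandidate,
    pd: PositionalDistribution,
    cfg: FilterConfig,
    is_mr: bool = True,
) -> tuple[bool, list[str]]:
    """Duplicate collapse, fragment-length outlier removal, junction distance.

    Mutates the candidate's fragment list and support counts; returns the
    keep decision with reasons.
    """
    reasons = []
    keep_idx = list(range(len(c.fragments)))
    if cfg.dup_collapse and c.fragments:
        seen: set[tuple[int, int]] = set()
        uniq = []
        for i in keep_idx:
            key = (pd.starts5[i], pd.starts3[i])
            if key not in seen:
                seen.add(key)
                uniq.append(i)
        if len(uniq) < len(keep_idx):
            reasons.append(f"dedup:{len(keep_idx) - len(uniq)}")
        keep_idx = uniq
    if pd.implied_fragment_lengths and len(keep_idx) >= 3:
        lens = np.asarray([pd.implied_fragment_lengths[i] for i in keep_idx], float)
        z = robust_z(lens)
        ok = [i for i, zz in zip(keep_idx, z) if zz <= cfg.fraglen_z_max]
        if len(ok) < len(keep_idx):
            reasons.append(f"fraglen_outliers:{len(keep_idx) - len(ok)}")
        keep_idx = ok
    if keep_idx != list(range(len(c.fragments))):
        scale = len(keep_idx) / max(len(c.fragments), 1)
        c.fragments = [c.fragments[i] for i in keep_idx]
        c.support_count = len(keep_idx)
        c.corrected_count *= scale
    drop = False
    if c.breakpoint is not None and c.breakpoint.chrom5 == c.breakpoint.chrom3:
        jd = abs(c.breakpoint.genomic_pos5 - c.breakpoint.genomic_pos3)
        if jd < cfg.min_junction_distance:
            reasons.append(f"junction_distance:{jd}")
            drop = True
    if is_mr and c.support_count < cfg.min_mr_support:
        reasons.append(f"mr_support_after_dedup:{c.support_count}")
        drop = True
    return (not drop, reasons)


def mr_sr_consistency(c: FusionGeneCandidate, cfg: FilterConfig) -> bool:
    """Flag (never drop) candidates whose split/spanning evidence ratio is
    inconsistent with the expected split fraction p0 under a binomial model.

    Single-evidence candidates are legitimate and left untested.
    Returns True when a flag was added.
    """
    if c.support_count <= 0 or c.sr_count <= 0:
        return False
    n = c.sr_count + c.support_count
    p = binomtest(c.sr_count, n, cfg.consistency_p0).pvalue
    if p < cfg.consistency_alpha:
        c.flags.add("mr_sr_inconsistent")
        return True
    return False


def load_gene_sets(paths: dict[str, str | Path]) -> dict[str, set[str]]:
    """Named single-column gene lists (e.g. ribosomal, mitochondrial)."""
    out = {}
    for label, path in paths.items():
        with open(path) as fh:
            out[label] = {
                line.split("\t")[0].strip() for line in fh
                if line.strip() and not line.startswith("#")
            }
    return out


def annotate_special_genes(
    c: FusionGeneCandidate, special_db: dict[str, set[str]]
) -> set[str]:
    """Report-only annotation for special gene categories; never drops."""
    added = set()
    for label, genes in special_db.items():
        for g in (c.gene5, c.gene3):
            if g in genes:
                added.add(f"{label}:{g}")
    c.flags |= added
    return added
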