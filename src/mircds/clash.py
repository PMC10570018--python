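"""CLEAR-CLIP / CLASH hybrid-read analysis.

Pipeline order: interval expansion (+3 nt per end, compensating nuclease
nibbling) -> region annotation against all transcript models -> duplicate
collapsing on identical (ref, interval, miRNA) -> per-hybrid duplex calls
-> region summaries and 5'/3'-anchored base-pairing matrices.

Reads may be genomic (target_ref is a chromosome; annotation uses the
transcripts' exon structure, and fragments from minus-strand transcripts
are reverse-complemented into mRNA orientation before duplexing) or
transcriptomic (target_ref is a transcript id; annotation uses the spliced
UTR/CDS intervals and introns cannot occur).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .duplex import Duplex, ScoringParams, pairing_vector, predict_duplex
from .io import HybridRead, MiRNA, TranscriptModel, reverse_complement

log = logging.getLogger(__name__)

REGIONS = ("UTR3", "CDS", "UTR5", "intron")


@dataclass
class AnnotatedHybrid:
    """One hybrid read with region annotation and (optionally) a duplex."""

    read: HybridRead
    region: str  # UTR3 | CDS | UTR5 | intron | discarded_intergenic
    overlap_flags: frozenset[str]  # subset of {intronic, exonic, utr3, utr5}
    tx_id: str | None = None
    tx_strand: str = "+"
    duplex: Duplex | None = None
    excluded: bool = False  # e.g. unknown miRNA id

    @property
    def count(self) -> int:
        return self.read.count


def expand_intervals(
    reads: list[HybridRead], pad: int = 3, bounds: dict[str, int] | None = None
) -> list[HybridRead]:
    """Expand each target interval by ``pad`` on both ends, clamped to the
    reference. Reads on unknown references are dropped with a warning."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for r in reads:
        if bounds is not None and r.target_ref not in bounds:
            log.warning("dropping read on unknown reference %r", r.target_ref)
            continue
        hi = bounds[r.target_ref] if bounds is not None else None
        start = max(0, r.start - pad)
        end = r.end + pad if hi is None else min(hi, r.end + pad)
        out.append(replace(r, start=start, end=end))
    return out


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

def _spliced_to_genomic_intervals(
    tx: TranscriptModel, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Project a spliced interval onto genomic exon pieces (any strand)."""
    gm = tx.genome_mapping
    L = len(tx.seq)
    if gm.strand == "-":
        lo, hi = L - hi, L - lo  # plus-strand spliced offsets
    pieces = []
    off = 0
    for b in gm.blocks:
        blen = b.end - b.start
        a, z = max(lo, off), min(hi, off + blen)
        if a < z:
            pieces.append((b.start + (a - off), b.start + (z - off)))
        off += blen
    return pieces


class RegionIndex:
    """Interval index of transcript regions for hybrid-read annotation.

    Genomic references are keyed by chromosome; transcriptomic references by
    transcript id. Payloads are (flag, transcript) where flag is one of
    intronic/exonic/utr3/utr5.
    """

    def __init__(self, transcripts: list[TranscriptModel]):
        self.trees: dict[str, IntervalTree] = {}
        self.by_id = {t.id: t for t in transcripts}
        for tx in transcripts:
            gm = tx.genome_mapping
            if gm is not None:
                tree = self.trees.setdefault(gm.chrom, IntervalTree())
                for b in gm.blocks:
                    tree.addi(b.start, b.end, ("exonic", tx))
                for prev, nxt in zip(gm.blocks, gm.blocks[1:]):
                    if prev.end < nxt.start:
                        tree.addi(prev.end, nxt.start, ("intronic", tx))
                for flag, (lo, hi) in (("utr5", tx.utr5), ("utr3", tx.utr3)):
                    if hi > lo:
                        for glo, ghi in _spliced_to_genomic_intervals(tx, lo, hi):
                            tree.addi(glo, ghi, (flag, tx))
            # transcript-id addressing is always available
            tree = self.trees.setdefault(tx.id, IntervalTree())
            tree.addi(0, len(tx.seq), ("exonic", tx))
            for flag, (lo, hi) in (("utr5", tx.utr5), ("utr3", tx.utr3)):
                if hi > lo:
                    tree.addi(lo, hi, (flag, tx))

    def overlaps(self, read: HybridRead) -> list[tuple[str, TranscriptModel]]:
        tree = self.trees.get(read.target_ref)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(read.start, read.end)]


def annotate_region(read: HybridRead, index: RegionIndex) -> AnnotatedHybrid:
    """Label a read by the union of its transcript overlaps.

    Priority: UTR3 > CDS (exonic, no UTR flag) > UTR5 > intron; reads
    overlapping no transcript are discarded as intergenic.
    """
    hits = index.overlaps(read)
    flags = frozenset(flag for flag, _ in hits)
    by_flag = {}
    for flag, tx in hits:
        by_flag.setdefault(flag, tx)
    if "utr3" in flags:
        region, tx = "UTR3", by_flag["utr3"]
    elif "exonic" in flags and "utr5" not in flags:
        region, tx = "CDS", by_flag["exonic"]
    elif "utr5" in flags:
        region, tx = "UTR5", by_flag["utr5"]
    elif "intronic" in flags:
        region, tx = "intron", by_flag["intronic"]
    else:
        return AnnotatedHybrid(read, "discarded_intergenic", flags)
    strand = tx.genome_mapping.strand if tx.genome_mapping is not None else "+"
    return AnnotatedHybrid(read, region, flags, tx_id=tx.id, tx_strand=strand)


def collapse_duplicates(reads: list[HybridRead]) -> list[HybridRead]:
    """Collapse reads with identical (ref, interval, miRNA) into one entry,
    summing counts. Total count is conserved."""
    groups: "OrderedDict[tuple, int]" = OrderedDict()
    for r in reads:
        key = (r.target_ref, r.start, r.end, r.mirna_id, r.strand)
        groups[key] = groups.get(key, 0) + r.count
    return [
        HybridRead(ref, s, e, mid, count, strand)
        for (ref, s, e, mid, strand), count in groups.items()
    ]


def annotate_hybrids(
    reads: list[HybridRead],
    transcripts: list[TranscriptModel],
    pad: int = 3,
    bounds: dict[str, int] | None = None,
) -> list[AnnotatedHybrid]:
    """expand -> collapse -> annotate, the standard front half of the pipeline."""
    index = RegionIndex(transcripts)
    expanded = expand_intervals(reads, pad=pad, bounds=bounds)
    collapsed = collapse_duplicates(expanded)
    return [annotate_region(r, index) for r in collapsed]


# ---------------------------------------------------------------------------
# Duplex calls and matrices
# ---------------------------------------------------------------------------

def hybrid_duplexes(
    annotated: list[AnnotatedHybrid],
    sequences: dict[str, str],
    mirnas: list[MiRNA],
    scoring: ScoringParams = ScoringParams(),
) -> list[AnnotatedHybrid]:
    """Attach a predicted duplex to every non-discarded hybrid.

    ``sequences`` maps reference names (chromosome or transcript id) to RNA
    sequence. Fragments from minus-strand transcripts are flipped into mRNA
    orientation first. Hybrids with unknown miRNA ids are flagged
    ``excluded`` and skipped by the matrix builders.
    """
    by_id = {m.id: m for m in mirnas}
    out = []
    for h in annotated:
        if h.region == "discarded_intergenic":
            out.append(h)
            continue
        mi = by_id.get(h.read.mirna_id)
        if mi is None:
            log.warning("unknown miRNA id %r; excluding hybrid", h.read.mirna_id)
            out.append(replace(h, excluded=True))
            continue
        ref_seq = sequences[h.read.target_ref]
        frag = ref_seq[h.read.start : h.read.end]
        if h.tx_strand == "-":
            frag = reverse_complement(frag)
        dup = predict_duplex(mi, frag, scoring, ref=h.read.target_ref, start=h.read.start)
        out.append(replace(h, duplex=dup))
    return out


@dataclass(frozen=True)
class PairingMatrix:
    """Count-weighted per-hybrid pairing vectors and column fractions."""

    anchor: str  # five_prime | three_prime
    region: str
    width: int
    rows: np.ndarray  # (n_hybrids, width) bool
    weights: np.ndarray  # (n_hybrids,) counts (all ones when unweighted)
    col_fraction: np.ndarray  # (width,)

    @property
    def n_hybrids(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slot": np.arange(1, self.width + 1), "paired_fraction": self.col_fraction}
        )


def pairing_matrices(
    annotated: list[AnnotatedHybrid],
    anchor: str,
    region: str,
    width: int | None = None,
    weighted: bool = True,
) -> PairingMatrix:
    """Build the anchored pairing matrix for one region class.

    ``width`` defaults to the longest miRNA among contributing hybrids.
    An empty region class yields an empty matrix, not an error.
    """
    hybrids = [
        h for h in annotated if h.region == region and h.duplex is not None and not h.excluded
    ]
    if width is None:
        width = max((h.duplex.len_mirna for h in hybrids), default=0)
    rows = np.zeros((len(hybrids), width), dtype=bool)
    weights = np.ones(len(hybrids))
    for k, h in enumerate(hybrids):
        rows[k] = pairing_vector(h.duplex, anchor, width)
        if weighted:
            weights[k] = h.count
    if len(hybrids) and weights.sum() > 0:
        col_fraction = (rows.astype(float).T @ weights) / weights.sum()
    else:
        col_fraction = np.zeros(width)
    return PairingMatrix(anchor, region, width, rows, weights, col_fraction)


def region_summary(annotated: list[AnnotatedHybrid], weighted: bool = True) -> pd.Series:
    """Count-weighted region fractions among non-discarded reads; sums to 1."""
    counts = {r: 0.0 for r in REGIONS}
    for h in annotated:
        if h.region == "discarded_intergenic":
            continue
        counts[h.region] += h.count if weighted else 1
    total = sum(counts.values())
    if total == 0:
        return pd.Series(counts, name="fraction")
    return pd.Series({r: c / total for r, c in counts.items()}, name="fraction")


def annotated_table(annotated: list[AnnotatedHybrid]) -> pd.DataFrame:
    """TSV-ready table mirroring the processed CLEAR-CLIP annotation layout."""
    rows = []
    for h in annotated:
        rows.append(
            {
                "ref": h.read.target_ref,
                "start": h.read.start,
                "end": h.read.end,
                "mirna_id": h.read.mirna_id,
                "counts": h.count,
                "overlap_flags": ",".join(sorted(h.overlap_flags)) or "-",
                "region": h.region,
                "transcript_id": h.tx_id or "-",
                "dot_bracket": h.duplex.dot_bracket if h.duplex else "-",
                "score": h.duplex.score if h.duplex else np.nan,
            }
        )
    return pd.DataFrame(rows)
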