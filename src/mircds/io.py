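"""Sequence, transcript-model and hybrid-read I/O.

All coordinates in this package are 0-based half-open. BED12 input is already
0-based; any 1-based hybrid-table dialect is converted here, at the boundary,
and nowhere else. RNA sequences are stored 5'->3' upper-case over {A,C,G,U};
DNA input is transliterated T->U when a collection is declared RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
import pandas as pd

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick complement for RNA.
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: miRNA position ranges (1-based, inclusive) with field-standard names.
SEED_RANGE = (2, 8)
SEED_CLEAVE_RANGE = (2, 12)
CENTRAL_RANGE = (9, 12)
SUPPLEMENTARY_RANGE = (13, 17)


class SequenceError(ValueError):
    """Malformed sequence input (alphabet, duplicate ids, empty records)."""


@dataclass(frozen=True)
class MiRNA:
    """A microRNA: identifier plus 5'->3' RNA sequence.

    Positions are numbered 1..L from the 5' end throughout the package;
    the seed is nt 2-8 and the supplementary region nt 13-17.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_rna(self.seq, what=f"miRNA {self.id!r}")
        if not 16 <= len(self.seq) <= 28:
            raise SequenceError(
                f"miRNA {self.id!r}: length {len(self.seq)} outside [16, 28]"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ExonBlock:
    """One exon of a genomic mapping, 0-based half-open on the chromosome."""

    start: int
    end: int


@dataclass(frozen=True)
class GenomeMapping:
    chrom: str
    strand: str  # '+' or '-'
    blocks: tuple[ExonBlock, ...]  # ascending genomic order

    @property
    def tx_start(self) -> int:
        return self.blocks[0].start

    @property
    def tx_end(self) -> int:
        return self.blocks[-1].end


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced mRNA with 5'UTR / CDS / 3'UTR segmentation.

    ``seq`` is the spliced sequence in mRNA (5'->3') orientation; the three
    region intervals are half-open on ``seq`` and tile it exactly:
    utr5.end == cds.start, cds.end == utr3.start, utr3.end == len(seq).
    """

    id: str
    seq: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    genome_mapping: GenomeMapping | None = None
    cds_complete: bool = True

    def __post_init__(self) -> None:
        _check_rna(self.seq, what=f"transcript {self.id!r}")
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == len(self.seq)):
            raise ValueError(f"transcript {self.id!r}: regions do not tile the sequence")
        if self.cds_complete and self.coding and (c[1] - c[0]) % 3 != 0:
            raise ValueError(f"transcript {self.id!r}: complete CDS length not divisible by 3")

    @property
    def coding(self) -> bool:
        return self.cds[1] > self.cds[0]

    def region_seq(self, region: str) -> str:
        lo, hi = {"UTR5": self.utr5, "CDS": self.cds, "UTR3": self.utr3}[region]
        return self.seq[lo:hi]


@dataclass
class HybridRead:
    """One CLASH/CLEAR-CLIP chimera: target interval + associated miRNA."""

    target_ref: str
    start: int
    end: int
    mirna_id: str
    count: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hybrid read on {self.target_ref}: start >= end")
        if self.count < 1:
            raise ValueError("hybrid read count must be >= 1")


def _check_rna(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"{what}: non-RNA characters {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick RNA complement, reversed (5'->3' of the opposite strand)."""
    _check_rna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, rna: bool = True) -> str:
    """Upper-case and, for RNA collections, transliterate T->U.

    A record mixing T and U is rejected: it is neither DNA nor RNA.
    """
    s = seq.upper()
    if rna:
        if "T" in s and "U" in s:
            raise SequenceError("sequence mixes T and U")
        s = s.replace("T", "U")
        _check_rna(s)
    return s


def read_fasta(path: str | Path, rna: bool = True) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, sequence).

    Sequences are upper-cased; with ``rna=True`` (default) T is transliterated
    to U. Duplicate ids and empty records are errors.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise SequenceError(f"empty FASTA record {rec.id!r} in {path}")
        out.append((rec.id, normalize_sequence(seq, rna=rna)))
    log.info("read %d records from %s", len(out), path)
    return out


def read_mirnas(path: str | Path) -> list[MiRNA]:
    return [MiRNA(i, s) for i, s in read_fasta(path, rna=True)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    log.info("wrote %d records to %s", n, path)


# ---------------------------------------------------------------------------
# BED12 transcript models
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str) -> dict:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"BED12 line has {len(f)} fields, need 12: {line[:80]!r}")
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    return {
        "chrom": f[0], "start": int(f[1]), "end": int(f[2]), "name": f[3],
        "strand": f[5], "thick_start": int(f[6]), "thick_end": int(f[7]),
        "block_sizes": sizes, "block_starts": starts,
    }


def _project_to_spliced(rec: dict) -> tuple[tuple[tuple[int, int], ...], int, int]:
    """Project thickStart/thickEnd into plus-strand spliced coordinates.

    Returns (genomic blocks, spliced thick start, spliced thick end). The
    spliced thick interval is on the plus-strand concatenation of exons; the
    caller flips it for minus-strand transcripts.
    """
    blocks = tuple(
        (rec["start"] + bs, rec["start"] + bs + sz)
        for bs, sz in zip(rec["block_starts"], rec["block_sizes"])
    )
    ts, te = rec["thick_start"], rec["thick_end"]
    if ts == te:  # non-coding
        return blocks, 0, 0

    def to_spliced(gpos: int) -> int:
        off = 0
        for lo, hi in blocks:
            if gpos <= lo:
                return off
            if gpos < hi:
                return off + (gpos - lo)
            off += hi - lo
        return off

    for lo, hi in blocks:
        if lo <= ts < hi:
            break
    else:
        raise ValueError(f"{rec['name']}: thickStart {ts} outside exon blocks")
    if not any(lo < te <= hi for lo, hi in blocks):
        raise ValueError(f"{rec['name']}: thickEnd {te} outside exon blocks")
    return blocks, to_spliced(ts), to_spliced(te)


def load_transcript_models(
    bed12_path: str | Path, fasta_path: str | Path
) -> list[TranscriptModel]:
    """Assemble TranscriptModel objects from BED12 + a chromosome FASTA.

    The spliced sequence is stitched from exon blocks; minus-strand models
    are reverse-complemented so ``seq`` is always the 5'->3' mRNA, with the
    UTR/CDS intervals flipped accordingly.
    """
    genome = dict(read_fasta(fasta_path, rna=True))
    models: list[TranscriptModel] = []
    with open(bed12_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            rec = _parse_bed12_line(line)
            if rec["chrom"] not in genome:
                raise SequenceError(f"{rec['name']}: no sequence for {rec['chrom']!r}")
            chrom_seq = genome[rec["chrom"]]
            blocks, s_ts, s_te = _project_to_spliced(rec)
            plus_seq = "".join(chrom_seq[lo:hi] for lo, hi in blocks)
            L = len(plus_seq)
            if rec["strand"] == "-":
                seq = reverse_complement(plus_seq)
                s_ts, s_te = (L - s_te, L - s_ts) if s_te > s_ts else (0, 0)
            else:
                seq = plus_seq
            coding = s_te > s_ts
            models.append(
                TranscriptModel(
                    id=rec["name"],
                    seq=seq,
                    utr5=(0, s_ts if coding else 0),
                    cds=(s_ts, s_te) if coding else (0, 0),
                    utr3=(s_te if coding else 0, L),
                    genome_mapping=GenomeMapping(
                        rec["chrom"], rec["strand"], tuple(ExonBlock(lo, hi) for lo, hi in blocks)
                    ),
                    cds_complete=coding and (s_te - s_ts) % 3 == 0,
                )
            )
    log.info("loaded %d transcript models from %s", len(models), bed12_path)
    return models


def write_bed12(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            gm = m.genome_mapping
            if gm is None:
                raise ValueError(f"{m.id}: no genome mapping, cannot emit BED12")
            L = len(m.seq)
            if m.coding:
                ts, te = (m.cds if gm.strand == "+" else (L - m.cds[1], L - m.cds[0]))
                # spliced -> genomic projection of the thick interval
                g_ts = _spliced_to_genomic(gm, ts)
                g_te = _spliced_to_genomic(gm, te - 1) + 1
            else:
                g_ts = g_te = gm.tx_start
            sizes = ",".join(str(b.end - b.start) for b in gm.blocks)
            starts = ",".join(str(b.start - gm.tx_start) for b in gm.blocks)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        gm.chrom, gm.tx_start, gm.tx_end, m.id, 0, gm.strand,
                        g_ts, g_te, 0, len(gm.blocks), sizes, starts,
                    )
                )
                + "\n"
            )


def _spliced_to_genomic(gm: GenomeMapping, pos: int) -> int:
    """Plus-strand spliced offset -> genomic coordinate."""
    off = pos
    for b in gm.blocks:
        if off < b.end - b.start:
            return b.start + off
        off -= b.end - b.start
    raise ValueError(f"spliced position {pos} beyond transcript")


# ---------------------------------------------------------------------------
# Hybrid-read tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridDialect:
    """Column map and coordinate convention of a hybrid-read TSV.

    ``one_based`` declares 1-based fully-closed input intervals, converted to
    0-based half-open on read. The GEO-style processed CLEAR-CLIP files carry
    at minimum (ref, start, end, miRNA name); a counts column is optional.
    """

    ref: str = "ref"
    start: str = "start"
    end: str = "end"
    mirna: str = "mirna_id"
    count: str | None = "count"
    strand: str | None = "strand"
    one_based: bool = False
    has_header: bool = True


def read_hybrid_table(path: str | Path, dialect: HybridDialect = HybridDialect()) -> list[HybridRead]:
    """Read a hybrid-read TSV, normalising coordinates to 0-based half-open.

    Rows with start >= end are rejected with a logged warning, not fatally.
    """
    d = dialect
    if d.has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        names = [d.ref, d.start, d.end, d.mirna]
        if d.count:
            names.append(d.count)
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    reads: list[HybridRead] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        start = int(r[d.start]) - (1 if d.one_based else 0)
        end = int(r[d.end])  # 1-based inclusive end == half-open end
        if start >= end:
            n_bad += 1
            log.warning("rejected hybrid row with start >= end: %s", r)
            continue
        count = int(r[d.count]) if d.count and d.count in r and pd.notna(r[d.count]) else 1
        strand = str(r[d.strand]) if d.strand and d.strand in r else "+"
        reads.append(HybridRead(str(r[d.ref]), start, end, str(r[d.mirna]), count, strand))
    log.info("read %d hybrid reads (%d rejected) from %s", len(reads), n_bad, path)
    return reads


def write_hybrid_table(reads: Sequence[HybridRead], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ref": [r.target_ref for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "mirna_id": [r.mirna_id for r in reads],
            "count": [r.count for r in reads],
            "strand": [r.strand for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)
    log.info("wrote %d hybrid reads to %s", len(reads), path)
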