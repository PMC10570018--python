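"""Seeded generator of miRNAs, transcript models, implanted MREs and
CLASH-like hybrid reads, with full ground truth.

The generator emulates processed CLEAR-CLIP input: chimeric reads whose
target fragments cover implanted response elements, truncated by up to
``max_nibble`` nucleotides of nuclease nibbling at each end, duplicated
reads, region labels (5'UTR/CDS/3'UTR/intron) and decoy reads carrying no
implanted site. Background sequence is i.i.d. with a configurable GC
content — no codon structure and no secondary structure, which means
recovery results here bound what the pipeline can do on ideal data, not on
structured real transcripts.

Transcript anatomy: three exons that coincide with the 5'UTR, CDS and
3'UTR, separated by two introns, laid out head-to-tail (with intergenic
gaps) on a single synthetic chromosome; a configurable fraction of
transcripts is placed on the minus strand. Placing the region boundaries
on intron boundaries keeps every implant inside a single exon, so its
genomic interval is contiguous and CLASH fragments cover it exactly.

All randomness flows from one integer seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .duplex import Duplex
from .io import (
    ExonBlock,
    GenomeMapping,
    HybridRead,
    MiRNA,
    TranscriptModel,
    reverse_complement,
)
from .rules import MREClass, RuleSet, build_template_duplex, classify, zone_profile

BASES = np.array(list("ACGU"))
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

#: template name -> miRNA positions left unpaired (callable of miRNA length L)
CLASS_TEMPLATES = {
    "perfect": lambda L: set(),
    "central_bulge_1": lambda L: {12},
    "central_bulge_2": lambda L: {11, 12},
    "central_bulge_4": lambda L: {10, 11, 12, 13},
    "seed_only": lambda L: {1} | set(range(9, L + 1)),
    "seedless_3prime": lambda L: set(range(2, 9)),
    "terminal_mm_2": lambda L: {L - 1, L},
    "terminal_mm_3": lambda L: {L - 2, L - 1, L},
}


def template_expected_class(template: str, L: int, rules: RuleSet = RuleSet()) -> MREClass:
    """Expected classifier output for an implant built from ``template``."""
    dup = build_template_duplex(L, CLASS_TEMPLATES[template](L))
    return classify(zone_profile(dup), rules)


@dataclass(frozen=True)
class ImplantSpec:
    mirna_id: str
    region: str  # CDS | UTR3 | UTR5
    class_template: str
    n_copies: int = 1


@dataclass(frozen=True)
class ReadModel:
    """CLASH read generation parameters."""

    reads_per_implant: int = 5
    fragment_len: tuple[int, int] = (25, 40)  # decoy fragment length range
    max_nibble: int = 3
    duplication_p: float = 0.5  # Geometric(p) duplicate multiplicity, support >= 1
    n_decoy_reads: int = 0
    region_mix: dict[str, float] = field(
        default_factory=lambda: {"UTR3": 0.5, "CDS": 0.3, "UTR5": 0.1, "intron": 0.1}
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic transcriptome and read set."""

    n_transcripts: int = 20
    utr5_len: tuple[int, int] = (60, 200)
    cds_len: tuple[int, int] = (300, 1200)  # forced divisible by 3
    utr3_len: tuple[int, int] = (200, 700)
    intron_len: tuple[int, int] = (80, 200)
    intergenic_len: int = 150
    gc_content: float = 0.45
    minus_strand_fraction: float = 0.3
    n_mirnas: int = 10
    mirna_len: tuple[int, int] = (20, 23)
    implant_spec: tuple[ImplantSpec, ...] = ()
    read_model: ReadModel = field(default_factory=ReadModel)
    seed: int = 0


@dataclass
class SimResult:
    """Simulated data plus ground truth."""

    config: SimConfig
    mirnas: list[MiRNA]
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    implants: pd.DataFrame  # implant_id, transcript_id, region, spliced/genomic intervals, ...

    @property
    def bounds(self) -> dict[str, int]:
        b = {chrom: len(seq) for chrom, seq in self.genome.items()}
        b.update({t.id: len(t.seq) for t in self.transcripts})
        return b

    @property
    def sequences(self) -> dict[str, str]:
        seqs = dict(self.genome)
        seqs.update({t.id: t.seq for t in self.transcripts})
        return seqs


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _mutate_target_base(rng: np.random.Generator, mirna_base: str) -> str:
    """A target base that can neither Watson-Crick nor wobble pair."""
    banned = {_WC[mirna_base], _WOBBLE.get(mirna_base, "")}
    options = [b for b in "ACGU" if b not in banned]
    return options[rng.integers(len(options))]


def implant_site_sequence(rng: np.random.Generator, mirna: MiRNA, template: str) -> str:
    """Target-side sequence of an implanted MRE (5'->3' mRNA orientation).

    Starts from the exact reverse complement and mutates the bases facing
    the template's unpaired miRNA positions. Window offset p (0-based)
    faces miRNA position L-p.
    """
    L = len(mirna)
    unpaired = CLASS_TEMPLATES[template](L)
    site = list(reverse_complement(mirna.seq))
    for mpos in unpaired:
        site[L - mpos] = _mutate_target_base(rng, mirna.seq[mpos - 1])
    return "".join(site)


def simulate_transcriptome(config: SimConfig) -> SimResult:
    """Generate miRNAs, a transcriptome with implanted MREs, and truth.

    Deterministic given ``config.seed``; implants never overlap each other.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = [
        MiRNA(
            f"miR-s{k + 1}",
            _random_seq(rng, int(rng.integers(config.mirna_len[0], config.mirna_len[1] + 1)), 0.5),
        )
        for k in range(config.n_mirnas)
    ]
    by_id = {m.id: m for m in mirnas}

    # region lengths per transcript
    specs = []
    for t in range(config.n_transcripts):
        u5 = int(rng.integers(*config.utr5_len))
        cds = int(rng.integers(*config.cds_len)) // 3 * 3
        u3 = int(rng.integers(*config.utr3_len))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        specs.append((u5, cds, u3, strand))

    # assign implants to transcripts round-robin per spec entry
    implant_rows = []
    placements: dict[int, list[tuple[str, int, str, str]]] = {t: [] for t in range(config.n_transcripts)}
    tx_cycle = 0
    for spec in config.implant_spec:
        if spec.mirna_id not in by_id:
            raise ValueError(f"implant names unknown miRNA {spec.mirna_id!r}")
        for _ in range(spec.n_copies):
            placed = False
            for attempt in range(config.n_transcripts):
                t = (tx_cycle + attempt) % config.n_transcripts
                u5, cds, u3, _ = specs[t]
                region_len = {"UTR5": u5, "CDS": cds, "UTR3": u3}[spec.region]
                L = len(by_id[spec.mirna_id])
                if region_len < L + 2:
                    continue
                lo = int(rng.integers(1, region_len - L))
                # rejection sampling against overlaps within the region
                ok = all(
                    not (lo < s + ln and s < lo + L)
                    for (r, s, ln, _mid, _tm) in placements[t]
                    if r == spec.region
                )
                if not ok:
                    continue
                placements[t].append((spec.region, lo, L, spec.mirna_id, spec.class_template))
                implant_rows.append(
                    {
                        "implant_id": f"imp{len(implant_rows)}",
                        "tx_index": t,
                        "region": spec.region,
                        "region_offset": lo,
                        "mirna_id": spec.mirna_id,
                        "class_template": spec.class_template,
                        "expected_class": template_expected_class(spec.class_template, L).name,
                    }
                )
                placed = True
                break
            if not placed:
                raise ValueError(f"cannot place implant {spec} (regions too small/full)")
            tx_cycle += 1

    # build sequences with implants written in, then lay out the genome
    chrom = "chrS"
    genome_parts: list[str] = []
    gpos = 0
    transcripts: list[TranscriptModel] = []
    for t, (u5, cds, u3, strand) in enumerate(specs):
        L_tx = u5 + cds + u3
        seq = list(_random_seq(rng, L_tx, config.gc_content))
        for region, lo, L, mirna_id, template in placements[t]:
            base = {"UTR5": 0, "CDS": u5, "UTR3": u5 + cds}[region]
            site = implant_site_sequence(rng, by_id[mirna_id], template)
            seq[base + lo : base + lo + L] = list(site)
        seq = "".join(seq)

        genome_parts.append(_random_seq(rng, config.intergenic_len, config.gc_content))
        gpos += config.intergenic_len
        i1 = int(rng.integers(*config.intron_len))
        i2 = int(rng.integers(*config.intron_len))
        # exon pieces in mRNA order: utr5, cds, utr3
        mrna_pieces = [seq[:u5], seq[u5 : u5 + cds], seq[u5 + cds :]]
        if strand == "+":
            genomic_pieces = mrna_pieces
        else:
            genomic_pieces = [reverse_complement(p) for p in reversed(mrna_pieces)]
        blocks = []
        cursor = gpos
        for k, piece in enumerate(genomic_pieces):
            blocks.append(ExonBlock(cursor, cursor + len(piece)))
            genome_parts.append(piece)
            cursor += len(piece)
            if k < 2:
                ilen = (i1, i2)[k]
                genome_parts.append(_random_seq(rng, ilen, config.gc_content))
                cursor += ilen
        gpos = cursor
        transcripts.append(
            TranscriptModel(
                id=f"tx{t}",
                seq=seq,
                utr5=(0, u5),
                cds=(u5, u5 + cds),
                utr3=(u5 + cds, L_tx),
                genome_mapping=GenomeMapping(chrom, strand, tuple(blocks)),
            )
        )
    genome_parts.append(_random_seq(rng, config.intergenic_len, config.gc_content))
    genome = {chrom: "".join(genome_parts)}

    # finalise implant truth with spliced + genomic coordinates
    for r in implant_rows:
        tx = transcripts[r["tx_index"]]
        u5, cds_len = tx.cds[0], tx.cds[1] - tx.cds[0]
        base = {"UTR5": 0, "CDS": u5, "UTR3": u5 + cds_len}[r["region"]]
        L = len(by_id[r["mirna_id"]])
        s_lo = base + r["region_offset"]
        r["transcript_id"] = tx.id
        r["spliced_start"], r["spliced_end"] = s_lo, s_lo + L
        g = _implant_genomic_interval(tx, s_lo, s_lo + L)
        r["chrom"], r["g_start"], r["g_end"] = tx.genome_mapping.chrom, g[0], g[1]
    implants = pd.DataFrame(
        implant_rows,
        columns=[
            "implant_id", "transcript_id", "tx_index", "region", "region_offset",
            "spliced_start", "spliced_end", "chrom", "g_start", "g_end",
            "mirna_id", "class_template", "expected_class",
        ],
    )
    return SimResult(config, mirnas, transcripts, genome, implants)


def _implant_genomic_interval(tx: TranscriptModel, lo: int, hi: int) -> tuple[int, int]:
    gm = tx.genome_mapping
    L = len(tx.seq)
    if gm.strand == "-":
        lo, hi = L - hi, L - lo
    off = 0
    for b in gm.blocks:
        blen = b.end - b.start
        if lo >= off and hi <= off + blen:
            return (b.start + lo - off, b.start + hi - off)
        off += blen
    raise ValueError("implant not contained in a single exon")


def simulate_hybrid_reads(
    sim: SimResult, seed: int | None = None
) -> tuple[list[HybridRead], pd.DataFrame]:
    """Emit CLASH-like hybrid reads (genomic coordinates, with duplicates).

    Implant reads cover the implanted site truncated independently at each
    end by Uniform{0..max_nibble}; each distinct fragment is emitted
    Geometric(duplication_p) times. Decoys are uniform within a region of a
    random transcript, with a random miRNA. Returns (reads, per-read truth).
    """
    rm = sim.config.read_model
    rng = np.random.default_rng(sim.config.seed + 1 if seed is None else seed)
    reads: list[HybridRead] = []
    truth_rows = []

    def dup_count() -> int:
        return int(rng.geometric(rm.duplication_p))

    for r in sim.implants.itertuples(index=False):
        for _ in range(rm.reads_per_implant):
            nl, nr = rng.integers(0, rm.max_nibble + 1, size=2)
            start, end = r.g_start + int(nl), r.g_end - int(nr)
            k = dup_count()
            for _ in range(k):
                reads.append(HybridRead(r.chrom, start, end, r.mirna_id, 1))
                truth_rows.append({"origin": r.implant_id, "region": r.region})

    region_names = list(rm.region_mix)
    probs = np.array([rm.region_mix[n] for n in region_names], dtype=float)
    probs = probs / probs.sum()
    for _ in range(rm.n_decoy_reads):
        region = region_names[rng.choice(len(region_names), p=probs)]
        tx = sim.transcripts[rng.integers(len(sim.transcripts))]
        gm = tx.genome_mapping
        flen = int(rng.integers(*rm.fragment_len))
        if region == "intron":
            introns = [
                (a.end, b.start) for a, b in zip(gm.blocks, gm.blocks[1:]) if a.end < b.start
            ]
            lo, hi = introns[rng.integers(len(introns))]
            if hi - lo <= flen:
                continue
            gs = int(rng.integers(lo, hi - flen))
            ge = gs + flen
        else:
            rlo, rhi = {"UTR5": tx.utr5, "CDS": tx.cds, "UTR3": tx.utr3}[region]
            if rhi - rlo <= flen:
                continue
            slo = int(rng.integers(rlo, rhi - flen))
            pieces = _spliced_piece(tx, slo, slo + flen)
            gs, ge = pieces
        mirna = sim.mirnas[rng.integers(len(sim.mirnas))]
        k = dup_count()
        for _ in range(k):
            reads.append(HybridRead(gm.chrom, gs, ge, mirna.id, 1))
            truth_rows.append({"origin": "decoy", "region": region})

    truth = pd.DataFrame(truth_rows, columns=["origin", "region"])
    return reads, truth


def _spliced_piece(tx: TranscriptModel, lo: int, hi: int) -> tuple[int, int]:
    """Genomic interval of a spliced interval contained in one exon region."""
    return _implant_genomic_interval(tx, lo, hi)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def scan_recovery(sites: pd.DataFrame, sim: SimResult, scannable_templates=("perfect",)) -> dict:
    """Sensitivity and false-discovery proportion of the scanner vs truth.

    A truth implant counts as recovered when a reported site matches its
    transcript, interval and miRNA. Sites matching no implant at all are
    false discoveries.
    """
    truth = sim.implants
    expected = truth[truth.class_template.isin(scannable_templates)]
    implant_keys = {
        (r.transcript_id, r.spliced_start, r.spliced_end, r.mirna_id)
        for r in truth.itertuples(index=False)
    }
    expected_keys = {
        (r.transcript_id, r.spliced_start, r.spliced_end, r.mirna_id)
        for r in expected.itertuples(index=False)
    }
    found_keys = (
        {
            (r.transcript_id, r.start, r.end, r.mirna_id)
            for r in sites.itertuples(index=False)
        }
        if len(sites)
        else set()
    )
    tp = len(expected_keys & found_keys)
    fp = len(found_keys - implant_keys)
    sensitivity = tp / len(expected_keys) if expected_keys else float("nan")
    fdp = fp / len(found_keys) if found_keys else 0.0
    return {"sensitivity": sensitivity, "n_false_sites": fp, "fdp": fdp,
            "n_expected": len(expected_keys), "n_found": len(found_keys)}


def region_fraction_error(summary: pd.Series, mix: dict[str, float]) -> float:
    """Max absolute deviation of recovered region fractions from the mix."""
    total = sum(mix.values())
    return max(abs(summary.get(r, 0.0) - mix[r] / total) for r in mix)


def implant_classes(sim: SimResult) -> pd.DataFrame:
    """Re-derive each implant's MRE class from its sequence context.

    Profiles the in-register gapless duplex over the implanted interval
    (the register is ground truth here, as it is for scanner hits); free
    refolding is not used because it can slip around engineered central
    bulges. Returns implant_id + class.
    """
    from .scan import site_duplex

    by_tx = {t.id: t for t in sim.transcripts}
    by_mi = {m.id: m for m in sim.mirnas}
    rows = []
    for r in sim.implants.itertuples(index=False):
        window = by_tx[r.transcript_id].seq[r.spliced_start : r.spliced_end]
        dup = site_duplex(by_mi[r.mirna_id], window, r.transcript_id, r.spliced_start)
        rows.append({"implant_id": r.implant_id, "class": classify(zone_profile(dup)).name})
    return pd.DataFrame(rows, columns=["implant_id", "class"])


def class_confusion(sim: SimResult, predicted: pd.DataFrame | None = None) -> pd.DataFrame:
    """Confusion matrix of expected vs re-derived MRE class per implant.

    ``predicted`` (implant_id + class) defaults to :func:`implant_classes`.
    """
    if predicted is None:
        predicted = implant_classes(sim)
    merged = sim.implants.merge(predicted, on="implant_id")
    return pd.crosstab(merged.expected_class, merged["class"])
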