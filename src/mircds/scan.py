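"""Transcriptome-wide scan for extensively complementary miRNA sites.

Algorithm: exact string matching of the reverse complement of the miRNA
anchor (nt 2-12 by default, an 11-mer) within the selected transcript
region(s), followed by gapless antiparallel extension over the full miRNA
and mismatch counting outside the anchor. No bulges are considered here —
bulged interfaces are the duplex module's job. Sites whose extension would
overhang the transcript are discarded (their pairing is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .duplex import Duplex, emit_dot_bracket
from .io import MiRNA, TranscriptModel, reverse_complement
from .rules import MREClass, RuleSet, classify, zone_profile

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration.

    ``max_mismatches_rest`` is the mismatch budget outside the anchor
    (settings 2 and 3 are the reported operating points);
    ``require_3prime_terminal_3`` additionally demands perfect pairing of
    the three 3'-terminal miRNA nucleotides. GU wobble outside the anchor
    counts as a match by default; the anchor itself is strict Watson-Crick.
    """

    anchor_range: tuple[int, int] = (2, 12)
    max_mismatches_rest: int = 2
    require_3prime_terminal_3: bool = False
    regions: tuple[str, ...] = ("CDS",)
    mirna_allowlist: frozenset[str] | None = None
    gu_is_match: bool = True

    def validate(self, mirna_len: int) -> None:
        lo, hi = self.anchor_range
        if not (1 <= lo <= hi <= mirna_len):
            raise ValueError(f"anchor range {self.anchor_range} outside 1..{mirna_len}")
        if self.max_mismatches_rest < 0:
            raise ValueError("mismatch budget must be >= 0")
        for r in self.regions:
            if r not in ("CDS", "UTR3"):
                raise ValueError(f"unknown region {r!r}")


@dataclass(frozen=True)
class CandidateSite:
    """One extensively complementary candidate site."""

    mirna_id: str
    transcript_id: str
    region: str
    start: int  # on the spliced sequence, 0-based half-open
    end: int
    mismatch_positions: tuple[int, ...]  # miRNA positions, 1-based
    duplex: Duplex
    mre_class: MREClass


def site_duplex(mirna: MiRNA, window: str, tx_id: str = "", start: int = 0) -> Duplex:
    """Gapless antiparallel in-register duplex over a full-length site.

    Window offset p (0-based) faces miRNA position L-p; every WC or GU
    combination is paired, everything else is a mismatch. This is the
    interface on which candidate sites (and implanted MREs, whose register
    is known) are profiled and classified; free refolding of a window can
    slip around an engineered central bulge, which the fixed register
    deliberately does not.
    """
    L = len(mirna)
    pairs = []
    for p in range(L):
        mpos = L - p
        qb, tb = mirna.seq[mpos - 1], window[p]
        if _WC[qb] == tb or (qb, tb) in _GU:
            pairs.append((mpos, p + 1))
    return Duplex(
        mirna_id=mirna.id,
        target_window=(tx_id, start, start + L),
        pairs=frozenset(pairs),
        dot_bracket=emit_dot_bracket(pairs, L, L),
        score=float(len(pairs)),
        len_mirna=L,
        len_target=L,
    )


def scan_transcript(
    mirna: MiRNA, tx: TranscriptModel, params: ScanParams = ScanParams()
) -> list[CandidateSite]:
    """Anchor-and-extend scan of one transcript for one miRNA.

    Overlapping sites found from distinct anchor occurrences are reported
    separately. The anchor must lie entirely within the selected region;
    the gapless extension may spill into a neighbouring region, in which
    case the site is labelled by the UTR3-first priority rule. An empty
    region (e.g. CDS scan of a non-coding transcript) yields an empty
    result.
    """
    params.validate(len(mirna))
    L = len(mirna)
    rc = reverse_complement(mirna.seq)
    a_lo, a_hi = params.anchor_range
    # rc offset p corresponds to miRNA position L - p (0-based p)
    anc_rc_start, anc_rc_end = L - a_hi, L - a_lo + 1
    anchor_probe = rc[anc_rc_start:anc_rc_end]
    out: list[CandidateSite] = []
    for region in params.regions:
        lo, hi = {"CDS": tx.cds, "UTR3": tx.utr3}[region]
        if hi - lo < len(anchor_probe):
            continue
        pos = tx.seq.find(anchor_probe, lo, hi)
        while pos != -1:
            site_start = pos - anc_rc_start  # spliced offset of miRNA nt L
            if 0 <= site_start and site_start + L <= len(tx.seq):
                window = tx.seq[site_start : site_start + L]
                mismatches = []
                for p in range(L):
                    mpos = L - p
                    if a_lo <= mpos <= a_hi:
                        continue
                    qb, tb = mirna.seq[mpos - 1], window[p]
                    if _WC[qb] == tb:
                        continue
                    if params.gu_is_match and (qb, tb) in _GU:
                        continue
                    mismatches.append(mpos)
                mismatches.sort()
                keep = len(mismatches) <= params.max_mismatches_rest
                if keep and params.require_3prime_terminal_3:
                    keep = all(mp <= L - 3 for mp in mismatches)
                if keep:
                    dup = site_duplex(mirna, window, tx.id, site_start)
                    label = _site_region_label(tx, site_start, site_start + L, region)
                    out.append(
                        CandidateSite(
                            mirna_id=mirna.id,
                            transcript_id=tx.id,
                            region=label,
                            start=site_start,
                            end=site_start + L,
                            mismatch_positions=tuple(mismatches),
                            duplex=dup,
                            mre_class=classify(zone_profile(dup)),
                        )
                    )
            pos = tx.seq.find(anchor_probe, pos + 1, hi)
    return out


def _site_region_label(tx: TranscriptModel, start: int, end: int, anchor_region: str) -> str:
    """UTR3-first priority label for a site that may straddle a boundary."""
    if tx.utr3[1] > tx.utr3[0] and start < tx.utr3[1] and end > tx.utr3[0]:
        return "UTR3"
    return anchor_region


def scan_transcriptome(
    mirnas: list[MiRNA],
    transcripts: list[TranscriptModel],
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Scan every (miRNA, transcript) pair; one row per candidate site."""
    allow = params.mirna_allowlist
    rows = []
    for mi in mirnas:
        if allow is not None and mi.id not in allow:
            continue
        for tx in transcripts:
            for site in scan_transcript(mi, tx, params):
                rows.append(
                    {
                        "mirna_id": site.mirna_id,
                        "transcript_id": site.transcript_id,
                        "region": site.region,
                        "start": site.start,
                        "end": site.end,
                        "n_mismatches": len(site.mismatch_positions),
                        "mismatch_positions": ",".join(map(str, site.mismatch_positions)),
                        "dot_bracket": site.duplex.dot_bracket,
                        "class": site.mre_class.name,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "transcript_id", "region", "start", "end",
            "n_mismatches", "mismatch_positions", "dot_bracket", "class",
        ],
    )


def scan_summary(
    mirnas: list[MiRNA],
    transcripts: list[TranscriptModel],
    params: ScanParams = ScanParams(),
    budgets: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Candidate counts over the budget x 3'-terminal-requirement grid."""
    rows = []
    for budget in budgets:
        for req3p in (True, False):
            p = replace(params, max_mismatches_rest=budget, require_3prime_terminal_3=req3p)
            n = len(scan_transcriptome(mirnas, transcripts, p))
            rows.append(
                {"max_mismatches_rest": budget, "require_3prime_terminal_3": req3p, "n_sites": n}
            )
    return pd.DataFrame(rows)
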