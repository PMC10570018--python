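"""Independent reference implementations used for validation.

These are deliberately naive — exhaustive enumeration and all-windows
sliding — and share no code with the optimised paths they check. They are
used by the test suite and the acceptance script, not by the pipelines.
"""

from __future__ import annotations

from itertools import combinations

from .duplex import ScoringParams
from .io import MiRNA


def score_pairing(
    pairs: list[tuple[int, int]], q: str, t: str, scoring: ScoringParams
) -> float | None:
    """Score an explicit pairing under the default duplex model.

    ``pairs`` are 1-based (miRNA pos, target pos). Returns None when the
    pairing is invalid: crossing, non-pairable bases, or any helix shorter
    than ``scoring.min_helix``.
    """
    if not pairs:
        return 0.0
    ps = sorted(pairs)
    score = 0.0
    # pairability and antiparallel non-crossing
    for k, (i, j) in enumerate(ps):
        w = scoring.pair_weight(q[i - 1], t[j - 1])
        if w is None:
            return None
        if k > 0 and j >= ps[k - 1][1]:
            return None
        score += w
    # helix lengths and interior loops
    helix = 1
    for k in range(1, len(ps)):
        i0, j0 = ps[k - 1]
        i1, j1 = ps[k]
        a, b = i1 - i0 - 1, j0 - j1 - 1
        if a == 0 and b == 0:
            helix += 1
        else:
            if helix < scoring.min_helix:
                return None
            helix = 1
            score -= scoring.gap_open + scoring.gap_extend * (a + b - 1)
    if helix < scoring.min_helix:
        return None
    return score


def best_pairing_bruteforce(
    mirna: MiRNA | str, window: str, scoring: ScoringParams = ScoringParams()
) -> tuple[float, int]:
    """Exhaustive enumeration over all non-crossing intermolecular pairings.

    Feasible only for short sequences (both lengths <= ~8). Returns
    (best score, paired bases of a best pairing maximising paired bases).
    """
    q = mirna if isinstance(mirna, str) else mirna.seq
    m, n = len(q), len(window)
    t = window
    best = (0.0, 0)
    for k in range(1, min(m, n) + 1):
        for qs in combinations(range(1, m + 1), k):
            for ts in combinations(range(1, n + 1), k):
                # antiparallel: ascending miRNA positions pair descending target
                pairs = list(zip(qs, reversed(ts)))
                s = score_pairing(pairs, q, t, scoring)
                if s is not None and (s, k) > best:
                    best = (s, k)
    return best


def scan_windows_naive(
    mirna: MiRNA | str,
    seq: str,
    region_interval: tuple[int, int] | None = None,
    anchor_range: tuple[int, int] = (2, 12),
    max_mismatches_rest: int = 2,
    require_3prime_terminal_3: bool = False,
    gu_is_match: bool = True,
) -> list[tuple[int, tuple[int, ...]]]:
    """All-windows scan for extensively complementary sites.

    Tests every length-L window of ``seq`` against the miRNA in
    antiparallel orientation: window position p (0-based) faces miRNA
    position L-p (1-based). A window qualifies when the bases facing the
    anchor positions are all Watson-Crick paired, the anchor lies within
    ``region_interval`` (whole sequence when None), and the mismatch count
    elsewhere is within budget. Returns [(window start, mismatch positions)].
    """
    q = mirna if isinstance(mirna, str) else mirna.seq
    L = len(q)
    a_lo, a_hi = anchor_range
    r_lo, r_hi = region_interval if region_interval is not None else (0, len(seq))
    wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
    out = []
    for s in range(0, len(seq) - L + 1):
        # anchor occupies window offsets L-a_hi .. L-a_lo
        if not (r_lo <= s + L - a_hi and s + L - a_lo + 1 <= r_hi):
            continue
        window = seq[s : s + L]
        mismatches = []
        ok = True
        for p in range(L):
            mpos = L - p  # 1-based miRNA position facing window offset p
            tb, qb = window[p], q[mpos - 1]
            is_wc = wc[qb] == tb
            is_gu = (qb, tb) in (("G", "U"), ("U", "G"))
            if a_lo <= mpos <= a_hi:
                if not is_wc:  # no wobble inside the anchor
                    ok = False
                    break
            elif not (is_wc or (gu_is_match and is_gu)):
                mismatches.append(mpos)
        if not ok or len(mismatches) > max_mismatches_rest:
            continue
        if require_3prime_terminal_3 and any(mp > L - 3 for mp in mismatches):
            continue
        out.append((s, tuple(sorted(mismatches))))
    return out
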