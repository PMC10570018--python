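"""Intermolecular miRNA:target duplex prediction.

The default engine is a self-contained dynamic program over antiparallel,
non-crossing base pairings between a miRNA (5'->3') and a target window
(5'->3'). Scoring is a dimensionless integer model: per-pair weights
(GC=3, AU=2, GU=1), an affine penalty for interior loops/bulges
(open + extend * (loop_len - 1)), free dangling ends, and a minimum helix
length of 2 stacked pairs (no isolated pairs). Higher scores are better.

An adapter mode (:func:`parse_dot_bracket`, :func:`duplex_from_dot_bracket`)
ingests two-part dot-bracket output (e.g. from RNAduplex) together with its
free energy; in that mode lower (kcal/mol) is more stable. The two score
conventions are never mixed within one analysis. Downstream classification
consumes only the pairing map, which both modes provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import MiRNA, RNA_ALPHABET, _check_rna

NEG = float("-inf")

#: default pair weights; keys are unordered base pairs
DEFAULT_WEIGHTS = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}


@dataclass(frozen=True)
class ScoringParams:
    """Integer scoring parameters for the default duplex model."""

    gc: int = 3
    au: int = 2
    gu: int = 1  # 0 disallows the wobble pair entirely
    gap_open: int = 2
    gap_extend: int = 1
    min_helix: int = 2

    def pair_weight(self, a: str, b: str) -> int | None:
        """Weight of pairing bases a, b; None if they cannot pair."""
        key = a + b
        if key in ("GC", "CG"):
            return self.gc
        if key in ("AU", "UA"):
            return self.au
        if key in ("GU", "UG"):
            return self.gu if self.gu > 0 else None
        return None


@dataclass(frozen=True)
class Duplex:
    """A predicted intermolecular pairing between one miRNA and one window.

    ``pairs`` holds (miRNA position, target position), both 1-based from the
    respective 5' ends. Pairing is antiparallel and non-crossing: as the
    miRNA position increases the target position strictly decreases.
    """

    mirna_id: str
    target_window: tuple[str, int, int]
    pairs: frozenset[tuple[int, int]]
    dot_bracket: str
    score: float
    len_mirna: int
    len_target: int

    @property
    def paired_mirna_positions(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.pairs)

    def target_partner(self, mirna_pos: int) -> int | None:
        for i, j in self.pairs:
            if i == mirna_pos:
                return j
        return None


def emit_dot_bracket(pairs, len_mirna: int, len_target: int) -> str:
    q = ["."] * len_mirna
    t = ["."] * len_target
    for i, j in pairs:
        q[i - 1] = "("
        t[j - 1] = ")"
    return "".join(q) + "&" + "".join(t)


def parse_dot_bracket(db: str, len_mirna: int, len_target: int) -> frozenset[tuple[int, int]]:
    """Invert two-part dot-bracket notation into 1-based index pairs.

    The k-th '(' of the query part pairs with the (N+1-k)-th ')' of the
    target part (last-open/first-close intermolecular matching).
    """
    if db.count("&") != 1:
        raise ValueError("dot-bracket must contain exactly one '&'")
    qpart, tpart = db.split("&")
    if len(qpart) != len_mirna or len(tpart) != len_target:
        raise ValueError(
            f"dot-bracket part lengths ({len(qpart)},{len(tpart)}) "
            f"do not match sequences ({len_mirna},{len_target})"
        )
    if ")" in qpart or "(" in tpart:
        raise ValueError("intramolecular pairs are out of model")
    opens = [k + 1 for k, c in enumerate(qpart) if c == "("]
    closes = [k + 1 for k, c in enumerate(tpart) if c == ")"]
    if len(opens) != len(closes):
        raise ValueError("unbalanced brackets across the two parts")
    return frozenset(zip(opens, reversed(closes)))


def pad_dot_bracket(
    db: str, q_interval: tuple[int, int], t_interval: tuple[int, int],
    len_mirna: int, len_target: int,
) -> str:
    """Pad an interval-scoped two-part dot-bracket to full-length parts.

    RNAduplex prints the structure only over the paired sub-intervals
    (1-based, inclusive) of each sequence; this restores the full-length
    notation expected by :func:`parse_dot_bracket`.
    """
    qpart, tpart = db.split("&")
    (qi, qj), (ti, tj) = q_interval, t_interval
    q_full = "." * (qi - 1) + qpart + "." * (len_mirna - qj)
    t_full = "." * (ti - 1) + tpart + "." * (len_target - tj)
    return q_full + "&" + t_full


def duplex_from_dot_bracket(
    mirna: MiRNA, window: str, db: str, energy: float, ref: str = "", start: int = 0
) -> Duplex:
    """Adapter mode: wrap externally predicted structure + free energy."""
    pairs = parse_dot_bracket(db, len(mirna), len(window))
    return Duplex(
        mirna_id=mirna.id,
        target_window=(ref, start, start + len(window)),
        pairs=pairs,
        dot_bracket=db,
        score=energy,
        len_mirna=len(mirna),
        len_target=len(window),
    )


def _encode(score: int, npaired: int) -> int:
    # lexicographic (score, npaired) in one int; npaired < 64 always
    return score * 64 + npaired


def predict_duplex(
    mirna: MiRNA | str,
    target_window: str,
    scoring: ScoringParams = ScoringParams(),
    ref: str = "",
    start: int = 0,
) -> Duplex:
    """Maximum-score non-crossing intermolecular pairing by dynamic programming.

    ``mirna`` may be a :class:`~mircds.io.MiRNA` or a bare RNA string (the
    latter gets query id "query"; useful for arbitrary-length probes).

    Deterministic tie-break: among equal-score pairings prefer the one pairing
    more miRNA bases, then the one whose paired target region starts 5'-most.

    Runs in O(len(miRNA) * len(window)) via 2D prefix maxima over
    gap-adjusted helix scores.
    """
    if isinstance(mirna, str):
        _check_rna(mirna, "query")
        qid, q = "query", mirna
    else:
        qid, q = mirna.id, mirna.seq
    window = target_window.upper().replace("T", "U")
    _check_rna(window, "target window")
    if len(window) < 4:
        raise ValueError("target window shorter than 4 nt")
    m, n = len(q), len(window)
    t = window
    open64 = scoring.gap_open * 64
    ext64 = scoring.gap_extend * 64
    minh = scoring.min_helix
    if minh not in (1, 2):
        raise ValueError("min_helix must be 1 or 2")

    # E: helix of length 1 ending at (i,j) (only if minh == 2); F: helix done.
    E = [[None] * n for _ in range(m)]
    F = [[None] * n for _ in range(m)]
    Eparent = [[None] * n for _ in range(m)]
    Fparent = [[None] * n for _ in range(m)]
    # P[i][j]: max over i'<=i, j'>=j of G[i'][j'] with argmax; G = F + ext64*(i'-j')
    P = [[(NEG, -1, -1)] * (n + 1) for _ in range(m)]

    for i in range(m):
        for j in range(n - 1, -1, -1):
            w = scoring.pair_weight(q[i], t[j])
            if w is not None:
                w64 = _encode(w, 1)
                # -- start of a new helix (state E, or F when minh == 1)
                best_loop = (NEG, None)
                # region excluding the stacked-adjacent corner (i-1, j+1)
                cand = []
                if i >= 2 and j + 1 <= n:
                    cand.append(P[i - 2][j + 1])
                if i >= 1 and j + 2 <= n:
                    cand.append(P[i - 1][j + 2])
                if cand:
                    g, ai, aj = max(cand, key=lambda x: x[0])
                    if g > NEG:
                        val = w64 + g - open64 - ext64 * (i - j - 3)
                        best_loop = (val, ("loop", ai, aj))
                first = (w64, ("first",))
                e_val, e_par = max(best_loop, first, key=lambda x: x[0])
                # -- extend an existing helix (state F)
                f_val, f_par = NEG, None
                if i >= 1 and j + 1 < n:
                    for src, arr in (("E", E), ("F", F)):
                        prev = arr[i - 1][j + 1]
                        if prev is not None and w64 + prev > f_val:
                            f_val, f_par = w64 + prev, ("stack", src)
                if minh == 1:
                    # no isolated-pair ban: E collapses into F
                    if e_val > f_val:
                        f_val, f_par = e_val, e_par
                    e_val, e_par = NEG, None
                if e_val > NEG:
                    E[i][j], Eparent[i][j] = e_val, e_par
                if f_val > NEG:
                    F[i][j], Fparent[i][j] = f_val, f_par
            # update prefix max of G over completed helices
            g_here = (NEG, -1, -1)
            if F[i][j] is not None:
                g_here = (F[i][j] + ext64 * (i - j), i, j)
            up = P[i - 1][j] if i >= 1 else (NEG, -1, -1)
            right = P[i][j + 1]
            P[i][j] = max(g_here, up, right, key=lambda x: x[0])

    # final: best completed helix end; prefer smaller j (5'-most target start)
    best_val, best_ij = 0, None
    for i in range(m):
        for j in range(n):
            v = F[i][j]
            if v is not None and (v > best_val or (v == best_val and best_ij and j < best_ij[1])):
                best_val, best_ij = v, (i, j)

    pairs: set[tuple[int, int]] = set()
    state, ij = "F", best_ij
    while ij is not None:
        i, j = ij
        pairs.add((i + 1, j + 1))
        par = (Fparent if state == "F" else Eparent)[i][j]
        if par[0] == "stack":
            state, ij = par[1], (i - 1, j + 1)
        elif par[0] == "loop":
            state, ij = "F", (par[1], par[2])
        else:  # first
            ij = None

    score = best_val // 64 if best_ij is not None else 0
    return Duplex(
        mirna_id=qid,
        target_window=(ref, start, start + n),
        pairs=frozenset(pairs),
        dot_bracket=emit_dot_bracket(pairs, m, n),
        score=float(score),
        len_mirna=m,
        len_target=n,
    )


def pairing_vector(duplex: Duplex, anchor: str, width: int) -> list[bool]:
    """Project a duplex onto a fixed-width per-position pairing vector.

    ``five_prime``: slot k (1-based) is True iff miRNA position k is paired.
    ``three_prime``: the same information right-aligned, slot width-L+k for
    miRNA position k. Slots beyond the miRNA are False.
    """
    L = duplex.len_mirna
    if width < L:
        raise ValueError(f"width {width} < miRNA length {L}")
    vec = [False] * width
    offset = 0 if anchor == "five_prime" else width - L
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    for i in duplex.paired_mirna_positions:
        vec[offset + i - 1] = True
    return vec
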