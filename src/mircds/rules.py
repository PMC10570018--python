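"""Per-zone pairing summaries and the MRE functionality classifier.

The miRNA binding interface is summarised over four named zones: the seed
(nt 2-8), the seed+cleavage region (nt 2-12), the central region (nt 9-12),
the supplementary region (nt 13-17) and the three 3'-terminal nucleotides.
A rule set derived from reporter dose-response experiments maps the zone
profile onto a functional class:

SLICING        full, contiguous pairing across nt 2-12 (licenses AGO2
               cleavage) with at most ``max_outside_mismatches`` elsewhere
REPRESSIVE     contiguous seed pairing, central disruption of at most 1 nt,
               mismatch budget met
WEAK           seed paired but a central bulge at the "severely reduced"
               threshold (default 2 nt)
NONFUNCTIONAL  any seed imperfection (including a target-side insertion
               within the seed), a central bulge at/over the dead threshold
               (default 3 nt), or a blown mismatch budget

Thresholds are configurable because the underlying evidence is a
dose-response, not a sharp cut-off.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .duplex import Duplex, emit_dot_bracket
from .io import (
    MiRNA,
    SEED_RANGE,
    SEED_CLEAVE_RANGE,
    CENTRAL_RANGE,
    SUPPLEMENTARY_RANGE,
)


class MREClass(enum.Enum):
    """Functional class of a miRNA response element, ranked by potency."""

    NONFUNCTIONAL = 0
    WEAK = 1
    REPRESSIVE = 2
    SLICING = 3

    @property
    def rank(self) -> int:
        return self.value

    @property
    def repressed(self) -> bool:
        """Whether a reporter bearing this site shows repression."""
        return self.value >= MREClass.WEAK.value


@dataclass(frozen=True)
class RuleSet:
    """Classifier thresholds with reporter-derived defaults."""

    max_outside_mismatches: int = 3
    central_bulge_weak: int = 2
    central_bulge_dead: int = 3
    require_three_prime_terminal: bool = False

    def __post_init__(self) -> None:
        if not self.central_bulge_weak < self.central_bulge_dead:
            raise ValueError("central_bulge_weak must be < central_bulge_dead")


@dataclass(frozen=True)
class ZoneProfile:
    """Per-zone pairing statistics of one duplex (miRNA side)."""

    seed_paired: bool
    seed_cleave_paired: bool
    central_bulge: int
    supp_paired_count: int
    three_prime_terminal_paired: bool
    total_mismatches: int
    interface_mismatches_outside_2_12: int
    supp_truncated: bool = False


def _contiguous(partner: dict[int, int], lo: int, hi: int) -> bool:
    """All of miRNA nt lo..hi paired, with strictly consecutive target bases."""
    if any(i not in partner for i in range(lo, hi + 1)):
        return False
    return all(partner[i + 1] == partner[i] - 1 for i in range(lo, hi))


def zone_profile(duplex: Duplex, mirna: MiRNA | None = None) -> ZoneProfile:
    """Summarise a duplex into per-zone pairing statistics.

    Target-side insertions are assigned to the zone of their flanking
    pairs: an insertion is charged to the central bulge when its
    5'-flanking pair lies at nt 8-11 (entering or inside the central
    region). Insertions within the seed break seed contiguity instead,
    and an insertion 3' of the nt-12 pair belongs to the supplementary
    interface, so full contiguous nt 2-12 pairing always implies a central
    bulge of zero.
    """
    L = duplex.len_mirna
    if mirna is not None and len(mirna) != L:
        raise ValueError("duplex does not belong to this miRNA")
    partner = {i: j for i, j in duplex.pairs}

    c_lo, c_hi = CENTRAL_RANGE
    bulge = sum(1 for i in range(c_lo, c_hi + 1) if i not in partner)
    paired = sorted(partner)
    for a, b in zip(paired, paired[1:]):
        inserted = partner[a] - partner[b] - 1 - (b - a - 1)
        if inserted > 0 and c_lo - 1 <= a <= c_hi - 1:
            bulge += inserted

    s_lo, s_hi = SUPPLEMENTARY_RANGE
    supp_hi = min(s_hi, L)
    mismatch_positions = [i for i in range(1, L + 1) if i not in partner]
    return ZoneProfile(
        seed_paired=_contiguous(partner, *SEED_RANGE),
        seed_cleave_paired=_contiguous(partner, *SEED_CLEAVE_RANGE),
        central_bulge=bulge,
        supp_paired_count=sum(1 for i in range(s_lo, supp_hi + 1) if i in partner),
        three_prime_terminal_paired=all(i in partner for i in range(L - 2, L + 1)),
        total_mismatches=len(mismatch_positions),
        interface_mismatches_outside_2_12=sum(
            1 for i in mismatch_positions if i < SEED_CLEAVE_RANGE[0] or i > SEED_CLEAVE_RANGE[1]
        ),
        supp_truncated=L < s_hi,
    )


def classify(profile: ZoneProfile, rules: RuleSet = RuleSet()) -> MREClass:
    """Assign the functional class implied by a zone profile. Total function."""
    if rules.require_three_prime_terminal and not profile.three_prime_terminal_paired:
        return MREClass.NONFUNCTIONAL
    if profile.interface_mismatches_outside_2_12 > rules.max_outside_mismatches:
        return MREClass.NONFUNCTIONAL
    if profile.seed_cleave_paired:
        return MREClass.SLICING
    if not profile.seed_paired:
        return MREClass.NONFUNCTIONAL
    if profile.central_bulge < rules.central_bulge_weak:
        return MREClass.REPRESSIVE
    if profile.central_bulge < rules.central_bulge_dead:
        return MREClass.WEAK
    return MREClass.NONFUNCTIONAL


def classify_duplex(duplex: Duplex, rules: RuleSet = RuleSet()) -> MREClass:
    return classify(zone_profile(duplex), rules)


# ---------------------------------------------------------------------------
# Binding-model fixture
# ---------------------------------------------------------------------------

def build_template_duplex(
    length: int,
    unpaired: frozenset[int] | set[int] = frozenset(),
    insertions: dict[int, int] | None = None,
    mirna_id: str = "template",
) -> Duplex:
    """Construct the duplex implied by a binding-model diagram.

    Starts from a fully antiparallel-paired L-mer and introduces
    mismatches (``unpaired`` miRNA positions, each still consuming one
    target base) and target-side insertions (``insertions[i]`` extra
    target bases between the partners of miRNA nt i and i+1).
    """
    insertions = insertions or {}
    len_target = length + sum(insertions.values())
    pairs = []
    tpos = len_target
    for i in range(1, length + 1):
        if i not in unpaired:
            pairs.append((i, tpos))
        tpos -= 1
        tpos -= insertions.get(i, 0)
    return Duplex(
        mirna_id=mirna_id,
        target_window=("template", 0, len_target),
        pairs=frozenset(pairs),
        dot_bracket=emit_dot_bracket(pairs, length, len_target),
        score=float(len(pairs)),
        len_mirna=length,
        len_target=len_target,
    )


def _parse_intlist(s: str) -> set[int]:
    s = str(s).strip()
    return set() if s in ("", "-", "nan") else {int(x) for x in s.split(",")}


def _parse_insertions(s: str) -> dict[int, int]:
    s = str(s).strip()
    if s in ("", "-", "nan"):
        return {}
    return {int(k): int(v) for k, v in (kv.split(":") for kv in s.split(","))}


def load_binding_model_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged reporter binding-model table (or a user TSV)."""
    if path is None:
        with resources.files("mircds.data").joinpath("binding_models.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t", dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def fixture_validation(
    fixture: pd.DataFrame | None = None, rules: RuleSet = RuleSet()
) -> pd.DataFrame:
    """Check the classifier against the reporter binding-model fixture.

    Each row names a binding model, its pairing-pattern template and the
    expected outcome ("repressed", "weak" or "not_repressed"). Returns the
    table with predicted class and an ``agree`` column; disagreements keep
    their model name for reporting.
    """
    if fixture is None:
        fixture = load_binding_model_fixture()
    rows = []
    for r in fixture.itertuples(index=False):
        dup = build_template_duplex(
            int(r.length), _parse_intlist(r.unpaired), _parse_insertions(r.insertions),
            mirna_id=r.model,
        )
        cls = classify(zone_profile(dup), rules)
        predicted = (
            "weak" if cls is MREClass.WEAK
            else "repressed" if cls.repressed
            else "not_repressed"
        )
        rows.append(
            {
                "model": r.model,
                "expected": r.expected,
                "class": cls.name,
                "predicted": predicted,
                "agree": predicted == r.expected,
            }
        )
    return pd.DataFrame(rows)
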