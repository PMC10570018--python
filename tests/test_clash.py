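import dataclasses
import random

import numpy as np
import pytest

from mircds.clash import (
    RegionIndex,
    annotate_hybrids,
    annotate_region,
    collapse_duplicates,
    expand_intervals,
    hybrid_duplexes,
    pairing_matrices,
    region_summary,
)
from mircds.io import HybridRead, MiRNA, reverse_complement
from mircds.rules import build_template_duplex
from mircds.simulate import (
    ImplantSpec,
    ReadModel,
    SimConfig,
    region_fraction_error,
    simulate_hybrid_reads,
    simulate_transcriptome,
)

from conftest import make_transcript, random_rna


class TestExpandIntervals:
    def test_pad_three(self):
        (r,) = expand_intervals([HybridRead("chr1", 100, 130, "m")], pad=3)
        assert (r.start, r.end) == (97, 133)

    def test_clamped_at_reference_bounds(self):
        (r,) = expand_intervals(
            [HybridRead("chr1", 1, 10, "m")], pad=3, bounds={"chr1": 11}
        )
        assert (r.start, r.end) == (0, 11)

    def test_pad_zero_identity(self):
        reads = [HybridRead("chr1", 5, 25, "m", 2)]
        out = expand_intervals(reads, pad=0)
        assert (out[0].start, out[0].end, out[0].count) == (5, 25, 2)

    def test_unknown_reference_dropped(self):
        out = expand_intervals(
            [HybridRead("chrX", 5, 25, "m")], pad=3, bounds={"chr1": 100}
        )
        assert out == []


class TestAnnotateRegion:
    @pytest.fixture
    def index(self, rng):
        seq = random_rna(rng, 600)
        tx = make_transcript("txA", seq, 120, 300)  # utr5 [0,120) cds [120,420) utr3 [420,600)
        return RegionIndex([tx])

    def test_read_inside_cds(self, index):
        h = annotate_region(HybridRead("txA", 200, 230, "m"), index)
        assert h.region == "CDS" and "exonic" in h.overlap_flags

    def test_cds_utr3_overlap_takes_utr3_priority(self, index):
        h = annotate_region(HybridRead("txA", 410, 440, "m"), index)
        assert h.region == "UTR3"
        assert {"exonic", "utr3"} <= h.overlap_flags

    def test_utr5_overlap(self, index):
        h = annotate_region(HybridRead("txA", 100, 130, "m"), index)
        assert h.region == "UTR5"

    def test_no_overlap_discarded_intergenic(self, index):
        h = annotate_region(HybridRead("chrZ", 0, 30, "m"), index)
        assert h.region == "discarded_intergenic"

    def test_intronic_read_on_genome(self):
        sim = simulate_transcriptome(SimConfig(n_transcripts=3, n_mirnas=2, seed=9))
        index = RegionIndex(sim.transcripts)
        gm = sim.transcripts[0].genome_mapping
        intron_start = gm.blocks[0].end
        h = annotate_region(HybridRead(gm.chrom, intron_start + 5, intron_start + 30, "m"), index)
        assert h.region == "intron"


class TestCollapse:
    def test_identical_reads_collapsed_with_counts(self):
        reads = [HybridRead("c", 10, 40, "m1")] * 3 + [HybridRead("c", 50, 80, "m1")]
        out = collapse_duplicates(reads)
        assert [(r.start, r.count) for r in out] == [(10, 3), (50, 1)]

    def test_total_count_conserved(self, rng):
        reads = [
            HybridRead("c", s, s + 30, f"m{rng.randint(1, 3)}", rng.randint(1, 4))
            for s in [rng.randint(0, 50) * 10 for _ in range(200)]
        ]
        out = collapse_duplicates(reads)
        assert sum(r.count for r in out) == sum(r.count for r in reads)

    def test_same_interval_different_mirnas_not_collapsed(self):
        reads = [HybridRead("c", 10, 40, "m1"), HybridRead("c", 10, 40, "m2")]
        assert len(collapse_duplicates(reads)) == 2


class TestHybridDuplexes:
    def test_exact_rc_fragment_fully_paired(self, rng, mirna22):
        frag = reverse_complement(mirna22.seq)
        seq = random_rna(rng, 100) + frag + random_rna(rng, 80)
        tx = make_transcript("tx", seq, 30, 150)
        reads = [HybridRead("tx", 100, 122, mirna22.id)]
        ann = annotate_hybrids(reads, [tx], pad=0)
        ann = hybrid_duplexes(ann, {"tx": seq}, [mirna22])
        assert ann[0].duplex.paired_mirna_positions == frozenset(range(1, 23))

    def test_unknown_mirna_flagged_excluded(self, rng):
        seq = random_rna(rng, 200)
        tx = make_transcript("tx", seq, 30, 150)
        ann = annotate_hybrids([HybridRead("tx", 50, 80, "nope")], [tx], pad=0)
        ann = hybrid_duplexes(ann, {"tx": seq}, [MiRNA("m", random_rna(rng, 22))])
        assert ann[0].excluded and ann[0].duplex is None
        pm = pairing_matrices(ann, "five_prime", "CDS")
        assert pm.n_hybrids == 0

    def test_implanted_seed_pairing_recovered(self):
        """>= 95% of reads covering perfect implants recover full seed
        pairing after nibbling and +3 re-expansion (n = 1000 reads)."""
        cfg = SimConfig(
            n_transcripts=20, n_mirnas=4, seed=42,
            implant_spec=(ImplantSpec("miR-s1", "CDS", "perfect", 10),),
            read_model=ReadModel(reads_per_implant=25, duplication_p=1.0, n_decoy_reads=0),
        )
        sim = simulate_transcriptome(cfg)
        reads, truth = simulate_hybrid_reads(sim, seed=42)
        assert len(reads) >= 250
        ann = annotate_hybrids(reads, sim.transcripts, pad=3, bounds=sim.bounds)
        ann = hybrid_duplexes(ann, sim.sequences, sim.mirnas)
        seed_ok = total = 0
        for h in ann:
            if h.duplex is None:
                continue
            total += h.count
            if frozenset(range(2, 9)) <= h.duplex.paired_mirna_positions:
                seed_ok += h.count
        assert total >= 250
        assert seed_ok / total >= 0.95


class TestPairingMatrices:
    def _annotated(self, duplexes, region="CDS", counts=None):
        from mircds.clash import AnnotatedHybrid

        out = []
        for k, d in enumerate(duplexes):
            read = HybridRead("c", 0, d.len_target, d.mirna_id, (counts or {}).get(k, 1))
            out.append(AnnotatedHybrid(read, region, frozenset({"exonic"}), duplex=d))
        return out

    def test_single_fully_paired_hybrid(self):
        d = build_template_duplex(22)
        pm = pairing_matrices(self._annotated([d]), "five_prime", "CDS", width=23)
        assert pm.col_fraction.tolist() == [1.0] * 22 + [0.0]

    def test_three_prime_anchor_is_shifted_five_prime(self, rng):
        duplexes = [
            build_template_duplex(L, set(rng.sample(range(1, L + 1), rng.randint(0, 8))))
            for L in [rng.randint(18, 24) for _ in range(50)]
        ]
        ann = self._annotated(duplexes)
        width = 26
        five = pairing_matrices(ann, "five_prime", "CDS", width=width)
        three = pairing_matrices(ann, "three_prime", "CDS", width=width)
        for row5, row3, d in zip(five.rows, three.rows, duplexes):
            shift = width - d.len_mirna
            assert row3.tolist() == [False] * shift + row5.tolist()[: width - shift]

    def test_mixed_seed_only_and_unpaired_collection(self):
        """A 50/50 mix of seed-only-paired and unpaired hybrids gives
        column fractions near 0.5 over the seed and 0 in the 3' half
        (binomial expectation, n = 2000, seed 7)."""
        rng = random.Random(7)
        seed_only = build_template_duplex(22, {1} | set(range(9, 23)))
        unpaired = build_template_duplex(22, set(range(1, 23)))
        duplexes = [seed_only if rng.random() < 0.5 else unpaired for _ in range(2000)]
        pm = pairing_matrices(self._annotated(duplexes), "five_prime", "CDS", width=23)
        assert np.all(np.abs(pm.col_fraction[1:8] - 0.5) <= 0.05)
        assert np.all(pm.col_fraction[12:] == 0.0)

    def test_count_weighting(self):
        full = build_template_duplex(22)
        none = build_template_duplex(22, set(range(1, 23)))
        ann = self._annotated([full, none], counts={0: 3, 1: 1})
        pm = pairing_matrices(ann, "five_prime", "CDS", width=22)
        assert pm.col_fraction[0] == pytest.approx(0.75)
        pm_u = pairing_matrices(ann, "five_prime", "CDS", width=22, weighted=False)
        assert pm_u.col_fraction[0] == pytest.approx(0.5)

    def test_empty_region_class_gives_empty_matrix(self):
        pm = pairing_matrices([], "five_prime", "UTR3")
        assert pm.n_hybrids == 0 and pm.width == 0


class TestRegionSummary:
    def test_all_cds_reads(self, rng):
        seq = random_rna(rng, 600)
        tx = make_transcript("tx", seq, 120, 300)
        ann = annotate_hybrids(
            [HybridRead("tx", 150, 180, "m"), HybridRead("tx", 200, 230, "m")], [tx], pad=0
        )
        s = region_summary(ann)
        assert s["CDS"] == 1.0 and s.sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        sim = simulate_transcriptome(
            SimConfig(n_transcripts=8, n_mirnas=3, seed=31,
                      read_model=ReadModel(n_decoy_reads=400))
        )
        reads, _ = simulate_hybrid_reads(sim)
        ann = annotate_hybrids(reads, sim.transcripts, pad=3, bounds=sim.bounds)
        assert region_summary(ann).sum() == pytest.approx(1.0)

    def test_multinomial_mix_recovered(self):
        """Decoy-only simulation with mix 0.5/0.3/0.1/0.1 over
        UTR3/CDS/UTR5/intron is recovered within +-0.03 at n = 5000."""
        mix = {"UTR3": 0.5, "CDS": 0.3, "UTR5": 0.1, "intron": 0.1}
        cfg = SimConfig(
            n_transcripts=20, n_mirnas=4, seed=11,
            read_model=ReadModel(n_decoy_reads=5000, duplication_p=1.0, region_mix=mix),
        )
        sim = simulate_transcriptome(cfg)
        reads, truth = simulate_hybrid_reads(sim, seed=11)
        assert len(reads) >= 4900
        ann = annotate_hybrids(reads, sim.transcripts, pad=3, bounds=sim.bounds)
        assert region_fraction_error(region_summary(ann), mix) <= 0.03


class TestCountConservation:
    def test_counts_conserved_through_pipeline(self):
        sim = simulate_transcriptome(
            SimConfig(n_transcripts=10, n_mirnas=3, seed=23,
                      implant_spec=(ImplantSpec("miR-s1", "CDS", "perfect", 3),),
                      read_model=ReadModel(n_decoy_reads=500))
        )
        reads, _ = simulate_hybrid_reads(sim)
        ann = annotate_hybrids(reads, sim.transcripts, pad=3, bounds=sim.bounds)
        assert sum(h.count for h in ann) == len(reads)
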