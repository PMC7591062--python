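"""Generator contracts: determinism, motif placement, divergence accounting,
genome composition and long-read truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satellitome import (
    FamilySpec,
    SpeciesProfile,
    default_species_profiles,
    generate_array,
    generate_genome,
    generate_long_reads,
    generate_monomer,
)
from oracles import naive_find_positions


class TestGenerateMonomer:
    def test_motif_fills_monomer(self):
        assert generate_monomer(10, "TTTCATTTGA", 0, 3) == "TTTCATTTGA"

    def test_motif_at_start(self):
        m = generate_monomer(40, "TTTCATTTGA", 0, 1)
        assert len(m) == 40 and m.startswith("TTTCATTTGA")

    def test_motif_at_offset(self):
        m = generate_monomer(60, "CCCGTCTGT", 10, 7)
        assert len(m) == 60 and m[10:19] == "CCCGTCTGT"

    def test_same_seed_same_monomer(self):
        assert generate_monomer(40, "TTTCATTTGA", 0, 5) == generate_monomer(
            40, "TTTCATTTGA", 0, 5
        )

    def test_motif_too_long_raises(self):
        with pytest.raises(ValueError):
            generate_monomer(8, "TTTCATTTGA", 0, 1)
        with pytest.raises(ValueError):
            generate_monomer(40, "TTTCATTTGA", 35, 1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        length=st.integers(20, 120),
        offset=st.integers(0, 10),
        seed=st.integers(0, 10_000),
    )
    def test_length_motif_and_determinism(self, length, offset, seed):
        motif = "GCATGTAGA"
        m = generate_monomer(length, motif, offset, seed)
        assert len(m) == length
        assert m[offset : offset + len(motif)] == motif
        assert set(m) <= set("ACGT")
        assert m == generate_monomer(length, motif, offset, seed)


class TestGenerateArray:
    def test_perfect_continuous(self):
        spec = FamilySpec("x", 5, None, 0, (1, 100), 0.0, "continuous", monomer="ACGTT")
        seq, truth = generate_array(spec, 20, 1)
        assert seq == "ACGTT" * 20
        assert truth.mean_identity_to_consensus == 1.0
        assert (truth.period, truth.copies) == (5, 20)

    def test_divergence_matches_direct_comparison(self):
        spec = FamilySpec(
            "f1", 40, "TTTCATTTGA", 0, (1, 500), 0.05, "continuous",
            monomer=generate_monomer(40, "TTTCATTTGA", 0, 9),
        )
        seq, truth = generate_array(spec, 100, 11)
        # oracle: per-copy hamming identity against the base monomer
        idents = [
            sum(a == b for a, b in zip(seq[i * 40 : (i + 1) * 40], spec.monomer)) / 40
            for i in range(100)
        ]
        assert np.isclose(np.mean(idents), truth.mean_identity_to_consensus)
        se = np.sqrt(0.05 * 0.95 / (100 * 40))
        assert abs(np.mean(idents) - 0.95) < 3 * se

    @pytest.mark.parametrize("frac", [0.0, 0.2])
    def test_motif_survives_mutation(self, frac):
        spec = FamilySpec(
            "f1", 40, "TTTCATTTGA", 0, (1, 500), 0.10, "continuous",
            monomer=generate_monomer(40, "TTTCATTTGA", 0, 9),
        )
        copies = 200
        seq, _ = generate_array(spec, copies, 13, motif_mutation_fraction=frac)
        n_exact = len(naive_find_positions(seq, "TTTCATTTGA"))
        # binomial slack below the expected (1-frac) floor
        assert n_exact >= copies * (1 - frac) - 3 * np.sqrt(copies * frac * (1 - frac) + 1)

    def test_composite_single_annotation(self):
        spec = FamilySpec("f5", 48, "AAGGGGCTC", 12, (1, 500), 0.05, "composite")
        seq, truth = generate_array(spec, 120, 5)
        assert (truth.start, truth.end) == (0, len(seq))
        assert truth.copies == 120
        assert len(seq) > 120 * 48  # spacers included in the major span

    def test_copies_must_be_positive(self):
        spec = FamilySpec("x", 5, None, 0, (1, 10), 0.0, "continuous", monomer="ACGTT")
        with pytest.raises(ValueError):
            generate_array(spec, 0, 1)

    def test_dispersed_spacing_bounded(self):
        spec = FamilySpec("f6", 21, "TATGTTCTAAA", 0, (1, 500), 0.05, "dispersed_motif")
        seq, _ = generate_array(spec, 60, 17)
        pos = naive_find_positions(seq, "TATGTTCTAAA")
        assert len(pos) == 60
        gaps = np.diff(pos)
        assert gaps.min() >= 21 and gaps.max() <= 4 * 21


class TestGenerateGenome:
    def test_only_requested_families(self, specs, spec_by_id):
        profile = SpeciesProfile("C_vulvaria", "H", ("f1", "f3", "f6", "f7"), 400_000)
        contigs, truth = generate_genome(
            profile, specs, 42,
            include_microsat=False, include_ultralong=False, noise=False,
        )
        assert {t.family_id for t in truth} == {"f1", "f3", "f6", "f7"}
        # absent families may leave chance motif hits in random background,
        # but never an array that would confirm presence
        from satellitome import confirm_presence, motif_scan

        for fid in ("f2", "f4", "f5", "f8"):
            spec = spec_by_id[fid]
            hits = motif_scan(contigs, spec.conserved_motif)
            present, _ = confirm_presence(
                hits, spec.monomer_length, motif_length=len(spec.conserved_motif)
            )
            assert not present

    def test_truth_annotations_never_overlap(self, specs):
        profile = default_species_profiles(500_000)[1]  # C_suecicum, most families
        _, truth = generate_genome(profile, specs, 7)
        by_contig = {}
        for t in truth:
            assert 0 <= t.start < t.end
            assert t.copies >= 1
            by_contig.setdefault(t.contig_id, []).append((t.start, t.end))
        for ivs in by_contig.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_empty_profile_pure_background(self, specs):
        profile = SpeciesProfile("empty", "A", (), 100_000)
        contigs, truth = generate_genome(
            profile, specs, 1,
            include_microsat=False, include_ultralong=False, noise=False,
        )
        assert truth == []
        assert sum(len(c) for c in contigs.values()) == 100_000

    def test_same_seed_identical_output(self, specs):
        profile = SpeciesProfile("sp", "B", ("f1", "f5"), 300_000)
        g1 = generate_genome(profile, specs, 5)
        g2 = generate_genome(profile, specs, 5)
        assert g1[0] == g2[0]
        assert [vars(t) for t in g1[1]] == [vars(t) for t in g2[1]]

    def test_different_seeds_same_composition(self, specs):
        profile = SpeciesProfile("sp", "B", ("f1", "f5"), 300_000)
        g1 = generate_genome(profile, specs, 5)
        g2 = generate_genome(profile, specs, 6)
        assert g1[0] != g2[0]
        assert {t.family_id for t in g1[1]} == {t.family_id for t in g2[1]}

    def test_too_small_genome_raises(self, specs):
        profile = SpeciesProfile("sp", "B", ("f1",), 30_000)
        with pytest.raises(ValueError, match="too small"):
            generate_genome(profile, specs, 1, contig_size=30_000)


class TestGenerateLongReads:
    def test_reads_are_substrings_and_truth_localized(self, specs, spec_by_id):
        profile = SpeciesProfile("sp", "D", ("f1", "f2"), 300_000)
        contigs, truth = generate_genome(
            profile, specs, 3, include_microsat=False, include_ultralong=False
        )
        reads, read_truth = generate_long_reads(contigs, 20_000, 30, 4, truth=truth)
        assert len(reads) == 30
        for rid, seq in reads.items():
            assert any(seq in c for c in contigs.values())
        for rt in read_truth:
            assert 0 <= rt["start"] < rt["end"] <= len(reads[rt["read_id"]])
            # the read-local interval really contains the family's motif
            fam = rt["family_id"]
            if fam in spec_by_id and rt["end"] - rt["start"] > 200:
                window = reads[rt["read_id"]][rt["start"] : rt["end"]]
                assert spec_by_id[fam].conserved_motif in window

    def test_full_contig_read(self):
        contigs = {"c": "ACGT" * 300}
        # a mean far above the contig length clips every draw to the full contig
        reads, _ = generate_long_reads(contigs, 10_000, 1, 0)
        assert reads["read_00000"] == contigs["c"]

    def test_colocalized_pair_lands_in_one_read(self, specs):
        profile = SpeciesProfile("sp", "D", ("f1", "f2"), 300_000)
        contigs, truth = generate_genome(
            profile, specs, 8, include_microsat=False, include_ultralong=False
        )
        # f1/f2 colocalized group: both truths adjacent on one contig
        f2 = [t for t in truth if t.family_id == "f2"]
        f1 = [t for t in truth if t.family_id == "f1"]
        pairs = [
            (a, b)
            for a in f1
            for b in f2
            if a.contig_id == b.contig_id and 0 < b.start - a.end <= 3000
        ]
        assert pairs, "generator should place one f1/f2 pair adjacently"
        a, b = pairs[0]
        # a read covering the whole contig is annotated with both families
        contig = {a.contig_id: contigs[a.contig_id]}
        _, rt = generate_long_reads(contig, len(contigs[a.contig_id]), 1, 0, truth=truth)
        fams = {r["family_id"] for r in rt}
        assert {"f1", "f2"} <= fams

    def test_n_reads_validation(self):
        with pytest.raises(ValueError):
            generate_long_reads({"c": "ACGT" * 100}, 100, 0, 1)
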