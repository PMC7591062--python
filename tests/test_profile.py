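"""Profiling: contig selection, exact motif scanning vs the naive oracle,
array-confirmed presence calls, matrix construction and classification."""

import warnings

import numpy as np
import pytest

from satellitome import (
    MotifHit,
    PresenceMatrix,
    build_presence_matrix,
    classify_families,
    confirm_presence,
    microsat_density,
    motif_scan,
    relative_density,
    select_longest_contigs,
)
from satellitome.config import SPECIES_TABLE
from satellitome.simulate import random_dna
from conftest import map_families_to_truth
from oracles import naive_find_positions, naive_revcomp

TABLE3 = {sp: set(row[1]) for sp, row in SPECIES_TABLE.items()}
ALL_FAMILIES = sorted({f for fams in TABLE3.values() for f in fams} | {"f2", "f4", "f5", "f8"})


class TestSelectLongestContigs:
    def test_top_n_by_length(self):
        contigs = {f"c{i}": "A" * (100 + 10 * i) for i in range(5)}
        out = select_longest_contigs(contigs, 3)
        assert list(out) == ["c4", "c3", "c2"]

    def test_exclusion_reference_drops_contig(self):
        rng = np.random.default_rng(1)
        organelle = random_dna(rng, 2000)
        nuclear = random_dna(rng, 1500)
        out = select_longest_contigs(
            {"org": organelle, "nuc": nuclear}, 10, exclusion_refs={"chloro": organelle}
        )
        assert list(out) == ["nuc"]

    def test_n_exceeding_supply_returns_all(self):
        contigs = {f"c{i}": "ACGT" * 50 for i in range(200)}
        assert len(select_longest_contigs(contigs, 1000)) == 200

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            select_longest_contigs({"c": "ACGT"}, 0)


class TestMotifScan:
    def test_forward_hits(self):
        contig = "TTTCATTTGA" + "C" * 10 + "TTTCATTTGA"
        hits = motif_scan({"c": contig}, "TTTCATTTGA")
        assert [(h.position, h.strand) for h in hits] == [(0, "+"), (20, "+")]

    def test_reverse_strand_hit(self):
        motif = "GCATGTAGA"
        hits = motif_scan({"c": naive_revcomp(motif)}, motif)
        assert [(h.position, h.strand) for h in hits] == [(0, "-")]

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 30_000)
        # salt with motif copies on both strands and an N island
        motif = "AATGGAATC"
        seq = motif + seq[9:15_000] + naive_revcomp(motif) + seq[15_000:] + motif
        seq = seq[:500] + "N" * 20 + seq[520:]
        hits = motif_scan({"c": seq}, motif)
        fwd = naive_find_positions(seq, motif)
        rev = naive_find_positions(seq, naive_revcomp(motif))
        assert [h.position for h in hits if h.strand == "+"] == fwd
        assert [h.position for h in hits if h.strand == "-"] == rev

    def test_never_matches_through_n(self):
        seq = "TTTCA" + "N" + "TTGA" + "TTTCATTTGA"
        hits = motif_scan({"c": seq}, "TTTCATTTGA")
        assert [h.position for h in hits if h.strand == "+"] == [10]

    def test_invalid_motif(self):
        with pytest.raises(ValueError):
            motif_scan({"c": "ACGT"}, "ACGTN")


class TestConfirmPresence:
    def _hits(self, positions, contig="c", strand="+"):
        return [MotifHit(contig, p, strand) for p in positions]

    def test_regular_chain_confirms(self):
        present, arrays = confirm_presence(self._hits([0, 40, 80, 120, 160, 200]), 40)
        assert present
        assert len(arrays) == 1

    def test_isolated_hits_are_noise(self):
        present, arrays = confirm_presence(self._hits([0, 10_000, 20_000]), 40)
        assert not present and arrays == []

    def test_dispersed_spacing_chains_into_one_array(self):
        rng = np.random.default_rng(3)
        positions = [0]
        for _ in range(30):
            positions.append(positions[-1] + 21 + int(rng.integers(0, 64)))
        present, arrays = confirm_presence(self._hits(positions), 21)
        assert present and len(arrays) == 1

    def test_strands_chain_independently(self):
        hits = self._hits([0, 40, 80]) + self._hits([20, 60, 100], strand="-")
        present, _ = confirm_presence(hits, 40, min_tandem_hits=5)
        assert not present  # 3 hits per strand never reach the threshold

    def test_monomer_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            confirm_presence(self._hits([0]), 8, motif_length=10)


class TestPresenceMatrixAndClassification:
    def test_study_simulation_reproduces_published_pattern(self, study_result):
        mapping = map_families_to_truth(study_result.families)
        assert len(mapping) == 8 and len(set(mapping.values())) == 8
        pattern = study_result.presence.pattern()
        for sp, fams in TABLE3.items():
            for disc, true in mapping.items():
                assert bool(pattern.loc[sp, disc]) == (true in fams)

    def test_published_matrix_classification_sets(self):
        matrix = PresenceMatrix.from_pattern(
            {sp: {f: f in fams for f in ALL_FAMILIES} for sp, fams in TABLE3.items()}
        )
        cats = classify_families(matrix)
        assert {f for f, c in cats.items() if c == "group"} == {"f1", "f7"}
        assert {f for f, c in cats.items() if c == "species"} == {"f2", "f4"}
        assert {f for f, c in cats.items() if c == "lineage"} == {"f3", "f5", "f6", "f8"}

    def test_classification_order_invariance(self):
        rows = list(TABLE3.items())
        m1 = PresenceMatrix.from_pattern(
            {sp: {f: f in fams for f in ALL_FAMILIES} for sp, fams in rows}
        )
        m2 = PresenceMatrix.from_pattern(
            {sp: {f: f in fams for f in reversed(ALL_FAMILIES)} for sp, fams in reversed(rows)}
        )
        assert classify_families(m1) == classify_families(m2)

    def test_single_species_dataset_is_species_specific(self):
        m = PresenceMatrix.from_pattern({"only": {"fx": True}})
        assert classify_families(m) == {"fx": "species"}

    def test_absent_family_warns(self):
        m = PresenceMatrix.from_pattern({"a": {"fx": False}, "b": {"fx": False}})
        with pytest.warns(UserWarning):
            cats = classify_families(m)
        assert cats == {"fx": "absent"}

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_presence_matrix([("a", {"c": "ACGT"}), ("a", {"c": "ACGT"})], [])

    def test_present_requires_an_array(self):
        m = PresenceMatrix(["sp"], ["f"])
        with pytest.raises(ValueError):
            m.set_cell("sp", "f", True, 10, 0)


class TestMicrosatDensity:
    def test_single_probe_hit(self):
        assert microsat_density({"c": "TTA" * 6}) == 1

    def test_overlapping_hits_counted(self):
        # (TTA)x8 is 24 bp; the 18 bp probe fits at offsets 0, 3, 6
        assert microsat_density({"c": "TTA" * 8}) == 3
        assert naive_find_positions("TTA" * 8, "TTA" * 6) == [0, 3, 6]

    def test_zero_tta_genome(self):
        assert microsat_density({"c": "GC" * 200}) == 0

    def test_monotone_in_n_contigs(self):
        contigs = {f"c{i}": "TTA" * (6 + i) + "G" * (40 - i) for i in range(10)}
        counts = [microsat_density(contigs, n_contigs=n) for n in (1, 3, 5, 10)]
        assert counts == sorted(counts)

    def test_invalid_repeats(self):
        with pytest.raises(ValueError):
            microsat_density({"c": "TTA"}, repeats=0)


class TestRelativeDensity:
    def test_published_style_example(self):
        out = relative_density({"acu": 100, "pam": 252}, "acu")
        assert out == {"acu": 100.0, "pam": 252.0}

    def test_reference_is_hundred_percent(self):
        assert relative_density({"a": 7}, "a") == {"a": 100.0}

    def test_half(self):
        assert relative_density({"a": 10, "b": 5}, "a")["b"] == 50.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_density({"a": 0, "b": 5}, "a")
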