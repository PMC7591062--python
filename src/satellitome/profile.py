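"""Multi-genome presence/absence profiling of satDNA families.

Presence of a family in a genome is confirmed only by arrays: exact
(zero-mismatch) hits of the family's conserved motif are chained along each
contig, and a chain of at least five hits with spacing at most four monomer
lengths counts as an array.  Isolated dispersed hits are genetic noise and
never confirm presence.  Families are then categorized as group-specific
(present in all species), species-specific (exactly one) or
lineage-specific (several but not all).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import MICROSAT_PROBE_REPEATS, MICROSAT_UNIT, RunConfig
from .families import SatFamily
from .io import reverse_complement

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class MotifHit:
    """One exact motif occurrence; position is the match start on forward coordinates."""

    contig_id: str
    position: int
    strand: str  # "+" or "-"


def _find_all(seq: str, pattern: str) -> list[int]:
    """All (overlapping) exact occurrences of pattern in seq."""
    out = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def motif_scan(contigs: Mapping[str, str], motif: str) -> list[MotifHit]:
    """All exact occurrences of `motif` on both strands of every contig.

    Reverse-complement occurrences are reported with strand "-" at the match
    start on forward coordinates; overlapping occurrences are all reported.
    Matching never crosses an N (N equals no base).
    """
    if not motif or set(motif) - _ACGT:
        raise ValueError("motif must be a non-empty A/C/G/T string")
    rc = reverse_complement(motif)
    hits: list[MotifHit] = []
    for cid, seq in contigs.items():
        for pos in _find_all(seq, motif):
            hits.append(MotifHit(cid, pos, "+"))
        for pos in _find_all(seq, rc):
            hits.append(MotifHit(cid, pos, "-"))
    hits.sort(key=lambda h: (h.contig_id, h.position, h.strand))
    return hits


def confirm_presence(
    hits: Sequence[MotifHit],
    monomer_length: int,
    min_tandem_hits: int = 5,
    max_gap_factor: float = 4.0,
    motif_length: Optional[int] = None,
) -> tuple[bool, list[tuple[str, int, int, str, int]]]:
    """Array-based presence call from motif hits.

    Same-strand hits on one contig are chained while consecutive spacing is
    at most ``max_gap_factor * monomer_length``; chains with at least
    ``min_tandem_hits`` hits are arrays, reported as
    (contig_id, start, end, strand, n_hits).  Present iff >= 1 array exists.
    """
    if motif_length is not None and monomer_length < motif_length:
        raise ValueError("monomer_length is shorter than the motif")
    tail = motif_length if motif_length is not None else 1
    max_gap = max_gap_factor * monomer_length
    groups: dict[tuple[str, str], list[int]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.strand), []).append(h.position)
    arrays: list[tuple[str, int, int, str, int]] = []
    for (cid, strand), positions in sorted(groups.items()):
        positions.sort()
        chain = [positions[0]]
        for p in positions[1:] + [None]:
            if p is not None and p - chain[-1] <= max_gap:
                chain.append(p)
            else:
                if len(chain) >= min_tandem_hits:
                    arrays.append((cid, chain[0], chain[-1] + tail, strand, len(chain)))
                if p is not None:
                    chain = [p]
    arrays.sort(key=lambda a: (a[0], a[1]))
    return bool(arrays), arrays


class PresenceMatrix:
    """Species x family occurrence table with hit/array evidence counts."""

    def __init__(self, species: Sequence[str], families: Sequence[str]):
        self.species = list(species)
        self.families = list(families)
        z = np.zeros((len(self.species), len(self.families)), dtype=int)
        self.n_hits = pd.DataFrame(z.copy(), index=self.species, columns=self.families)
        self.n_arrays = pd.DataFrame(z.copy(), index=self.species, columns=self.families)
        self.present = pd.DataFrame(
            np.zeros_like(z, dtype=bool), index=self.species, columns=self.families
        )

    def set_cell(self, species: str, family: str, present: bool, n_hits: int, n_arrays: int):
        if present and n_arrays < 1:
            raise ValueError("present cells require at least one array")
        self.present.loc[species, family] = present
        self.n_hits.loc[species, family] = n_hits
        self.n_arrays.loc[species, family] = n_arrays

    def pattern(self) -> pd.DataFrame:
        return self.present.copy()

    def to_tsv(self, path) -> None:
        """Published-table dialect: one row per species, "+"/"-" cells."""
        symbolic = self.present.map(lambda v: "+" if v else "–")
        symbolic.index.name = "species/family"
        symbolic.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            sp: {
                fam: {
                    "present": bool(self.present.loc[sp, fam]),
                    "n_hits": int(self.n_hits.loc[sp, fam]),
                    "n_arrays": int(self.n_arrays.loc[sp, fam]),
                }
                for fam in self.families
            }
            for sp in self.species
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_pattern(cls, pattern: Mapping[str, Mapping[str, bool]]) -> "PresenceMatrix":
        """Build a matrix from a {species: {family: bool}} pattern (evidence
        counts set to 1 for present cells)."""
        species = list(pattern)
        families = sorted({f for row in pattern.values() for f in row})
        m = cls(species, families)
        for sp, row in pattern.items():
            for fam in families:
                pres = bool(row.get(fam, False))
                m.set_cell(sp, fam, pres, int(pres), int(pres))
        return m


def select_longest_contigs(
    contigs: Mapping[str, str],
    n: int,
    exclusion_refs: Optional[Mapping[str, str]] = None,
    kmer: int = 21,
    shared_fraction: float = 0.05,
) -> dict[str, str]:
    """The n longest contigs, excluding organelle/rDNA-like sequences.

    Contigs sharing >= ``shared_fraction`` of their k-mers with any exclusion
    reference are dropped before the top-n cut.  Ties in length are broken
    by contig id.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    excl_kmers: set[str] = set()
    if exclusion_refs:
        for seq in exclusion_refs.values():
            excl_kmers.update(seq[i : i + kmer] for i in range(len(seq) - kmer + 1))
    ordered = sorted(contigs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out: dict[str, str] = {}
    for cid, seq in ordered:
        if len(out) >= n:
            break
        if excl_kmers and len(seq) >= kmer:
            kms = {seq[i : i + kmer] for i in range(len(seq) - kmer + 1)}
            if len(kms & excl_kmers) >= shared_fraction * len(kms):
                continue
        out[cid] = seq
    return out


def build_presence_matrix(
    genomes,
    families: Sequence[SatFamily],
    config: Optional[RunConfig] = None,
) -> PresenceMatrix:
    """Occurrence matrix: one presence call per species x family.

    ``genomes`` maps species_id -> {contig_id: seq} (a sequence of
    (species_id, contigs) pairs is also accepted).  Each cell chains exact
    conserved-motif hits over the species' selected longest contigs.
    """
    cfg = config or RunConfig()
    if not isinstance(genomes, Mapping):
        pairs = list(genomes)
        ids = [sp for sp, _ in pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species ids")
        genomes = dict(pairs)
    fam_list = [f for f in families if f.conserved_motif is not None]
    matrix = PresenceMatrix(list(genomes), [f.family_id for f in fam_list])
    for sp, contigs in genomes.items():
        selected = select_longest_contigs(contigs, cfg.contig_selection_n)
        for fam in fam_list:
            hits = motif_scan(selected, fam.conserved_motif)
            present, arrays = confirm_presence(
                hits,
                fam.monomer_length,
                cfg.presence_min_tandem_hits,
                cfg.presence_max_gap_factor,
                motif_length=len(fam.conserved_motif),
            )
            matrix.set_cell(sp, fam.family_id, present, len(hits), len(arrays))
    return matrix


def classify_families(matrix: PresenceMatrix) -> dict[str, str]:
    """Group/lineage/species classification from the presence matrix.

    Present in all (>= 2) species -> group-specific; in exactly one ->
    species-specific; otherwise lineage-specific.  A family absent
    everywhere is categorized "absent" with a warning.
    """
    n_species = len(matrix.species)
    out: dict[str, str] = {}
    for fam in matrix.families:
        count = int(matrix.present[fam].sum())
        if count == 0:
            warnings.warn(f"family {fam} is absent from every genome")
            out[fam] = "absent"
        elif count == 1:
            out[fam] = "species"
        elif count == n_species:
            out[fam] = "group"
        else:
            out[fam] = "lineage"
    return out


def microsat_density(
    contigs: Mapping[str, str],
    motif_unit: str = MICROSAT_UNIT,
    repeats: int = MICROSAT_PROBE_REPEATS,
    n_contigs: int = 50_000,
) -> int:
    """Number of exact (unit)^repeats hits in the n longest contigs.

    Both strands are scanned and overlapping hits all count, so a pure
    (TTA)_k run contributes k-repeats+1 forward hits.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    probe = motif_unit * repeats
    selected = select_longest_contigs(contigs, n_contigs)
    rc = reverse_complement(probe)
    total = 0
    for seq in selected.values():
        total += len(_find_all(seq, probe))
        total += len(_find_all(seq, rc))
    return total


def relative_density(
    counts: Mapping[str, int], reference_species: str
) -> dict[str, float]:
    """Densities as percentages of the reference species (reference = 100%)."""
    if reference_species not in counts:
        raise ValueError(f"unknown reference species {reference_species!r}")
    ref = counts[reference_species]
    if ref == 0:
        raise ValueError("reference species has zero count")
    return {sp: 100.0 * c / ref for sp, c in counts.items()}
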