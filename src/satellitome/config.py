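"""Run configuration and the default Chenopodium album aggregate study setup.

The constants here encode the published study design for the seven diploid
*C. album* aggregate species: eight satDNA families (f1-f8) plus the TTA
microsatellite, their conserved 9-12 bp motifs, approximate monomer lengths,
and the species x family occurrence pattern used both by the synthetic-genome
generator and as a reference matrix for classification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

# Conserved motifs per satDNA family (published primer/motif table) and the
# monomer lengths reported for each family.  Offsets of the motif within the
# monomer are a simulator convention (the true consensi are not printed).
FAMILY_TABLE = {
    # family_id: (monomer_length, conserved_motif, motif_offset, structure,
    #             arrays_per_genome, copies_range)
    "f1": (40, "TTTCATTTGA", 0, "continuous", 3, (300, 1000)),
    "f2": (170, "GCATGTAGA", 10, "continuous", 2, (30, 100)),
    "f3": (170, "AGCCATATA", 40, "continuous", 3, (6, 20)),
    "f4": (40, "AATGGAATC", 5, "continuous", 2, (40, 62)),
    "f5": (48, "AAGGGGCTC", 12, "composite", 2, (100, 160)),
    "f6": (21, "TATGTTCTAAA", 0, "dispersed_motif", 2, (40, 120)),
    "f7": (21, "GGAGCGGGC", 0, "continuous", 4, (40, 120)),
    "f8": (60, "CCCGTCTGT", 20, "continuous", 2, (31, 100)),
}

MICROSAT_UNIT = "TTA"
MICROSAT_PROBE_REPEATS = 6  # the (TTA)6 scanning probe
MICROSAT_MAX_SPAN = 1500  # longest TTA array seen in long reads, bp
ULTRALONG_UNIT = 13_000  # decayed-TE tandem unit, bp

# Species x family occurrence ("+" rows of the published 7x8 matrix) together
# with the genome-group letter and the TTA density of each genome relative to
# C. acuminatum (= 1.0).
SPECIES_TABLE = {
    # species_id: (genome_letter, families_present, tta_weight)
    "C_ficifolium": ("B", ("f1", "f3", "f5", "f7"), 1.41),
    "C_suecicum": ("B", ("f1", "f3", "f4", "f5", "f7"), 1.56),
    "C_iljinii": ("E", ("f1", "f6", "f7", "f8"), 0.54),
    "C_pamiricum": ("E", ("f1", "f6", "f7", "f8"), 2.52),
    "C_acuminatum": ("D", ("f1", "f2", "f6", "f7"), 1.00),
    "C_bryoniifolium": ("A", ("f1", "f6", "f7"), 1.44),
    "C_vulvaria": ("H", ("f1", "f3", "f6", "f7"), 1.32),
}

FAMILY_IDS = tuple(FAMILY_TABLE)
SPECIES_IDS = tuple(SPECIES_TABLE)


@dataclass
class RunConfig:
    """Thresholds shared across the pipeline.

    Defaults equal the published values where the study prints them
    (9-12 bp motifs, >30 monomer minisatellite and >5 monomer satellite
    filters, 1,000 selected contigs, (TTA)6 per 50,000 contigs); the rest
    are package conventions documented in docs/methods.md.
    """

    motif_min_len: int = 9
    motif_max_len: int = 12
    minisat_period_max: int = 60  # period <= 60 bp counts as minisatellite
    min_copies_minisat: int = 30  # arrays must exceed this (strict >)
    min_copies_sat: int = 5
    contig_selection_n: int = 1000
    microsat_contig_n: int = 50_000
    family_identity_threshold: float = 0.80  # single-linkage clustering
    boundary_identity_floor: float = 0.70  # array boundary refinement
    period_score_floor: float = 0.60
    harmonic_tolerance: float = 0.03
    presence_min_tandem_hits: int = 5
    presence_max_gap_factor: float = 4.0
    detect_word: int = 12
    detect_max_period: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "motif_min_len", "motif_max_len", "minisat_period_max",
            "min_copies_minisat", "min_copies_sat", "contig_selection_n",
            "microsat_contig_n", "family_identity_threshold",
            "boundary_identity_floor", "period_score_floor",
            "presence_min_tandem_hits", "presence_max_gap_factor",
            "detect_word", "detect_max_period",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")
        if self.motif_min_len > self.motif_max_len:
            raise ValueError("motif_min_len exceeds motif_max_len")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
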