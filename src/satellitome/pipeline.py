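"""End-to-end satellitome inference over a set of genomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .config import RunConfig
from .detect import DetectParams, SatArray, filter_arrays, find_arrays
from .families import SatFamily, cluster_families
from .profile import (
    PresenceMatrix,
    build_presence_matrix,
    classify_families,
    microsat_density,
    relative_density,
    select_longest_contigs,
)
from .tree import build_tree, pairwise_distance


@dataclass
class SatellitomeResult:
    """Everything the pipeline infers from a set of genomes."""

    arrays: dict[str, list[SatArray]]
    families: list[SatFamily]  # satDNA families (monomer > 6 bp)
    microsat_families: list[SatFamily]
    presence: PresenceMatrix
    classification: dict[str, str]
    microsat_counts: dict[str, int]
    microsat_relative: Optional[dict[str, float]]
    tree_newick: Optional[str]
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def n_families(self) -> int:
        return len(self.families)


def detect_params(config: RunConfig) -> DetectParams:
    return DetectParams(
        word=config.detect_word,
        max_period=config.detect_max_period,
        min_score=config.period_score_floor,
        harmonic_tolerance=config.harmonic_tolerance,
        boundary_floor=config.boundary_identity_floor,
    )


def run_pipeline(
    genomes: Mapping[str, Mapping[str, str]],
    config: Optional[RunConfig] = None,
    reference_species: Optional[str] = None,
) -> SatellitomeResult:
    """Full inference: contig selection, array detection and filtering,
    family clustering, presence profiling, classification, microsatellite
    densities, and the family-relationship tree.

    ``genomes`` maps species_id -> {contig_id: sequence}.
    """
    cfg = config or RunConfig()
    params = detect_params(cfg)
    arrays: dict[str, list[SatArray]] = {}
    for sp in sorted(genomes):
        selected = select_longest_contigs(genomes[sp], cfg.contig_selection_n)
        found: list[SatArray] = []
        for cid, seq in selected.items():
            found.extend(find_arrays(seq, params, seq_id=cid))
        arrays[sp] = filter_arrays(
            found,
            cfg.minisat_period_max,
            cfg.min_copies_minisat,
            cfg.min_copies_sat,
        )
    clusters = cluster_families(
        arrays,
        identity_threshold=cfg.family_identity_threshold,
        motif_min_len=cfg.motif_min_len,
        motif_max_len=cfg.motif_max_len,
    )
    sat_families = [f for f in clusters if not f.is_microsatellite]
    ms_families = [f for f in clusters if f.is_microsatellite]
    presence = build_presence_matrix(genomes, sat_families, cfg)
    classification = classify_families(presence)
    for f in sat_families:
        f.origin_category = classification.get(f.family_id)
    counts = {
        sp: microsat_density(genomes[sp], n_contigs=cfg.microsat_contig_n)
        for sp in sorted(genomes)
    }
    rel = None
    if reference_species is not None and counts.get(reference_species, 0) > 0:
        rel = relative_density(counts, reference_species)
    newick = None
    if len(sat_families) >= 2:
        dm = pairwise_distance([(f.family_id, f.consensus) for f in sat_families])
        newick = build_tree(dm)
    return SatellitomeResult(
        arrays=arrays,
        families=sat_families,
        microsat_families=ms_families,
        presence=presence,
        classification=classification,
        microsat_counts=counts,
        microsat_relative=rel,
        tree_newick=newick,
        config=cfg,
    )
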