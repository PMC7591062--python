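"""Synthetic satellitome generator.

Builds genomes that emulate the statistical structure of the seven diploid
*Chenopodium album* aggregate satellitomes: eight satDNA families with
conserved 9-12 bp motifs embedded per the published species x family
occurrence pattern, (TTA)n microsatellite arrays with species-specific
loads, ultralong (~13 kb unit) decayed-TE tandem repeats, uniform random
background, and simulated long reads over those genomes.  Every product is
deterministic in the seed and is accompanied by ground-truth annotations
for parameter-recovery testing.

Monomer lengths are realized exactly at the stated integers (40, 170, 170,
40, 48, 21, 21, 60 bp for f1-f8) so that recovery tests have a sharp truth;
divergence is substitution-only by default, and the conserved-motif window
is fully protected from mutation unless a nonzero mutation fraction is
requested (the motif exists to be found by zero-mismatch scanning).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .config import (
    FAMILY_TABLE,
    MICROSAT_MAX_SPAN,
    MICROSAT_UNIT,
    SPECIES_TABLE,
    ULTRALONG_UNIT,
)
from .io import reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STRUCTURES = ("continuous", "composite", "dispersed_motif", "microsatellite")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _encode(seq: str) -> np.ndarray:
    """Map an ACGT string to 0..3 codes."""
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def random_dna(rng, n: int, gc: float = 0.5) -> str:
    """Uniform (or GC-biased) random DNA of length n."""
    return _decode(_random_codes(_as_rng(rng), n, gc))


@dataclass(frozen=True)
class FamilySpec:
    """One satDNA family as the generator realizes it."""

    family_id: str
    monomer_length: int
    conserved_motif: Optional[str]
    motif_offset: int
    copies_range: tuple[int, int]
    divergence: float = 0.05
    structure: str = "continuous"
    array_span_range: Optional[tuple[int, int]] = None
    monomer: Optional[str] = None  # realized base monomer; generated if None
    arrays_per_genome: int = 2

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError("divergence must lie in [0, 0.25]")
        if self.conserved_motif is not None:
            mlen = len(self.conserved_motif)
            if self.structure != "microsatellite" and not 9 <= mlen <= 12:
                raise ValueError("conserved motif must be 9-12 bp")
            if self.motif_offset + mlen > self.monomer_length:
                raise ValueError("motif does not fit within the monomer")
        if self.monomer is not None and len(self.monomer) != self.monomer_length:
            raise ValueError("explicit monomer length mismatch")


@dataclass(frozen=True)
class SpeciesProfile:
    """Which families a synthetic genome contains and at what scale."""

    species_id: str
    genome_label: str
    families_present: tuple[str, ...]
    genome_size: int = 1_000_000
    tta_weight: float = 1.0

    def __post_init__(self):
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.tta_weight < 0:
            raise ValueError("tta_weight must be nonnegative")


@dataclass
class TruthAnnotation:
    """Ground truth for one embedded array (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    family_id: str
    period: int
    copies: int
    mean_identity_to_consensus: float

    def to_gff_feature(self) -> dict:
        return {
            "seqid": self.contig_id,
            "start": self.start,
            "end": self.end,
            "type": "satellite_DNA",
            "score": self.mean_identity_to_consensus,
            "attributes": {
                "family_id": self.family_id,
                "period": self.period,
                "copies": self.copies,
            },
        }


def generate_monomer(length: int, motif: Optional[str], motif_offset: int, seed) -> str:
    """Random monomer of `length` bp with `motif` placed exactly at `motif_offset`.

    Bases outside the motif are i.i.d. uniform over ACGT under the seed; the
    same seed yields an identical monomer.
    """
    if length <= 0:
        raise ValueError("monomer length must be positive")
    rng = _as_rng(seed)
    codes = _random_codes(rng, length)
    if motif is not None:
        m = _encode(motif)
        if motif_offset < 0 or motif_offset + len(m) > length:
            raise ValueError("motif does not fit within the monomer")
        codes[motif_offset : motif_offset + len(m)] = m
    return _decode(codes)


def _mutate_copy(
    codes: np.ndarray,
    rng: np.random.Generator,
    divergence: float,
    protect: Optional[tuple[int, int]],
) -> tuple[np.ndarray, int]:
    """Substitute each base with probability `divergence`; mutated bases always
    change.  Returns (mutated copy, number of substitutions)."""
    out = codes.copy()
    if divergence <= 0:
        return out, 0
    hit = rng.random(codes.size) < divergence
    if protect is not None:
        hit[protect[0] : protect[1]] = False
    idx = np.nonzero(hit)[0]
    if idx.size:
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    return out, int(idx.size)


def generate_array(
    spec: FamilySpec,
    copies: int,
    seed,
    motif_mutation_fraction: float = 0.0,
) -> tuple[str, TruthAnnotation]:
    """Generate one tandem array of `copies` monomers under `spec`.

    continuous:      straight concatenation of independently mutated copies.
    composite:       3-8 sub-arrays separated by 50-300 bp random spacers,
                     annotated as one combined major array.
    dispersed_motif: each conserved unit is followed by a random spacer of
                     0-3x the monomer length, so consecutive motif hits sit
                     at most 4 monomer lengths apart.
    microsatellite:  exact tandem of the unit (divergence ignored).

    The conserved-motif window is protected from substitution except in a
    `motif_mutation_fraction` of copies.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = _as_rng(seed)
    m = spec.monomer_length
    if spec.structure == "microsatellite":
        seq = (spec.monomer or spec.conserved_motif or MICROSAT_UNIT) * copies
        truth = TruthAnnotation("", 0, len(seq), spec.family_id, m, copies, 1.0)
        return seq, truth

    base = spec.monomer
    if base is None:
        base = generate_monomer(m, spec.conserved_motif, spec.motif_offset, rng)
    codes = _encode(base)
    protect = None
    protected_rate = spec.divergence
    if spec.conserved_motif is not None:
        w = len(spec.conserved_motif)
        protect = (spec.motif_offset, spec.motif_offset + w)
        # concentrate the divergence budget on unprotected positions so the
        # whole-copy expected identity stays 1 - divergence
        free = m - w
        protected_rate = min(0.75, spec.divergence * m / free) if free else 0.0

    def one_copy() -> tuple[np.ndarray, int]:
        window, rate = protect, protected_rate
        if window is not None and motif_mutation_fraction > 0:
            if rng.random() < motif_mutation_fraction:
                window, rate = None, spec.divergence
        return _mutate_copy(codes, rng, rate, window)

    parts: list[np.ndarray] = []
    nsubs = 0
    if spec.structure == "continuous":
        for _ in range(copies):
            c, s = one_copy()
            parts.append(c)
            nsubs += s
    elif spec.structure == "composite":
        n_sub = int(rng.integers(3, 9)) if copies >= 3 else 1
        n_sub = min(n_sub, copies)
        sizes = np.full(n_sub, copies // n_sub)
        sizes[: copies % n_sub] += 1
        for j, size in enumerate(sizes):
            if j > 0:
                parts.append(_random_codes(rng, int(rng.integers(50, 301))))
            for _ in range(size):
                c, s = one_copy()
                parts.append(c)
                nsubs += s
    elif spec.structure == "dispersed_motif":
        for _ in range(copies):
            c, s = one_copy()
            parts.append(c)
            nsubs += s
            spacer = int(rng.integers(0, 3 * m + 1))
            if spacer:
                parts.append(_random_codes(rng, spacer))
    else:  # pragma: no cover - guarded by FamilySpec validation
        raise ValueError(spec.structure)

    seq = _decode(np.concatenate(parts))
    mean_identity = 1.0 - nsubs / (copies * m)
    truth = TruthAnnotation("", 0, len(seq), spec.family_id, m, copies, mean_identity)
    return seq, truth


def default_family_specs(seed=0, divergence: float = 0.05) -> list[FamilySpec]:
    """The eight-family study setup with realized monomers shared across species.

    A family's random-fill monomer is resampled until it contains no other
    family's conserved motif (either strand) and its own motif exactly once:
    the conserved motifs are diagnostic probes by construction, mirroring
    their role in the study.
    """
    rng = _as_rng(seed)
    all_motifs = [row[1] for row in FAMILY_TABLE.values()]
    specs = []
    for fid, (mlen, motif, offset, structure, n_arrays, copies) in FAMILY_TABLE.items():
        for _ in range(200):
            monomer = generate_monomer(mlen, motif, offset, rng)
            ok = monomer.count(motif) == 1
            for other in all_motifs:
                if other == motif:
                    continue
                if other in monomer or reverse_complement(other) in monomer:
                    ok = False
            if ok and reverse_complement(motif) not in monomer:
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not realize a clean monomer for {fid}")
        specs.append(
            FamilySpec(
                family_id=fid,
                monomer_length=mlen,
                conserved_motif=motif,
                motif_offset=offset,
                copies_range=copies,
                divergence=divergence,
                structure=structure,
                arrays_per_genome=n_arrays,
                monomer=monomer,
            )
        )
    return specs


def microsat_spec() -> FamilySpec:
    return FamilySpec(
        family_id="MS",
        monomer_length=len(MICROSAT_UNIT),
        conserved_motif=None,
        motif_offset=0,
        copies_range=(100, MICROSAT_MAX_SPAN // len(MICROSAT_UNIT)),
        divergence=0.0,
        structure="microsatellite",
        array_span_range=(300, MICROSAT_MAX_SPAN),
        monomer=MICROSAT_UNIT,
    )


def default_species_profiles(genome_size: int = 1_000_000) -> list[SpeciesProfile]:
    return [
        SpeciesProfile(sid, label, tuple(fams), genome_size, tta)
        for sid, (label, fams, tta) in SPECIES_TABLE.items()
    ]


def generate_genome(
    profile: SpeciesProfile,
    specs: Sequence[FamilySpec],
    seed,
    *,
    contig_size: int = 50_000,
    noise: bool = True,
    noise_copies: int = 15,
    gc: float = 0.5,
    include_microsat: bool = True,
    include_ultralong: bool = True,
    colocalize: Sequence[tuple[str, str]] = (("f1", "f2"),),
) -> tuple[dict[str, str], list[TruthAnnotation]]:
    """Assemble a synthetic genome as contigs with embedded satDNA arrays.

    Arrays of exactly the families in ``profile.families_present`` are placed
    at non-overlapping positions; when ``noise`` is on, isolated single motif
    copies of absent families are sprinkled at low density (the genetic noise
    that array-based presence calling must ignore).  Microsatellite load
    scales with ``profile.tta_weight`` and one ultralong decayed-TE tandem
    repeat is embedded per genome by default.
    """
    rng = _as_rng(seed)
    spec_by_id = {s.family_id: s for s in specs}
    unknown = set(profile.families_present) - set(spec_by_id)
    if unknown:
        raise ValueError(f"profile references unknown families: {sorted(unknown)}")

    # ---- realize arrays, grouped so colocalized pairs stay adjacent -------
    arrays: dict[str, list[tuple[str, TruthAnnotation]]] = {}
    for fid in profile.families_present:
        spec = spec_by_id[fid]
        lo, hi = spec.copies_range
        arrays[fid] = [
            generate_array(spec, int(rng.integers(lo, hi + 1)), rng)
            for _ in range(spec.arrays_per_genome)
        ]
    if include_microsat and profile.tta_weight > 0:
        ms = microsat_spec()
        n_ms = max(1, round(12 * profile.tta_weight))
        unit = len(ms.monomer)
        lo_span, hi_span = ms.array_span_range
        arrays["MS"] = [
            generate_array(ms, int(rng.integers(lo_span // unit, hi_span // unit + 1)), rng)
            for _ in range(n_ms)
        ]
    if include_ultralong:
        ul = FamilySpec(
            family_id="uL",
            monomer_length=ULTRALONG_UNIT,
            conserved_motif=None,
            motif_offset=0,
            copies_range=(2, 3),
            divergence=0.02,
            structure="continuous",
            monomer=random_dna(rng, ULTRALONG_UNIT, gc),
        )
        arrays["uL"] = [generate_array(ul, int(rng.integers(2, 4)), rng)]

    # groups: list of (seq, [(offset_within_group, truth), ...])
    groups: list[tuple[str, list[tuple[int, TruthAnnotation]]]] = []
    for fa, fb in colocalize:
        if fa in arrays and fb in arrays and arrays[fa] and arrays[fb]:
            ia = min(range(len(arrays[fa])), key=lambda k: len(arrays[fa][k][0]))
            ib = min(range(len(arrays[fb])), key=lambda k: len(arrays[fb][k][0]))
            sa, ta = arrays[fa][ia]
            sb, tb = arrays[fb][ib]
            gap = random_dna(rng, int(rng.integers(500, 1501)), gc)
            if len(sa) + len(gap) + len(sb) > contig_size - 500:
                continue  # pairing is opportunistic; skip when it cannot fit
            groups.append((sa + gap + sb, [(0, ta), (len(sa) + len(gap), tb)]))
            arrays[fa] = [x for k, x in enumerate(arrays[fa]) if k != ia]
            arrays[fb] = [x for k, x in enumerate(arrays[fb]) if k != ib]
    for fid, items in arrays.items():
        for seq, tr in items:
            groups.append((seq, [(0, tr)]))

    n_contigs = max(1, profile.genome_size // contig_size)
    budget = [contig_size] * n_contigs
    total_arrays = sum(len(g[0]) for g in groups)
    if total_arrays > 0.8 * profile.genome_size or any(
        len(g[0]) > contig_size for g in groups
    ):
        raise ValueError(
            "genome too small to host the requested arrays; increase genome_size "
            "or contig_size"
        )

    # first-fit decreasing onto contigs (deterministic), random order within
    order = np.argsort([-len(g[0]) for g in groups], kind="stable")
    assignment: list[list[int]] = [[] for _ in range(n_contigs)]
    for gi in order:
        glen = len(groups[gi][0])
        ci = int(np.argmax(budget))
        if budget[ci] < glen + 200:
            raise ValueError("genome too small to host the requested arrays")
        assignment[ci].append(int(gi))
        budget[ci] -= glen

    contigs: dict[str, str] = {}
    truth: list[TruthAnnotation] = []
    for ci in range(n_contigs):
        cid = f"{profile.species_id}_ctg{ci:03d}"
        gids = list(assignment[ci])
        rng.shuffle(gids)
        bg_total = budget[ci]
        k = len(gids)
        if k:
            cuts = np.sort(rng.integers(0, bg_total + 1, size=k))
            seg_lens = np.diff(np.concatenate([[0], cuts, [bg_total]]))
        else:
            seg_lens = np.array([bg_total])
        pieces = []
        pos = 0
        for j in range(k + 1):
            bg = random_dna(rng, int(seg_lens[j]), gc)
            pieces.append(bg)
            pos += len(bg)
            if j < k:
                gseq, gtruth = groups[gids[j]]
                for off, tr in gtruth:
                    truth.append(
                        replace(tr, contig_id=cid, start=pos + off, end=pos + off + (tr.end - tr.start))
                    )
                pieces.append(gseq)
                pos += len(gseq)
        contigs[cid] = "".join(pieces)

    if noise:
        truth_by_contig: dict[str, list[tuple[int, int]]] = {}
        for tr in truth:
            truth_by_contig.setdefault(tr.contig_id, []).append((tr.start, tr.end))
        absent = [
            s for s in specs
            if s.family_id not in profile.families_present and s.conserved_motif
        ]
        cids = list(contigs)
        for spec in absent:
            motif = spec.conserved_motif
            for _ in range(noise_copies):
                for _attempt in range(20):
                    cid = cids[int(rng.integers(len(cids)))]
                    seq = contigs[cid]
                    if len(seq) <= len(motif):
                        continue
                    pos = int(rng.integers(0, len(seq) - len(motif)))
                    if any(
                        pos < e and pos + len(motif) > s
                        for s, e in truth_by_contig.get(cid, [])
                    ):
                        continue
                    contigs[cid] = seq[:pos] + motif + seq[pos + len(motif):]
                    break

    truth.sort(key=lambda t: (t.contig_id, t.start))
    return contigs, truth


def generate_long_reads(
    contigs: dict[str, str],
    read_length_mean: int,
    n_reads: int,
    seed,
    *,
    error_rate: float = 0.0,
    truth: Optional[list[TruthAnnotation]] = None,
) -> tuple[dict[str, str], list[dict]]:
    """Draw reads as substrings of the contigs (error-free by default).

    Returns (reads, per-read truth): each truth row maps an overlapped
    genome annotation into read-local coordinates.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = _as_rng(seed)
    cids = list(contigs)
    lens = np.array([len(contigs[c]) for c in cids], dtype=float)
    weights = lens / lens.sum()
    reads: dict[str, str] = {}
    read_truth: list[dict] = []
    for i in range(n_reads):
        ci = int(rng.choice(len(cids), p=weights))
        cid = cids[ci]
        clen = int(lens[ci])
        length = int(np.clip(rng.normal(read_length_mean, read_length_mean / 4), 500, clen))
        start = int(rng.integers(0, clen - length + 1))
        seq = contigs[cid][start : start + length]
        if error_rate > 0:
            codes, _ = _mutate_copy(_encode(seq), rng, error_rate, None)
            seq = _decode(codes)
        rid = f"read_{i:05d}"
        reads[rid] = seq
        if truth is not None:
            for tr in truth:
                if tr.contig_id != cid or tr.end <= start or tr.start >= start + length:
                    continue
                read_truth.append(
                    {
                        "read_id": rid,
                        "family_id": tr.family_id,
                        "start": max(0, tr.start - start),
                        "end": min(length, tr.end - start),
                        "period": tr.period,
                        "contig_id": cid,
                        "contig_start": tr.start,
                    }
                )
    return reads, read_truth


def simulate_study(
    seed,
    genome_size: int = 1_000_000,
    divergence: float = 0.05,
    **genome_kwargs,
):
    """Generate the full seven-genome study emulation.

    Returns (specs, profiles, genomes) where genomes maps species_id to
    (contigs, truth).  Family monomers are shared across species; each
    genome draws from its own seed stream.
    """
    specs = default_family_specs(np.random.default_rng([int(seed), 0]), divergence)
    profiles = default_species_profiles(genome_size)
    genomes = {}
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng([int(seed), i + 1])
        genomes[profile.species_id] = generate_genome(
            profile, specs, rng, **genome_kwargs
        )
    return specs, profiles, genomes
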