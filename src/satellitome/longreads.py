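"""SatDNA array characterization in long reads.

Reads are scanned with the same conserved-motif chaining used for assembled
contigs; each chained array is classified by the geometry of its motif hits
into continuous (uniform spacing near one monomer length), composite
(several continuous sub-arrays separated by short spacers) or
dispersed-motif (conserved unit at irregular distances) structure.
Ultralong tandem units (kb-scale monomers, typically decayed transposable
elements) are detected from the self-dot-plot as dominant off-diagonal
separations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .detect import self_dotplot
from .families import SatFamily
from .profile import confirm_presence, motif_scan


@dataclass
class ReadArrayCall:
    """One family array call in read-local coordinates."""

    read_id: str
    family_id: str
    start: int
    end: int
    structure: str  # continuous | composite | dispersed_motif
    copies: int
    strand: str = "+"

    @property
    def span(self) -> int:
        return self.end - self.start


def _classify_structure(positions: list[int], monomer: int) -> str:
    spac = np.diff(positions)
    if spac.size == 0:
        return "continuous"
    med = float(np.median(spac))
    if abs(med - monomer) <= 0.25 * monomer and spac.max() <= 2 * monomer:
        return "continuous"
    # split into sub-chains at gaps beyond 2 monomers
    segments: list[list[int]] = [[positions[0]]]
    seps: list[int] = []
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev > 2 * monomer:
            seps.append(cur - prev)
            segments.append([cur])
        else:
            segments[-1].append(cur)
    def is_uniform(s):
        # a true sub-array has near-constant monomer-length spacing, not just
        # a lucky median: require 80% of spacings within +-25% of the monomer
        d = np.diff(s)
        return len(s) >= 3 and np.mean(np.abs(d - monomer) <= 0.25 * monomer) >= 0.8

    good = [s for s in segments if is_uniform(s)]
    if (
        len(good) >= 2
        and all(sep <= 10 * monomer for sep in seps)
        and sum(len(s) for s in good) >= 0.6 * len(positions)
    ):
        return "composite"
    return "dispersed_motif"


def scan_read(
    seq: str,
    families: Sequence[SatFamily],
    config: Optional[RunConfig] = None,
    read_id: str = "read",
    read_gap_factor: float = 10.0,
) -> list[ReadArrayCall]:
    """Motif-chained family array calls on one read (both strands).

    Read-level chains tolerate gaps up to ``read_gap_factor`` monomer
    lengths (default 10) so a composite array — continuous sub-arrays
    separated by 2-10x monomer spacers — stays one call; structure
    classification then separates continuous, composite and
    dispersed-motif geometries.
    """
    cfg = config or RunConfig()
    calls: list[ReadArrayCall] = []
    for fam in families:
        if fam.conserved_motif is None:
            continue
        motif = fam.conserved_motif
        mlen = fam.monomer_length
        hits = motif_scan({read_id: seq}, motif)
        _, arrays = confirm_presence(
            hits,
            mlen,
            cfg.presence_min_tandem_hits,
            read_gap_factor,
            motif_length=len(motif),
        )
        by_strand: dict[str, list[int]] = {}
        for h in hits:
            by_strand.setdefault(h.strand, []).append(h.position)
        for cid, a_start, a_end, strand, n_hits in arrays:
            positions = sorted(p for p in by_strand[strand] if a_start <= p < a_end)
            structure = _classify_structure(positions, mlen)
            off = fam.motif_offset or 0
            if strand == "+":
                lead, trail = off, mlen - off
            else:
                trail_f = mlen - off - len(motif)
                lead, trail = trail_f, mlen - trail_f
            start = max(0, positions[0] - lead)
            end = min(len(seq), positions[-1] + trail)
            calls.append(
                ReadArrayCall(read_id, fam.family_id, start, end, structure, n_hits, strand)
            )
    calls.sort(key=lambda c: (c.start, c.family_id))
    return calls


def colocalization(
    calls: Sequence[ReadArrayCall], max_gap: int = 5000
) -> list[tuple[str, str, str, int]]:
    """Unordered family pairs colocalized on the same read.

    Two calls of different families colocalize when the gap between their
    intervals is at most ``max_gap`` (overlap counts as gap 0); each pair is
    reported once per read with the smallest observed gap.
    """
    by_read: dict[str, list[ReadArrayCall]] = {}
    for c in calls:
        by_read.setdefault(c.read_id, []).append(c)
    best: dict[tuple[str, str, str], int] = {}
    for rid, items in by_read.items():
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a.family_id == b.family_id:
                    continue
                gap = max(0, max(a.start, b.start) - min(a.end, b.end))
                if gap > max_gap:
                    continue
                fa, fb = sorted((a.family_id, b.family_id))
                key = (fa, fb, rid)
                if key not in best or gap < best[key]:
                    best[key] = gap
    return sorted((fa, fb, rid, gap) for (fa, fb, rid), gap in best.items())


def detect_ultralong(
    seq: str,
    min_unit: int = 5000,
    word: int = 16,
    max_word_occurrences: int = 64,
    min_runs: int = 2,
    min_unit_coverage: float = 0.5,
) -> list[tuple[int, int, int]]:
    """Ultralong tandem units from the self-dot-plot.

    A unit is called at separation d >= ``min_unit`` when word runs sharing
    that separation (within 1%) together cover >= ``min_unit_coverage`` of
    it (a perfect repeat yields a single maximal run covering the whole
    unit, so ``min_runs`` only applies when coverage is partial); the
    reported unit length is the
    run-length-weighted modal separation.  Separations that are multiples of
    an accepted shorter unit are suppressed.  Returns (start, end,
    unit_length) tuples; reads shorter than 2x ``min_unit`` yield [].
    """
    if len(seq) < 2 * min_unit:
        return []
    runs = [
        m
        for m in self_dotplot(seq, word=word, max_word_occurrences=max_word_occurrences)
        if m.separation >= min_unit
    ]
    if not runs:
        return []
    runs.sort(key=lambda m: m.separation)
    groups: list[list] = [[runs[0]]]
    for m in runs[1:]:
        if m.separation <= groups[-1][-1].separation * 1.01:
            groups[-1].append(m)
        else:
            groups.append([m])
    candidates = []
    for grp in groups:
        weights = Counter()
        for m in grp:
            weights[m.separation] += m.length
        unit = max(weights, key=lambda d: (weights[d], -d))
        intervals = sorted((m.pos_a, m.pos_a + m.length) for m in grp)
        cov, cur_s, cur_e = 0, *intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                cov += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        cov += cur_e - cur_s
        if cov < min_unit_coverage * unit:
            continue
        if len(grp) < min_runs and cov < 0.9 * unit:
            continue
        start = min(m.pos_a for m in grp)
        end = max(m.pos_b + m.length for m in grp)
        candidates.append((start, end, unit, cov))
    kept: list[tuple[int, int, int]] = []
    for start, end, unit, _cov in sorted(candidates, key=lambda c: c[2]):
        if any(
            abs(unit - round(unit / ku) * ku) <= 0.02 * unit and round(unit / ku) >= 2
            for _, _, ku in kept
        ):
            continue
        kept.append((start, end, unit))
    kept.sort()
    return kept


def calls_to_tsv(calls: Sequence[ReadArrayCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tfamily_id\tstart\tend\tstructure\tcopies\tstrand\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.family_id}\t{c.start}\t{c.end}\t"
                f"{c.structure}\t{c.copies}\t{c.strand}\n"
            )
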