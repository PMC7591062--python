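"""Consensus monomers, conserved motifs and cross-genome satDNA families.

Tandem monomers have arbitrary phase, so consensus building aligns copies by
best circular rotation (substitution-only scoring) and takes a column-wise
majority; families are single-linkage clusters of array consensi under
rotation-aligned identity.  The conserved motif of a family is the 9-12 bp
consensus window that the largest fraction of monomers contains exactly,
mirroring its downstream use as a zero-mismatch scanning probe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .detect import SatArray

_ACGT = np.array([65, 67, 71, 84], dtype=np.uint8)


@dataclass
class SatFamily:
    """A cross-genome repeat family."""

    family_id: str
    consensus: str
    conserved_motif: Optional[str]
    motif_offset: Optional[int]
    members: list[tuple[str, SatArray]] = field(default_factory=list)
    origin_category: Optional[str] = None  # group | lineage | species | absent

    def __post_init__(self):
        if self.conserved_motif is not None:
            if not 9 <= len(self.conserved_motif) <= 12:
                raise ValueError("conserved motif must be 9-12 bp")
            circ = self.consensus + self.consensus[: len(self.conserved_motif) - 1]
            if circ[self.motif_offset : self.motif_offset + len(self.conserved_motif)] != self.conserved_motif:
                raise ValueError("conserved motif is not at its offset in the consensus")

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def is_microsatellite(self) -> bool:
        return len(self.consensus) <= 6

    @property
    def total_span(self) -> int:
        return sum(a.span for _, a in self.members)

    @property
    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self.members})


def _to_matrix(seqs: Sequence[str]) -> list[np.ndarray]:
    return [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]


def _best_rotation(mon: np.ndarray, ref: np.ndarray) -> int:
    """Rotation of `mon` maximizing identity to `ref` over the overlap."""
    m = mon.size
    L = min(m, ref.size)
    idx = (np.arange(m)[None, :] + np.arange(m)[:, None]) % m  # row r = rotation r
    scores = (mon[idx][:, :L] == ref[:L]).sum(axis=1)
    return int(np.argmax(scores))


def build_consensus(monomers: Sequence[str]) -> str:
    """Majority-rule consensus of rotation-aligned monomers.

    Monomers are aligned by their best circular rotation to a fixed reference
    (the lexicographically smallest input monomer, which makes the result
    invariant to input order); columns are decided by majority with ties
    broken by base order A<C<G<T.  The consensus length is the modal monomer
    length.  Requires >= 2 monomers, all within +-20% of the median length.
    """
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers to build a consensus")
    lengths = np.array([len(m) for m in monomers])
    med = float(np.median(lengths))
    if (np.abs(lengths - med) > 0.2 * med).any():
        raise ValueError(
            "monomer lengths vary by more than 20% of the median; "
            "re-segment the array before consensus building"
        )
    modal_len = Counter(lengths.tolist()).most_common()
    best_count = modal_len[0][1]
    target = min(l for l, c in modal_len if c == best_count)
    ref = min(monomers)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    counts = np.zeros((4, target), dtype=np.int64)
    for mon in _to_matrix(monomers):
        r = _best_rotation(mon, ref_arr)
        rot = np.roll(mon, -r)[:target]
        for bi, b in enumerate(_ACGT):
            cols = np.nonzero(rot == b)[0]
            counts[bi, cols] += 1
    return _ACGT[counts.argmax(axis=0)].tobytes().decode()


def conserved_motif(
    monomers: Sequence[str],
    consensus: str,
    min_len: int = 9,
    max_len: int = 12,
    sample_cap: int = 150,
) -> tuple[str, int]:
    """Most conserved 9-12 bp window of the consensus (treated circularly).

    Conservation of a window is the fraction of monomers containing it as an
    exact substring; ties prefer the longer window, then the smaller offset.
    """
    if len(consensus) < min_len:
        raise ValueError("consensus shorter than the minimum motif length")
    if len(monomers) > sample_cap:
        idx = np.linspace(0, len(monomers) - 1, sample_cap).astype(int)
        monomers = [monomers[i] for i in idx]
    circ = consensus + consensus[: max_len - 1]
    best = None  # (count, length, -offset)
    for length in range(min_len, min(max_len, len(consensus)) + 1):
        for off in range(len(consensus)):
            window = circ[off : off + length]
            count = sum(1 for m in monomers if window in m)
            key = (count, length, -off)
            if best is None or key > best[0]:
                best = (key, window, off)
    return best[1], best[2]


def best_rotation_identity(a: str, b: str) -> float:
    """Best circular-rotation, free-end-gap identity of the shorter vs the longer.

    The shorter sequence is rotated over all phases and slid over the longer;
    identity is matches over the shorter length.
    """
    if len(a) > len(b):
        a, b = b, a
    sa = np.frombuffer(a.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.encode(), dtype=np.uint8)
    m, L = sa.size, sb.size
    if m == 0:
        raise ValueError("empty sequence")
    idx = (np.arange(m)[None, :] + np.arange(m)[:, None]) % m
    rots = sa[idx]  # (m rotations, m)
    windows = np.lib.stride_tricks.sliding_window_view(sb, m)  # (L-m+1, m)
    matches = (windows[:, None, :] == rots[None, :, :]).sum(axis=2)
    return float(matches.max()) / m


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_families(
    arrays_by_species: Mapping[str, Sequence[SatArray]],
    identity_threshold: float = 0.80,
    length_ratio_min: float = 0.6,
    motif_min_len: int = 9,
    motif_max_len: int = 12,
    consensus_monomer_cap: int = 300,
) -> list[SatFamily]:
    """Single-linkage clustering of array consensi into satDNA families.

    Two arrays link iff their consensus monomer lengths are compatible
    (min/max >= ``length_ratio_min``) and their best rotation-aligned
    identity is >= ``identity_threshold`` (default 0.80, the lower end of
    reported within-family similarity).  Each cluster is re-consensused from
    pooled member monomers, its conserved motif derived, and family ids are
    assigned deterministically by decreasing total member span.
    """
    items: list[tuple[str, SatArray, str]] = []
    for sp in sorted(arrays_by_species):
        for arr in arrays_by_species[sp]:
            cons = arr.consensus or build_consensus(arr.monomers)
            items.append((sp, arr, cons))
    if not items:
        return []
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ca, cb = items[i][2], items[j][2]
            ratio = min(len(ca), len(cb)) / max(len(ca), len(cb))
            if ratio < length_ratio_min:
                continue
            if best_rotation_identity(ca, cb) >= identity_threshold:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(uf.find(i), []).append(i)

    built: list[SatFamily] = []
    for root in sorted(clusters):
        members = clusters[root]
        pooled: list[str] = []
        per_arr = max(2, consensus_monomer_cap // len(members))
        for i in members:
            mons = items[i][1].monomers
            if len(mons) > per_arr:
                idx = np.linspace(0, len(mons) - 1, per_arr).astype(int)
                mons = [mons[k] for k in idx]
            pooled.extend(mons)
        # anchored-mode members can carry slightly inflated unit estimates;
        # restrict the joint consensus to monomers near the median length
        med = float(np.median([len(m) for m in pooled])) if pooled else 0.0
        usable = [m for m in pooled if abs(len(m) - med) <= 0.2 * med]
        if len(usable) >= 2:
            consensus = build_consensus(usable)
        else:
            consensus = max((items[i][2] for i in members), key=len)
        motif, offset = (None, None)
        if len(consensus) >= motif_min_len:
            motif, offset = conserved_motif(
                pooled if len(pooled) >= 2 else [consensus, consensus],
                consensus,
                motif_min_len,
                motif_max_len,
            )
        fam = SatFamily(
            family_id="pending",
            consensus=consensus,
            conserved_motif=motif,
            motif_offset=offset,
            members=[(items[i][0], items[i][1]) for i in members],
        )
        built.append(fam)
    built.sort(key=lambda f: (-f.total_span, f.consensus))
    for rank, fam in enumerate(built, start=1):
        fam.family_id = f"fam{rank}"
    return built


def families_to_fasta(families: Sequence[SatFamily], path) -> None:
    """Serialize family consensi with motif/offset metadata in the description."""
    with open(path, "w") as fh:
        for f in families:
            desc = []
            if f.conserved_motif is not None:
                desc.append(f"motif={f.conserved_motif}")
                desc.append(f"offset={f.motif_offset}")
            if f.origin_category:
                desc.append(f"category={f.origin_category}")
            fh.write(f">{f.family_id} {' '.join(desc)}\n{f.consensus}\n")


def families_from_fasta(path) -> list[SatFamily]:
    fams = []
    with open(path) as fh:
        header, seq = None, []
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    fields = dict(
                        kv.split("=", 1) for kv in header.split()[1:] if "=" in kv
                    )
                    fams.append(
                        SatFamily(
                            family_id=header.split()[0],
                            consensus="".join(seq).upper(),
                            conserved_motif=fields.get("motif"),
                            motif_offset=int(fields["offset"]) if "offset" in fields else None,
                            origin_category=fields.get("category"),
                        )
                    )
                header, seq = line[1:] or None, []
            elif line:
                seq.append(line)
    return fams


def families_to_table(families: Sequence[SatFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tmonomer_length\tconserved_motif\tmotif_offset\t"
            "n_arrays\tn_species\ttotal_span\tcategory\n"
        )
        for f in families:
            fh.write(
                f"{f.family_id}\t{f.monomer_length}\t{f.conserved_motif or '.'}\t"
                f"{f.motif_offset if f.motif_offset is not None else '.'}\t"
                f"{len(f.members)}\t{len(f.species)}\t{f.total_span}\t"
                f"{f.origin_category or '.'}\n"
            )
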