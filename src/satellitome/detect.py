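"""Tandem-repeat array detection.

Periodicity is measured by direct base-identity autocorrelation: the score of
a candidate period p over a window is the fraction of positions i whose base
equals the base p ahead.  Candidate windows are restricted by exact k-mer
recurrence (a position is repetitive when the same word recurs within the
maximum period), scored over all periods, refined to base-accurate
boundaries, and phased to a canonical monomer rotation.  Irregularly spaced
families whose conserved unit is separated by variable spacers carry no
autocorrelation peak; those are recovered by an anchored mode that chains
recurrences of the most frequent exact word in the window.

Self-dot-plots (exact shared-word matches collapsed to maximal diagonal
runs) are provided for visual inspection and ultralong-unit detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

_LUT5 = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _LUT5[ord(_b)] = _i
_ACGT = np.array([65, 67, 71, 84], dtype=np.uint8)  # tie-break order A<C<G<T


@dataclass(frozen=True)
class DotPlotMatch:
    """A maximal run of exact shared words between two positions (upper triangle)."""

    pos_a: int
    pos_b: int
    length: int

    @property
    def separation(self) -> int:
        return self.pos_b - self.pos_a


@dataclass
class SatArray:
    """One detected tandem array (0-based half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    period: int
    copies: int
    monomers: list[str]
    consensus: str
    mean_pairwise_identity: float
    score: float
    structure: str = "continuous"

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DetectParams:
    """Detector knobs; defaults documented in docs/methods.md."""

    word: int = 12
    max_period: int = 500
    min_score: float = 0.60
    harmonic_tolerance: float = 0.03
    boundary_floor: float = 0.70
    min_copies: int = 3
    merge_gap: int = 500
    min_region: int = 40
    anchor_min_copies: int = 8


def _seq_to_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (raw uint8 chars, base-5 codes with N=4); rejects other chars."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _LUT5[raw & 0x7F]
    if (codes == 255).any():
        raise ValueError("sequence contains characters other than A/C/G/T/N")
    return raw, codes


def _kmer_codes(codes5: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-5 integer codes for every k-word plus a validity mask (no N)."""
    n = codes5.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    has_n = np.zeros(n - k + 1, dtype=bool)
    for j in range(k):
        col = codes5[j : n - k + 1 + j]
        vals = vals * 5 + col
        has_n |= col == 4
    return vals, ~has_n


def self_dotplot(
    seq: str,
    word: int = 12,
    step: int = 1,
    max_word_occurrences: int = 100,
) -> list[DotPlotMatch]:
    """Exact shared-word self-matches, deduplicated into maximal diagonal runs.

    Only the upper triangle (pos_a < pos_b) is reported; a perfect tandem of
    period p yields runs at separations p, 2p, ...  Words occurring more than
    ``max_word_occurrences`` times are skipped (they would contribute a
    quadratic blow-up of pairs without adding structure).
    """
    if word < 4:
        raise ValueError("word must be >= 4")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(seq) < word:
        return []
    _, codes5 = _seq_to_codes(seq)
    vals, valid = _kmer_codes(codes5, word)
    pos = np.arange(vals.size)[valid]
    if step > 1:
        pos = pos[pos % step == 0]
    vals = vals[pos]
    order = np.argsort(vals, kind="stable")
    sv, sp = vals[order], pos[order]
    # group boundaries of equal codes
    bounds = np.nonzero(np.diff(sv))[0] + 1
    groups = np.split(sp, bounds)
    pairs_a: list[np.ndarray] = []
    pairs_b: list[np.ndarray] = []
    for g in groups:
        c = g.size
        if c < 2 or c > max_word_occurrences:
            continue
        ia, ib = np.triu_indices(c, k=1)
        pairs_a.append(g[ia])
        pairs_b.append(g[ib])
    if not pairs_a:
        return []
    a = np.concatenate(pairs_a)
    b = np.concatenate(pairs_b)
    diag = b - a
    order = np.lexsort((a, diag))
    a, b, diag = a[order], b[order], diag[order]
    out: list[DotPlotMatch] = []
    link = max(word, step)
    run_a = int(a[0])
    run_end = int(a[0]) + word
    run_d = int(diag[0])
    for i in range(1, a.size):
        if diag[i] == run_d and a[i] <= run_end + (link - word):
            run_end = max(run_end, int(a[i]) + word)
        else:
            out.append(DotPlotMatch(run_a, run_a + run_d, run_end - run_a))
            run_a, run_end, run_d = int(a[i]), int(a[i]) + word, int(diag[i])
    out.append(DotPlotMatch(run_a, run_a + run_d, run_end - run_a))
    return out


def dotplot_to_tsv(matches: Sequence[DotPlotMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("pos_a\tpos_b\tlength\n")
        for m in matches:
            fh.write(f"{m.pos_a}\t{m.pos_b}\t{m.length}\n")


def _period_scores(
    sub: np.ndarray,
    max_period: int,
    floor: float,
    tol: float,
    min_period: int = 1,
) -> list[tuple[int, float]]:
    n = sub.size
    mp = min(max_period, n // 2)
    if mp < min_period:
        return []
    scores = np.full(mp + 2, -1.0)
    for p in range(min_period, mp + 1):
        scores[p] = np.count_nonzero(sub[:-p] == sub[p:]) / (n - p)
    cands = [
        p
        for p in range(min_period, mp + 1)
        if scores[p] >= floor and scores[p] >= scores[p - 1] and scores[p] >= scores[p + 1]
    ]
    kept: list[int] = []
    for p in cands:  # ascending; keep fundamentals, drop comparable harmonics
        if any(p % q == 0 and scores[p] - scores[q] <= tol for q in kept):
            continue
        kept.append(p)
    out = [(p, float(scores[p])) for p in kept]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def estimate_period(
    seq: str,
    max_period: int,
    min_score: float = 0.60,
    harmonic_tolerance: float = 0.03,
) -> list[tuple[int, float]]:
    """Rank candidate repeat periods of ``seq`` by autocorrelation identity.

    score(p) is the mean base identity between seq[i] and seq[i+p]; returned
    periods are local maxima above ``min_score`` with harmonics (2p, 3p, ...)
    suppressed in favor of the fundamental when their scores are within
    ``harmonic_tolerance``.  Sorted by score (ties: smaller period first).
    """
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    raw, _ = _seq_to_codes(seq)
    return _period_scores(raw, max_period, min_score, harmonic_tolerance)


def _majority(M: np.ndarray) -> np.ndarray:
    counts = np.stack([(M == b).sum(axis=0) for b in _ACGT])
    return _ACGT[counts.argmax(axis=0)]


def _xdrop_extend(
    raw: np.ndarray,
    edge: int,
    direction: int,
    cons: np.ndarray,
    phase_origin: int,
    period: int,
    xdrop: int = 12,
    max_ext: Optional[int] = None,
) -> int:
    """Locate an array boundary base-by-base against the cyclic consensus.

    Walks outward from ``edge`` (exclusive), scoring +1 per match and -2 per
    mismatch, and returns the offset of the score argmax — so a boundary
    anchored one period inside the array can both trim and extend."""
    n = raw.size
    best, best_t, score = 0, 0, 0
    if max_ext is None:
        max_ext = 2 * period + 20
    for t in range(1, max_ext + 1):
        pos = edge + direction * t if direction > 0 else edge - t
        if pos < 0 or pos >= n:
            break
        ci = (pos - phase_origin) % period
        score += 1 if raw[pos] == cons[ci] else -2
        if score > best:
            best, best_t = score, t
        if score < best - xdrop:
            break
    return best_t


def _pairwise_identity(monomers: list[str], cap: int = 40) -> float:
    if len(monomers) < 2:
        return 1.0
    if len(monomers) > cap:
        idx = np.linspace(0, len(monomers) - 1, cap).astype(int)
        monomers = [monomers[i] for i in idx]
    L = min(len(m) for m in monomers)
    M = np.stack([np.frombuffer(m[:L].encode(), dtype=np.uint8) for m in monomers])
    k = M.shape[0]
    total, npairs = 0.0, 0
    for i in range(k - 1):
        total += (M[i + 1 :] == M[i]).mean(axis=1).sum()
        npairs += k - 1 - i
    return float(total / npairs)


def _canonical_rotation(cons: str) -> tuple[str, int]:
    rot = min(range(len(cons)), key=lambda r: cons[r:] + cons[:r])
    return cons[rot:] + cons[:rot], rot


def _refine_periodic(
    raw: np.ndarray,
    seq: str,
    seq_id: str,
    s: int,
    e: int,
    period: int,
    params: DetectParams,
) -> Optional[SatArray]:
    k = (e - s) // period
    if k < 2:
        return None
    M = raw[s : s + k * period].reshape(k, period)
    # seed from the most self-consistent adjacent monomer pair: a global
    # majority would mix phases when spacers (composite arrays) or a second
    # array desynchronize the monomer grid within the window
    adj = (M[1:] == M[:-1]).mean(axis=1)
    i0 = int(np.argmax(adj))
    if adj[i0] < params.boundary_floor:
        return None
    cons = M[i0]
    ident = (M == cons).mean(axis=1)
    lo = hi = i0
    while lo > 0 and ident[lo - 1] >= params.boundary_floor:
        lo -= 1
    while hi < k - 1 and ident[hi + 1] >= params.boundary_floor:
        hi += 1
    cons = _majority(M[lo : hi + 1])
    ident = (M == cons).mean(axis=1)
    lo = hi = i0
    while lo > 0 and ident[lo - 1] >= params.boundary_floor:
        lo -= 1
    while hi < k - 1 and ident[hi + 1] >= params.boundary_floor:
        hi += 1
    gs, ge = s + lo * period, s + (hi + 1) * period
    # if the refined consensus is an exact self-repetition the window was
    # scored at a harmonic (e.g. a trinucleotide microsatellite caught at a
    # multiple of 3 in a mixed window); reduce to the fundamental unit — the
    # interval [gs, ge) stays valid because the old grid is a refinement
    for d in range(2, period // 2 + 1):
        if period % d == 0 and not (cons != np.tile(cons[:d], period // d)).any():
            cons = cons[:d]
            period = d
            break
    # anchor the boundary search one period inside the run so that edge
    # monomers partially overlapping background can be trimmed as well as
    # extended; the score argmax settles on the true transition
    ga = min(gs + period, ge - 1)
    gb = max(ge - period, ga)
    ext = 3 * period + 30
    left = _xdrop_extend(raw, ga, -1, cons, gs, period, max_ext=ext)
    right = _xdrop_extend(raw, gb - 1, +1, cons, gs, period, max_ext=ext)
    start, end = ga - left, gb + right
    if end - start < period:
        return None
    copies = int(round((end - start) / period))
    if copies < params.min_copies:
        return None
    cons_str = cons.tobytes().decode()
    canonical, rot = _canonical_rotation(cons_str)
    off = (rot - (start - gs)) % period
    m0 = start + off
    monomers = [seq[i : i + period] for i in range(m0, end - period + 1, period)]
    return SatArray(
        seq_id=seq_id,
        start=start,
        end=end,
        period=period,
        copies=copies,
        monomers=monomers,
        consensus=canonical,
        mean_pairwise_identity=_pairwise_identity(monomers),
        score=float(ident[lo : hi + 1].mean()),
        structure="continuous",
    )


def _anchored_array(
    raw: np.ndarray,
    codes5: np.ndarray,
    seq: str,
    seq_id: str,
    s: int,
    e: int,
    params: DetectParams,
) -> Optional[SatArray]:
    vals, valid = _kmer_codes(codes5[s:e], params.word)
    if vals.size == 0 or not valid.any():
        return None
    v = vals[valid]
    pos = np.arange(vals.size)[valid]
    uniq, counts = np.unique(v, return_counts=True)
    best = int(np.argmax(counts))
    if counts[best] < params.anchor_min_copies:
        return None
    anchors = np.sort(pos[v == uniq[best]]) + s
    gaps = np.diff(anchors)
    if gaps.size == 0:
        return None
    unit = int(gaps.min())
    if unit < 10 or unit > params.max_period:
        return None
    monomers = [
        seq[int(a) : int(a) + unit] for a in anchors if int(a) + unit <= raw.size
    ]
    if len(monomers) < 2:
        return None
    M = np.stack([np.frombuffer(m.encode(), dtype=np.uint8) for m in monomers])
    cons = _majority(M)
    ident = float((M == cons).mean())
    start, end = int(anchors[0]), int(anchors[-1]) + unit
    return SatArray(
        seq_id=seq_id,
        start=start,
        end=end,
        period=unit,
        copies=int(anchors.size),
        monomers=monomers,
        consensus=cons.tobytes().decode(),
        mean_pairwise_identity=ident,
        score=ident,
        structure="dispersed_motif",
    )


def _candidate_regions(
    codes5: np.ndarray, params: DetectParams
) -> list[tuple[int, int]]:
    vals, valid = _kmer_codes(codes5, params.word)
    if vals.size == 0:
        return []
    pos = np.arange(vals.size)[valid]
    v = vals[valid]
    order = np.argsort(v, kind="stable")
    sv, sp = v[order], pos[order]
    same = sv[1:] == sv[:-1]
    gaps = sp[1:] - sp[:-1]
    hit = same & (gaps <= params.max_period)
    starts = sp[:-1][hit]
    ends = sp[1:][hit] + params.word
    if starts.size == 0:
        return []
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    regions: list[tuple[int, int]] = []
    cs, ce = int(starts[0]), int(ends[0])
    for i in range(1, starts.size):
        if starts[i] <= ce + params.merge_gap:
            ce = max(ce, int(ends[i]))
        else:
            regions.append((cs, ce))
            cs, ce = int(starts[i]), int(ends[i])
    regions.append((cs, ce))
    return [(a, b) for a, b in regions if b - a >= params.min_region]


def find_arrays(
    seq: str, params: Optional[DetectParams] = None, seq_id: str = "seq"
) -> list[SatArray]:
    """Detect tandem arrays in one sequence.

    Candidate windows (exact-word recurrence within the maximum period) are
    scored for periodicity; each detected array is boundary-refined so
    flanking background is excluded, phased to the lexicographically
    smallest consensus rotation, and the window remainder is re-scanned so
    adjacent arrays of different families are found separately.  Same-period
    arrays separated by short spacers are merged (composite arrays);
    overlapping calls with different periods keep the higher score.
    """
    p = params or DetectParams()
    n = len(seq)
    if n < 2 * p.word:
        return []
    raw, codes5 = _seq_to_codes(seq)
    arrays: list[SatArray] = []
    for rs, re_ in _candidate_regions(codes5, p):
        rs, re_ = max(0, rs - 30), min(n, re_ + 30)
        stack = [(rs, re_)]
        guard = 0
        anchored_tried = False
        while stack and guard < 64:
            guard += 1
            s, e = stack.pop()
            if e - s < p.min_region:
                continue
            cands = _period_scores(
                raw[s:e],
                min(p.max_period, (e - s) // 2),
                p.min_score,
                p.harmonic_tolerance,
                min_period=2,
            )
            arr = None
            if cands:
                arr = _refine_periodic(raw, seq, seq_id, s, e, cands[0][0], p)
            if arr is not None:
                arrays.append(arr)
                if arr.start - s >= p.min_region:
                    stack.append((s, arr.start))
                if e - arr.end >= p.min_region:
                    stack.append((arr.end, e))
            elif not anchored_tried:
                anchored_tried = True
                arr = _anchored_array(raw, codes5, seq, seq_id, s, e, p)
                if arr is not None:
                    arrays.append(arr)
    arrays.sort(key=lambda a: a.start)
    arrays = _merge_nearby(arrays, p.merge_gap)
    arrays = _resolve_overlaps(arrays)
    arrays.sort(key=lambda a: a.start)
    return arrays


def _merge_nearby(arrays: list[SatArray], merge_gap: int) -> list[SatArray]:
    out: list[SatArray] = []
    for a in arrays:
        if out:
            b = out[-1]
            ratio = min(a.period, b.period) / max(a.period, b.period)
            gap = a.start - b.end
            if 0 <= gap <= merge_gap and ratio >= 0.9:
                big, small = (b, a) if b.span >= a.span else (a, b)
                merged = SatArray(
                    seq_id=b.seq_id,
                    start=b.start,
                    end=a.end,
                    period=big.period,
                    copies=b.copies + a.copies,
                    monomers=b.monomers + a.monomers,
                    consensus=big.consensus,
                    mean_pairwise_identity=(
                        b.mean_pairwise_identity * b.span + a.mean_pairwise_identity * a.span
                    )
                    / (b.span + a.span),
                    score=max(a.score, b.score),
                    structure="composite" if gap > 0 else big.structure,
                )
                out[-1] = merged
                continue
        out.append(a)
    return out


def _resolve_overlaps(arrays: list[SatArray]) -> list[SatArray]:
    keep = [True] * len(arrays)
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if not (keep[i] and keep[j]):
                continue
            a, b = arrays[i], arrays[j]
            if b.start >= a.end:
                break
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0.5 * min(a.span, b.span) and a.period != b.period:
                if a.score >= b.score:
                    keep[j] = False
                else:
                    keep[i] = False
    return [a for a, k in zip(arrays, keep) if k]


def filter_arrays(
    arrays: Sequence[SatArray],
    minisat_period_max: int = 60,
    min_copies_minisat: int = 30,
    min_copies_sat: int = 5,
) -> list[SatArray]:
    """Apply the study's array-selection thresholds.

    Minisatellites (period <= ``minisat_period_max``) must exceed
    ``min_copies_minisat`` monomers; longer-period satellites must exceed
    ``min_copies_sat``.  Both comparisons are strict, order is preserved.
    """
    if min(minisat_period_max, min_copies_minisat, min_copies_sat) <= 0:
        raise ValueError("thresholds must be positive")
    out = []
    for a in arrays:
        cutoff = min_copies_minisat if a.period <= minisat_period_max else min_copies_sat
        if a.copies > cutoff:
            out.append(a)
    return out


def extract_monomers(seq: str, array: SatArray) -> list[str]:
    """Consecutive period-length slices of the array interval.

    The final partial slice is dropped, so the count equals
    floor(span / period); degenerate arrays (span < period) yield [].
    """
    p = array.period
    return [
        seq[array.start + i * p : array.start + (i + 1) * p]
        for i in range(array.span // p)
    ]
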