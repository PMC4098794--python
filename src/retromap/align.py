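"""Greedy seed-and-extend split alignment.

A minimal ungapped aligner sufficient for desk-scale chimera detection:
exact 20-mer seeds located through a sorted integer k-mer index, extended
ungapped in both directions with an X-drop criterion, then non-overlapping
query segments retained best-score-first.  Each retained segment carries a
``uniqueness_margin`` — its score minus the best score of any competing
placement of (essentially) the same query stretch — which operationalizes
the "unambiguously mapped" requirement of the integration caller.

The alignment target is the host genome with the provirus appended as an
extra chromosome, so chimeric reads split into a host segment and a
provirus segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, Provirus, revcomp

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start; invalid where a non-ACGT base occurs."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    for i in range(k):
        vals = vals * 4 + np.maximum(codes[i : i + n], 0)
    bad = np.concatenate([[0], np.cumsum(codes < 0)])
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid


@dataclass
class AlignedSegment:
    """An ungapped alignment of a read substring to one reference location.

    ``qstart/qend`` are half-open coordinates in the read as sequenced;
    ``strand`` is the strand of the reference the read aligns to.
    """

    read_id: str
    mate: int
    qstart: int
    qend: int
    ref: str
    rstart: int
    rend: int
    strand: str
    score: float
    identity: float
    uniqueness_margin: float = 0.0

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart


class SeedIndex:
    """Sorted-integer exact k-mer index over a set of reference sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 20, max_hits: int = 64):
        self.k = k
        self.max_hits = max_hits
        self.sequences = sequences
        self.names = list(sequences)
        codes_all = []
        pos_all = []
        self._bounds = []
        gstart = 0
        for name in self.names:
            seq = sequences[name]
            codes = _encode(seq)
            vals, valid = _kmer_codes(codes, k)
            idx = np.nonzero(valid)[0]
            codes_all.append(vals[idx])
            pos_all.append(idx + gstart)
            self._bounds.append((gstart, gstart + len(seq), name))
            gstart += len(seq)
        codes_cat = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.int64)
        pos_cat = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes_cat, kind="stable")
        self._codes = codes_cat[order]
        self._pos = pos_cat[order]
        self._starts = np.array([b[0] for b in self._bounds], dtype=np.int64)

    @classmethod
    def from_genome(cls, genome: Genome, provirus: Provirus | None = None,
                    k: int = 20, max_hits: int = 64) -> "SeedIndex":
        seqs = dict(genome.sequences)
        if provirus is not None:
            seqs[provirus.name] = provirus.sequence
        return cls(seqs, k=k, max_hits=max_hits)

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def locate(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._starts, gpos, side="right") - 1)
        start, _end, name = self._bounds[i]
        return name, gpos - start


def _extend(
    q: str, ref: str, qpos: int, rpos: int, k: int,
    match: int = 1, mismatch: int = -3, xdrop: int = 6,
) -> tuple[int, int, int, float, float]:
    """Ungapped X-drop extension around an exact seed.

    Returns (qstart, qend, rstart, score, identity) with qstart/qend relative
    to ``q`` and rstart the reference coordinate aligned to qstart.
    """
    # right extension from seed end
    score = k
    best = score
    best_q = qpos + k
    i, j = qpos + k, rpos + k
    while i < len(q) and j < len(ref):
        score += match if q[i] == ref[j] else mismatch
        i += 1
        j += 1
        if score > best:
            best, best_q = score, i
        if score <= best - xdrop:
            break
    right_q = best_q
    right_score = best
    # left extension from seed start
    score = right_score
    best = score
    best_q = qpos
    i, j = qpos, rpos
    while i > 0 and j > 0:
        score += match if q[i - 1] == ref[j - 1] else mismatch
        i -= 1
        j -= 1
        if score > best:
            best, best_q = score, i
        if score <= best - xdrop:
            break
    left_q = best_q
    total = best
    length = right_q - left_q
    # with unit match score: total = matches - 3*mismatches, length = matches + mismatches
    mism = (length - total) // (match - mismatch) if length else 0
    identity = (length - mism) / length if length else 0.0
    rstart = rpos - (qpos - left_q)
    return left_q, right_q, rstart, float(total), float(identity)


def split_align_read(
    read: str,
    index: SeedIndex,
    read_id: str = "",
    mate: int = 1,
    min_seg: int = 25,
    seed_step: int = 5,
    max_overlap: int = 8,
) -> list[AlignedSegment]:
    """Split a read into non-overlapping aligned segments, best-score-first.

    Unalignable reads (e.g. all N) yield an empty list.  Segments shorter
    than ``min_seg`` are discarded after selection.
    """
    k = index.k
    read = read.upper()
    if len(read) < k:
        return []
    placements: list[AlignedSegment] = []
    for strand in "+-":
        q = read if strand == "+" else revcomp(read)
        codes = _encode(q)
        vals, valid = _kmer_codes(codes, k)
        offsets = list(range(0, len(q) - k + 1, seed_step))
        if offsets[-1] != len(q) - k:
            offsets.append(len(q) - k)
        seen_diag: set[tuple[int, int]] = set()
        for off in offsets:
            if not valid[off]:
                continue
            hits = index.lookup(int(vals[off]))
            if hits.size == 0 or hits.size > index.max_hits:
                continue
            for gpos in hits:
                ref_name, rpos = index.locate(int(gpos))
                key = (ref_name, rpos - off)  # one seed per alignment diagonal
                if key in seen_diag:
                    continue
                seen_diag.add(key)
                ref = index.sequences[ref_name]
                qs, qe, rs, score, ident = _extend(q, ref, off, rpos, k)
                if strand == "+":
                    seg_qs, seg_qe = qs, qe
                else:
                    seg_qs, seg_qe = len(q) - qe, len(q) - qs
                placements.append(
                    AlignedSegment(
                        read_id=read_id, mate=mate,
                        qstart=seg_qs, qend=seg_qe,
                        ref=ref_name, rstart=rs, rend=rs + (qe - qs),
                        strand=strand, score=score, identity=ident,
                    )
                )
    # deduplicate identical placements (same query span and reference span)
    uniq: dict[tuple, AlignedSegment] = {}
    for p in placements:
        key = (p.qstart, p.qend, p.ref, p.rstart, p.strand)
        if key not in uniq or p.score > uniq[key].score:
            uniq[key] = p
    placements = sorted(
        uniq.values(),
        key=lambda p: (-p.score, p.ref, p.rstart, p.strand, p.qstart),
    )
    accepted: list[AlignedSegment] = []
    for p in placements:
        overlap = 0
        for a in accepted:
            overlap = max(overlap, min(p.qend, a.qend) - max(p.qstart, a.qstart))
        if overlap > max_overlap:
            continue
        accepted.append(p)
    # uniqueness margin: competitors cover >= 50% of the accepted query span
    # at a different reference placement
    for a in accepted:
        margin = a.score
        for p in placements:
            if p is a:
                continue
            if (p.ref, p.rstart, p.strand) == (a.ref, a.rstart, a.strand):
                continue
            ov = min(p.qend, a.qend) - max(p.qstart, a.qstart)
            if ov >= 0.5 * a.qlen:
                margin = min(margin, a.score - p.score)
        a.uniqueness_margin = float(margin)
    return [a for a in accepted if a.qlen >= min_seg]
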