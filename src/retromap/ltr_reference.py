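"""LTR-likeness scan and chimera-filtering reference.

The chimera filter needs a compact reference holding (a) every genome window
with high ungapped identity to the viral LTR — endogenous LTR-like decoys —
and (b) the proviral sequences themselves.  Read pairs in which exactly one
mate matches this reference are candidate chimeras.

The scan slides the LTR along both strands of the genome in fixed increments
(default 5 bp) and keeps windows with ungapped identity at or above a
threshold (default 0.90).  Ungapped identity (matches / window length) is a
deterministic, oracle-checkable stand-in for gapped local alignment; decoys
diverged by indels are a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, Provirus, revcomp


@dataclass
class LTRLikeRegion:
    chrom: str
    start: int
    end: int
    identity: float
    source_window_offsets: list[int] = field(default_factory=list)


def _identity_profile(
    seq: str, query: str, step: int, max_n_frac: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset ungapped identity of ``query`` against ``seq`` on a step grid.

    Returns (offsets, identity); windows with more than ``max_n_frac`` N are
    assigned identity -1 (skipped).  N never matches (the query is N-free).
    """
    wlen = len(query)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    offsets = np.arange(0, len(arr) - wlen + 1, step, dtype=np.int64)
    ident = np.empty(offsets.size, dtype=np.float64)
    is_n = (arr == ord("N")).astype(np.int32)
    n_cum = np.concatenate([[0], np.cumsum(is_n)])
    chunk = 20_000
    cols = np.arange(wlen)
    for lo in range(0, offsets.size, chunk):
        off = offsets[lo : lo + chunk]
        windows = arr[off[:, None] + cols[None, :]]
        ident[lo : lo + chunk] = (windows == q[None, :]).mean(axis=1)
    n_count = n_cum[offsets + wlen] - n_cum[offsets]
    ident[n_count > max_n_frac * wlen] = -1.0
    return offsets, ident


def scan_ltr_like(
    genome: Genome,
    ltr: str,
    step: int = 5,
    min_identity: float = 0.90,
    window_len: int | None = None,
) -> list[LTRLikeRegion]:
    """Find genome windows with LTR identity >= ``min_identity`` on both strands.

    Offsets on the step grid meeting the threshold are merged into maximal
    regions; each region reports its best identity and the contributing
    window offsets.
    """
    if window_len is None:
        window_len = len(ltr)
    if window_len > len(ltr):
        raise ValueError("window_len must be <= LTR length")
    if not 0 < step <= window_len:
        raise ValueError("step must be in (0, window_len]")
    queries = [ltr[i : i + window_len] for i in range(0, len(ltr) - window_len + 1, window_len)]
    regions: list[LTRLikeRegion] = []
    for chrom, seq in genome.sequences.items():
        if len(seq) < window_len:
            warnings.warn(f"{chrom} shorter than the scan window; skipped")
            continue
        best: np.ndarray | None = None
        offsets = None
        for query in queries:
            for q in (query, revcomp(query)):
                offsets, ident = _identity_profile(seq, q, step)
                best = ident if best is None else np.maximum(best, ident)
        hits = np.nonzero(best >= min_identity)[0]
        if hits.size == 0:
            continue
        # merge overlapping hit windows into maximal regions
        cur_offsets = [int(offsets[hits[0]])]
        cur_end = int(offsets[hits[0]]) + window_len
        cur_best = float(best[hits[0]])
        for h in hits[1:]:
            o = int(offsets[h])
            if o <= cur_end:
                cur_offsets.append(o)
                cur_end = o + window_len
                cur_best = max(cur_best, float(best[h]))
            else:
                regions.append(
                    LTRLikeRegion(chrom, cur_offsets[0], cur_end, cur_best, cur_offsets)
                )
                cur_offsets = [o]
                cur_end = o + window_len
                cur_best = float(best[h])
        regions.append(
            LTRLikeRegion(chrom, cur_offsets[0], cur_end, cur_best, cur_offsets)
        )
    return regions


def write_regions_bed(regions: list[LTRLikeRegion], path) -> None:
    """BED6 with identity scaled x1000 in the score column."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tltr_like\t{int(round(r.identity * 1000))}\t.\n"
            )


@dataclass
class RefEntry:
    name: str
    sequence: str
    kind: str  # "decoy" | "provirus"


def decoy_entry_name(chrom: str, start: int, end: int) -> str:
    return f"decoy|{chrom}:{start}-{end}"


def parse_entry_name(name: str) -> tuple[str, ...]:
    """Invert entry naming: ('decoy', chrom, start, end) or ('provirus', name)."""
    kind, rest = name.split("|", 1)
    if kind == "provirus":
        return ("provirus", rest)
    chrom, span = rest.rsplit(":", 1)
    start, end = span.split("-")
    return ("decoy", chrom, int(start), int(end))


@dataclass
class ChimeraReference:
    """Named decoy + provirus sequences with an exact k-mer lookup index."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference entry names")
        self._kmer_cache: dict[int, set[str]] = {}

    def kmer_set(self, k: int) -> set[str]:
        """All k-mers of all entries, both strands."""
        cached = self._kmer_cache.get(k)
        if cached is not None:
            return cached
        kmers: set[str] = set()
        for entry in self.entries:
            for seq in (entry.sequence, revcomp(entry.sequence)):
                kmers.update(seq[i : i + k] for i in range(len(seq) - k + 1))
        self._kmer_cache[k] = kmers
        return kmers

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name}\n")
                for i in range(0, len(e.sequence), 80):
                    fh.write(e.sequence[i : i + 80] + "\n")


def build_chimera_reference(
    regions: list[LTRLikeRegion],
    genome: Genome,
    proviruses: list[Provirus],
    flank: int = 100,
) -> ChimeraReference:
    """One decoy entry per region (extended by ``flank``, clipped at chromosome
    ends) plus every provirus; entry names encode source coordinates
    reversibly."""
    entries: list[RefEntry] = []
    for r in regions:
        seq = genome.sequences.get(r.chrom)
        if seq is None or r.start < 0 or r.end > len(seq):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside genome")
        s = max(0, r.start - flank)
        e = min(len(seq), r.end + flank)
        entries.append(RefEntry(decoy_entry_name(r.chrom, s, e), seq[s:e], "decoy"))
    for pv in proviruses:
        entries.append(RefEntry(f"provirus|{pv.name}", pv.sequence, "provirus"))
    return ChimeraReference(entries=entries)
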