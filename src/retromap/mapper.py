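"""Chimeric read-pair classification and integration calling.

Pipeline stages:

1. :func:`prefix_filter` — map each mate's leading 25 bp against the chimera
   reference; keep pairs in which exactly one mate matches (the candidate
   chimeras).
2. :func:`split_align_read` (in :mod:`retromap.align`) against the host
   genome with the provirus as an extra chromosome.
3. :func:`classify_pair` — assign each candidate pair to one signature cell
   (element x fusion-coverage x transcription direction) or NOT_CHIMERIC /
   AMBIGUOUS.
4. :func:`call_integrations` — cluster junction evidence into per-sample
   integration calls; a call needs at least 40 bp of unambiguously mapped
   host sequence in one supporting pair.
5. :func:`filter_endogenous` — positions called in two or more samples are
   endogenous false positives (insertion at the exact same base in
   independent tumors is improbable) and are removed everywhere.

Signature taxonomy
------------------
``element``   : U3 | U5 | SD — which proviral element abuts host sequence at
                the junction.
``coverage``  : FUSION_M1 | FUSION_M2 | SPANNING — which mate (if any)
                contains the host/virus fusion; SPANNING pairs bracket the
                junction with one fully-viral and one fully-host mate.
``direction`` : MOUSE_TO_VIRUS | VIRUS_TO_MOUSE — transcription order across
                the junction under the strand-specific library convention
                (mate1 carries the transcript sense strand).
Six (element, direction) combinations are physically constructible (U3 and
U5 in both directions; SD at the donor side virus->mouse and at the env-SA
acceptor side mouse->virus), giving 18 cells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedSegment, SeedIndex, split_align_read
from .genome import Provirus, revcomp
from .ltr_reference import ChimeraReference
from .simulate import ReadPair

DIRECTIONS = ("MOUSE_TO_VIRUS", "VIRUS_TO_MOUSE")


@dataclass(frozen=True)
class PESignatureClass:
    element: str  # U3 | U5 | SD
    coverage: str  # FUSION_M1 | FUSION_M2 | SPANNING
    direction: str  # MOUSE_TO_VIRUS | VIRUS_TO_MOUSE

    def __post_init__(self) -> None:
        if self.element not in ("U3", "U5", "SD"):
            raise ValueError(f"bad element {self.element!r}")
        if self.coverage not in ("FUSION_M1", "FUSION_M2", "SPANNING"):
            raise ValueError(f"bad coverage {self.coverage!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")

    def label(self) -> str:
        return f"{self.element}:{self.coverage}:{self.direction}"


@dataclass
class PairEvidence:
    """Classification outcome for one read pair."""

    read_id: str
    sample: str
    status: str  # "chimeric" | "not_chimeric" | "ambiguous"
    signature: PESignatureClass | None = None
    chrom: str | None = None
    position: int | None = None  # host-genome junction coordinate
    approximate: bool = False
    mouse_len: int = 0
    mouse_margin: float = 0.0
    orientation: str | None = None  # S | AS provirus orientation vote


@dataclass
class IntegrationCall:
    sample: str
    chrom: str
    position: int  # 0-based internally; +1 in human-readable reports
    orientation: str
    fusion_supported: bool
    n_pairs: int
    n_fusion_reads: int
    signatures: Counter = field(default_factory=Counter)
    approximate: bool = False
    relative_coverage: float = float("nan")


def prefix_filter(
    pairs, ref: ChimeraReference, prefix_len: int = 25
) -> tuple[list[ReadPair], dict]:
    """Keep pairs in which exactly one mate's leading ``prefix_len`` bases (or
    their reverse complement) occur in the reference; order-preserving."""
    index = ref.kmer_set(prefix_len)
    kept: list[ReadPair] = []
    stats = {"kept": 0, "dropped_both": 0, "dropped_neither": 0, "malformed": 0}
    for pair in pairs:
        if len(pair.seq1) < prefix_len or len(pair.seq2) < prefix_len:
            stats["malformed"] += 1
            continue
        hits = []
        for seq in (pair.seq1, pair.seq2):
            p = seq[:prefix_len].upper()
            hits.append(p in index or revcomp(p) in index)
        if hits[0] ^ hits[1]:
            kept.append(pair)
            stats["kept"] += 1
        elif hits[0]:
            stats["dropped_both"] += 1
        else:
            stats["dropped_neither"] += 1
    return kept, stats


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# expected host-genome transcription strand for a sense-orientation provirus
_SENSE_SIGN = {
    ("U3", "MOUSE_TO_VIRUS"): "+",
    ("U3", "VIRUS_TO_MOUSE"): "-",
    ("U5", "VIRUS_TO_MOUSE"): "+",
    ("U5", "MOUSE_TO_VIRUS"): "-",
    ("SD", "VIRUS_TO_MOUSE"): "+",
    ("SD", "MOUSE_TO_VIRUS"): "+",
}


def _anchor_candidates(provirus: Provirus, direction: str, dp: str) -> list[tuple[int, str]]:
    """Junction anchors in provirus coordinates for a transcript that enters
    (mouse->virus) or exits (virus->mouse) the provirus along strand ``dp``.

    The two LTRs are identical, so U3/U5 anchors accept the equivalent
    coordinate in either copy.
    """
    el = provirus.elements
    L = len(provirus)
    ltr = provirus.ltr_len
    if direction == "VIRUS_TO_MOUSE":
        if dp == "+":
            return [(L, "U5"), (ltr, "U5"), (el["SD"][1], "SD")]
        return [(0, "U3"), (L - ltr, "U3")]
    if dp == "+":
        return [(0, "U3"), (L - ltr, "U3"), (el["env_SA"][0], "SD")]
    return [(L, "U5"), (ltr, "U5")]


def _nearest_anchor(
    c: int, candidates: list[tuple[int, str]], tol: int
) -> str | None:
    best = min(candidates, key=lambda a: abs(c - a[0]))
    return best[1] if abs(c - best[0]) <= tol else None


def _mate_groups(segs: list[AlignedSegment], provirus_name: str):
    viral = [s for s in segs if s.ref == provirus_name]
    mouse = [s for s in segs if s.ref != provirus_name]
    return viral, mouse


def classify_pair(
    segs1: list[AlignedSegment],
    segs2: list[AlignedSegment],
    provirus: Provirus,
    read_id: str = "",
    sample: str = "",
    orientation: str = "FR",
    fusion_anchor_tol: int = 12,
    spanning_anchor_tol: int = 600,
) -> PairEvidence:
    """Total classifier: every pair maps to one signature cell, NOT_CHIMERIC,
    or AMBIGUOUS (contradictory segment layout)."""
    if orientation != "FR":
        # RF libraries are handled by swapping mates up front
        segs1, segs2 = segs2, segs1
    pv = provirus.name
    v1, m1 = _mate_groups(segs1, pv)
    v2, m2 = _mate_groups(segs2, pv)
    chim = [bool(v1 and m1), bool(v2 and m2)]

    def fusion_eval(mate: int):
        viral, mouse = (v1, m1) if mate == 1 else (v2, m2)
        # the (mouse, viral) segment pair that is query-adjacent
        best = None
        for mv in mouse:
            for vv in viral:
                gap = max(mv.qstart, vv.qstart) - min(mv.qend, vv.qend)
                key = (abs(gap), -(mv.qlen + vv.qlen))
                if best is None or key < best[0]:
                    best = (key, mv, vv)
        if best is None:
            return None
        _, mseg, vseg = best
        mouse_first_in_read = mseg.qstart < vseg.qstart
        mouse_first = mouse_first_in_read if mate == 1 else not mouse_first_in_read
        direction = "MOUSE_TO_VIRUS" if mouse_first else "VIRUS_TO_MOUSE"
        # provirus-frame transcript strand
        dp = vseg.strand if mate == 1 else _flip(vseg.strand)
        # viral coordinate facing the mouse segment in query order
        viral_on_left = vseg.qstart < mseg.qstart
        if vseg.strand == "+":
            c = vseg.rend if viral_on_left else vseg.rstart
        else:
            c = vseg.rstart if viral_on_left else vseg.rend
        element = _nearest_anchor(
            c, _anchor_candidates(provirus, direction, dp), fusion_anchor_tol
        )
        if element is None:
            return None
        # host coordinate facing the viral segment
        mouse_on_left = not viral_on_left
        if mseg.strand == "+":
            g = mseg.rend if mouse_on_left else mseg.rstart
        else:
            g = mseg.rstart if mouse_on_left else mseg.rend
        dg = mseg.strand if mate == 1 else _flip(mseg.strand)
        ori = "S" if dg == _SENSE_SIGN[(element, direction)] else "AS"
        return direction, element, mseg, g, ori

    if chim[0] or chim[1]:
        evals = {}
        for mate in (1, 2):
            if chim[mate - 1]:
                evals[mate] = fusion_eval(mate)
        good = {m: e for m, e in evals.items() if e is not None}
        if not good:
            return PairEvidence(read_id, sample, "ambiguous")
        if len(good) == 2:
            (d1, e1, ms1, g1, o1), (d2, e2, ms2, g2, o2) = good[1], good[2]
            if e1 != e2 or abs(g1 - g2) > fusion_anchor_tol or ms1.ref != ms2.ref:
                return PairEvidence(read_id, sample, "ambiguous")
        mate = min(good)
        direction, element, mseg, g, ori = good[mate]
        sig = PESignatureClass(element, f"FUSION_M{mate}", direction)
        return PairEvidence(
            read_id, sample, "chimeric", sig, mseg.ref, int(g), False,
            mseg.qlen, mseg.uniqueness_margin, ori,
        )

    # no chimeric mate: spanning, or not chimeric at all
    mate1_viral = bool(v1) and not m1
    mate1_mouse = bool(m1) and not v1
    mate2_viral = bool(v2) and not m2
    mate2_mouse = bool(m2) and not v2
    if mate1_viral and mate2_mouse:
        viral_mate, mouse_mate = 1, 2
        vseg = max(v1, key=lambda s: s.score)
        mseg = max(m2, key=lambda s: s.score)
    elif mate1_mouse and mate2_viral:
        viral_mate, mouse_mate = 2, 1
        vseg = max(v2, key=lambda s: s.score)
        mseg = max(m1, key=lambda s: s.score)
    else:
        return PairEvidence(read_id, sample, "not_chimeric")

    # mate1 is the transcript-5' mate under the FR convention
    direction = "MOUSE_TO_VIRUS" if mouse_mate == 1 else "VIRUS_TO_MOUSE"
    dp = vseg.strand if viral_mate == 1 else _flip(vseg.strand)
    # junction-facing viral coordinate: transcript-5' end of a downstream viral
    # mate, transcript-3' end of an upstream viral mate
    viral_downstream = direction == "MOUSE_TO_VIRUS"
    if viral_downstream:
        c = vseg.rstart if dp == "+" else vseg.rend
    else:
        c = vseg.rend if dp == "+" else vseg.rstart
    element = _nearest_anchor(
        c, _anchor_candidates(provirus, direction, dp), spanning_anchor_tol
    )
    if element is None:
        return PairEvidence(read_id, sample, "ambiguous")
    dg = mseg.strand if mouse_mate == 1 else _flip(mseg.strand)
    # host inner (junction-facing) coordinate
    mouse_downstream = not viral_downstream
    if mouse_downstream:
        g = mseg.rstart if dg == "+" else mseg.rend
    else:
        g = mseg.rend if dg == "+" else mseg.rstart
    ori = "S" if dg == _SENSE_SIGN[(element, direction)] else "AS"
    sig = PESignatureClass(element, "SPANNING", direction)
    return PairEvidence(
        read_id, sample, "chimeric", sig, mseg.ref, int(g), True,
        mseg.qlen, mseg.uniqueness_margin, ori,
    )


def classify_pairs(
    pairs: list[ReadPair],
    index: SeedIndex,
    provirus: Provirus,
    min_seg: int = 25,
    **kwargs,
) -> list[PairEvidence]:
    """Split-align both mates of every pair and classify."""
    out = []
    for pair in pairs:
        s1 = split_align_read(pair.seq1, index, pair.id, 1, min_seg=min_seg)
        s2 = split_align_read(pair.seq2, index, pair.id, 2, min_seg=min_seg)
        out.append(
            classify_pair(s1, s2, provirus, pair.id, pair.sample, **kwargs)
        )
    return out


def _cluster_positions(positions: list[int], tol: int) -> list[list[int]]:
    """Single-linkage grouping of sorted indices by gap <= tol; returns index
    groups over the sorted order."""
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    groups: list[list[int]] = []
    for i in order:
        if groups and positions[i] - positions[groups[-1][-1]] <= tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def call_integrations(
    evidence: list[PairEvidence],
    min_unambig: int = 40,
    cluster_tol: int = 10,
    spanning_tol: int = 600,
) -> tuple[list[IntegrationCall], list[IntegrationCall]]:
    """Cluster pair evidence into integration calls, per sample.

    Fusion-read junctions (exact) are clustered at ``cluster_tol``; spanning
    pairs localize the junction only to within the unsequenced insert gap and
    are attached to the nearest fusion cluster within ``spanning_tol``,
    with leftovers forming approximate fusionless calls.  A call requires at
    least one pair whose host-side segment is >= ``min_unambig`` bp with
    positive uniqueness margin; sub-threshold clusters are returned in the
    second ("unsupported") list.  Calling is order-independent.
    """
    chimeric = [e for e in evidence if e.status == "chimeric"]
    calls: list[IntegrationCall] = []
    unsupported: list[IntegrationCall] = []
    samples = sorted({e.sample for e in chimeric})
    for sample in samples:
        sample_calls: list[IntegrationCall] = []
        ev = [e for e in chimeric if e.sample == sample]
        chroms = sorted({e.chrom for e in ev})
        for chrom in chroms:
            on_chrom = [e for e in ev if e.chrom == chrom]
            fusion = [e for e in on_chrom if e.signature.coverage.startswith("FUSION")]
            spanning = [e for e in on_chrom if e.signature.coverage == "SPANNING"]
            fusion.sort(key=lambda e: (e.position, e.read_id))
            groups = _cluster_positions([e.position for e in fusion], cluster_tol)
            clusters = [[fusion[i] for i in g] for g in groups]
            centers = [
                int(np.median([e.position for e in c])) for c in clusters
            ]
            leftover: list[PairEvidence] = []
            for e in sorted(spanning, key=lambda e: (e.position, e.read_id)):
                if centers:
                    d = [abs(e.position - c) for c in centers]
                    k = int(np.argmin(d))
                    if d[k] <= spanning_tol:
                        clusters[k].append(e)
                        continue
                leftover.append(e)
            lgroups = _cluster_positions([e.position for e in leftover], spanning_tol)
            clusters.extend([leftover[i] for i in g] for g in lgroups)
            for cluster in clusters:
                fus = [e for e in cluster if e.signature.coverage.startswith("FUSION")]
                if fus:
                    pos_counts = Counter(e.position for e in fus)
                    top = max(pos_counts.values())
                    position = min(p for p, n in pos_counts.items() if n == top)
                    approximate = False
                else:
                    position = int(np.median([e.position for e in cluster]))
                    approximate = True
                ori_counts = Counter(e.orientation for e in cluster)
                orientation = max(sorted(ori_counts), key=lambda o: ori_counts[o])
                call = IntegrationCall(
                    sample=sample,
                    chrom=cluster[0].chrom,
                    position=position,
                    orientation=orientation,
                    fusion_supported=bool(fus),
                    n_pairs=len(cluster),
                    n_fusion_reads=len(fus),
                    signatures=Counter(e.signature.label() for e in cluster),
                    approximate=approximate,
                )
                supported = any(
                    e.mouse_len >= min_unambig and e.mouse_margin > 0
                    for e in cluster
                )
                (sample_calls if supported else unsupported).append(call)
        if sample_calls:
            mean_pairs = float(np.mean([c.n_pairs for c in sample_calls]))
            for c in sample_calls:
                c.relative_coverage = c.n_pairs / mean_pairs
        calls.extend(sample_calls)
    return calls, unsupported


def filter_endogenous(
    calls: list[IntegrationCall], position_tol: int = 10
) -> tuple[list[IntegrationCall], pd.DataFrame]:
    """Remove loci called in >= 2 samples (endogenous false positives).

    Returns (filtered calls, removed-locus table with sample multiplicity).
    """
    removed_rows = []
    keep = list(calls)
    by_chrom: dict[str, list[IntegrationCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    to_remove: set[int] = set()
    for chrom, cs in sorted(by_chrom.items()):
        cs.sort(key=lambda c: (c.position, c.sample))
        groups = _cluster_positions([c.position for c in cs], position_tol)
        for g in groups:
            members = [cs[i] for i in g]
            samples = {m.sample for m in members}
            if len(samples) >= 2:
                for m in members:
                    to_remove.add(id(m))
                removed_rows.append(
                    {
                        "chrom": chrom,
                        "position": int(np.median([m.position for m in members])),
                        "n_samples": len(samples),
                        "samples": ",".join(sorted(samples)),
                    }
                )
    filtered = [c for c in keep if id(c) not in to_remove]
    removed = pd.DataFrame(
        removed_rows, columns=["chrom", "position", "n_samples", "samples"]
    )
    return filtered, removed


def calls_to_frame(calls: list[IntegrationCall]) -> pd.DataFrame:
    """Human-readable call table (1-based positions)."""
    rows = [
        {
            "sample": c.sample,
            "chrom": c.chrom,
            "pos": c.position + 1,
            "orientation": c.orientation,
            "fusion": "+" if c.fusion_supported else "-",
            "n_pairs": c.n_pairs,
            "n_fusion_reads": c.n_fusion_reads,
            "signatures": ";".join(f"{k}={v}" for k, v in sorted(c.signatures.items())),
            "relative_coverage": round(c.relative_coverage, 4),
            "approximate": c.approximate,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "orientation", "fusion", "n_pairs",
                 "n_fusion_reads", "signatures", "relative_coverage", "approximate"],
    )
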