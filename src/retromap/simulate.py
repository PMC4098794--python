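"""Synthetic-data generation with known ground truth.

Everything downstream of this module (LTR-like reference construction,
chimeric read mapping, annotation, enrichment statistics, deregulation
pattern calling) is exercised on data produced here: small genomes seeded
with LTR-like decoy loci, planted proviruses with target-site duplications
(TSDs), strand-specific paired-end libraries containing junction-spanning
chimeric fragments, and peak/integration sets with a controllable planted
enrichment fold.

All randomness flows from a single integer seed through one named
``numpy.random.Generator`` per operation, so a scenario regenerates
byte-identically from its recorded seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import Genome, Provirus, revcomp
from .intervals import Interval, subtract_intervals, total_length

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default per-junction mean fragment counts.  Chosen so a junction transcript
# typically yields well over five fusion-covered pairs (see docs/methods.md).
DEFAULT_EXPRESSION = {"u3_readin": 50.0, "u5_promoter": 50.0, "sd_splice": 50.0}


@dataclass
class PlantedProvirus:
    """A provirus to integrate: where, in which orientation, how expressed."""

    chrom: str
    insertion_point: int
    orientation: str = "S"  # S: provirus plus strand == genome plus strand
    tsd_len: int = 4
    expression: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSION))

    def __post_init__(self) -> None:
        if self.orientation not in ("S", "AS"):
            raise ValueError("orientation must be 'S' or 'AS'")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if any(v < 0 for v in self.expression.values()):
            raise ValueError("expression means must be >= 0")


@dataclass
class ScenarioTruth:
    """Everything needed to regenerate a scenario and score results against it."""

    seed: int
    params: dict = field(default_factory=dict)
    decoys: list[dict] = field(default_factory=list)
    proviruses: dict[str, list[dict]] = field(default_factory=dict)  # sample -> sites
    peaks: list[dict] = field(default_factory=list)
    enrichment_fold: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    sample: str = ""
    qual: str = "I"


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute round((1-identity)*len) distinct positions to other bases."""
    n_sub = int(round((1.0 - identity) * len(seq)))
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = bytearray(seq.encode())
    for p in pos:
        alt = [b for b in b"ACGT" if b != out[p]]
        out[p] = alt[rng.integers(3)]
    return out.decode()


def make_provirus(
    seed: int = 0,
    u3: int = 250,
    r: int = 70,
    u5: int = 80,
    internal_len: int = 7200,
    env_sa_offset: int = 5400,
    gc: float = 0.5,
    name: str = "SL33",
) -> Provirus:
    """Build a synthetic SL3-3-like provirus with identical 5' and 3' LTRs.

    The splice donor is placed 30 bp after the 5' LTR (GT motif); the env
    splice acceptor ends with AG at ``env_sa_offset`` from the sequence start.
    """
    rng = np.random.default_rng(seed)
    ltr_len = u3 + r + u5
    ltr = _random_seq(ltr_len, gc, rng)
    internal = list(_random_seq(internal_len, gc, rng))
    sd_start = 30  # relative to internal
    internal[sd_start : sd_start + 2] = "GT"
    sa_rel = env_sa_offset - ltr_len
    if not (sd_start + 6 < sa_rel and sa_rel + 6 < internal_len):
        raise ValueError("env_sa_offset must fall inside the internal sequence")
    internal[sa_rel + 4 : sa_rel + 6] = "AG"
    seq = ltr + "".join(internal) + ltr
    L = len(seq)
    elements = {
        "5U3": (0, u3),
        "5R": (u3, u3 + r),
        "5U5": (u3 + r, ltr_len),
        "SD": (ltr_len + sd_start, ltr_len + sd_start + 6),
        "env_SA": (ltr_len + sa_rel, ltr_len + sa_rel + 6),
        "3U3": (L - ltr_len, L - ltr_len + u3),
        "3R": (L - ltr_len + u3, L - u5),
        "3U5": (L - u5, L),
    }
    return Provirus(name=name, sequence=seq, elements=elements)


def make_genome(
    n_chrom: int,
    lengths: list[int],
    gc: float,
    decoy_spec: list[tuple[float, int]],
    ltr: str,
    seed: int,
    align_grid: int = 5,
    margin: int = 1000,
) -> tuple[Genome, ScenarioTruth]:
    """Random genome with planted LTR-like decoy loci.

    ``decoy_spec`` is a list of (identity, count) pairs; each decoy is the LTR
    with substitutions placed uniformly to hit the requested identity within
    one substitution.  Decoy offsets are snapped to ``align_grid`` (default 5,
    matching the 5-bp increments of the LTR-likeness scan) and placed without
    mutual overlap; failure to fit raises an error naming the chromosome.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if any(l < 10_000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    for ident, _ in decoy_spec:
        if not 0.5 <= ident <= 1.0:
            raise ValueError("decoy identities must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {name: _random_seq(l, gc, rng) for name, l in zip(names, lengths)}

    wlen = len(ltr)
    placed: dict[str, list[Interval]] = {name: [] for name in names}
    decoys = []
    weights = np.array(lengths, dtype=float) / sum(lengths)
    for ident, count in decoy_spec:
        for _ in range(count):
            chrom = names[rng.choice(n_chrom, p=weights)]
            clen = len(seqs[chrom])
            ok = False
            for _attempt in range(200):
                hi = (clen - margin - wlen - margin) // align_grid
                if hi <= 0:
                    break
                start = margin + int(rng.integers(0, hi + 1)) * align_grid
                iv = (start, start + wlen)
                if all(iv[1] <= s or iv[0] >= e for s, e in placed[chrom]):
                    ok = True
                    break
            if not ok:
                raise ValueError(f"cannot place decoy without overlap on {chrom}")
            placed[chrom].append(iv)
            strand = "+" if rng.random() < 0.5 else "-"
            body = mutate_to_identity(ltr, ident, rng)
            if strand == "-":
                body = revcomp(body)
            seqs[chrom] = seqs[chrom][: iv[0]] + body + seqs[chrom][iv[1] :]
            decoys.append(
                {"chrom": chrom, "start": iv[0], "end": iv[1], "identity": ident,
                 "strand": strand}
            )
    genome = Genome(sequences=seqs)
    truth = ScenarioTruth(
        seed=seed,
        params={"n_chrom": n_chrom, "lengths": lengths, "gc": gc,
                "decoy_spec": [list(d) for d in decoy_spec], "align_grid": align_grid},
        decoys=decoys,
    )
    return genome, truth


def plant_proviruses(
    genome: Genome, provirus: Provirus, sites: list[PlantedProvirus]
) -> tuple[Genome, pd.DataFrame]:
    """Integrate proviruses with TSDs; return the modified genome and junctions.

    At each site the host sequence becomes
    ``host[:p+tsd] + provirus + host[p:]`` (the TSD ``host[p:p+tsd]`` is
    duplicated around the provirus; antisense sites insert the reverse
    complement).  The junction table reports left/right junction coordinates
    in both the original and the modified coordinate system.
    """
    by_chrom: dict[str, list[PlantedProvirus]] = {}
    for s in sites:
        if s.chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {s.chrom}")
        by_chrom.setdefault(s.chrom, []).append(s)
    pv_len = len(provirus)
    new_seqs = dict(genome.sequences)
    rows = []
    for chrom, chrom_sites in by_chrom.items():
        chrom_sites.sort(key=lambda s: s.insertion_point)
        seq = genome.sequences[chrom]
        for a, b in zip(chrom_sites, chrom_sites[1:]):
            if b.insertion_point < a.insertion_point + a.tsd_len:
                raise ValueError(f"overlapping insertion sites on {chrom}")
        pieces = []
        cursor = 0
        offset = 0
        for s in chrom_sites:
            p, t = s.insertion_point, s.tsd_len
            region = seq[p : p + t]
            if "N" in region or "N" in seq[max(0, p - 1) : p + 1]:
                raise ValueError(f"insertion site {chrom}:{p} lies in an N region")
            body = provirus.sequence if s.orientation == "S" else revcomp(provirus.sequence)
            pieces.append(seq[cursor : p + t])
            pieces.append(body)
            cursor = p
            left_mod = p + t + offset
            rows.append(
                {
                    "chrom": chrom,
                    "insertion_point": p,
                    "orientation": s.orientation,
                    "tsd_len": t,
                    "left_jx_orig": p + t,
                    "right_jx_orig": p,
                    "left_jx_mod": left_mod,
                    "right_jx_mod": left_mod + pv_len,
                }
            )
            offset += pv_len + t
        pieces.append(seq[cursor:])
        new_seqs[chrom] = "".join(pieces)
    table = pd.DataFrame(
        rows,
        columns=["chrom", "insertion_point", "orientation", "tsd_len",
                 "left_jx_orig", "right_jx_orig", "left_jx_mod", "right_jx_mod"],
    )
    return Genome(sequences=new_seqs), table


# --- junction transcript construction -------------------------------------

#: transcript kinds and their (element, direction) signature at the junction
JUNCTION_KINDS = ("u3_readin", "u5_promoter", "sd_splice")


def junction_transcript(
    genome_mod: Genome,
    provirus: Provirus,
    row,
    kind: str,
    up: int = 400,
    into: int = 400,
    down: int = 800,
) -> tuple[str, int, int]:
    """Build one chimeric junction transcript.

    Returns ``(sequence, junction_offset, junction_orig_coord)`` where the
    junction offset is the transcript coordinate of the host/virus boundary
    and the orig coord is the host-genome (pre-integration) junction base.

    * ``u3_readin``  — host transcription reading through the 5' LTR
      (mouse -> U3, direction mouse-to-virus).
    * ``u5_promoter`` — retroviral promoter insertion: the 3' LTR drives an
      R+U5 leader into downstream host sequence (U5 -> mouse).
    * ``sd_splice``  — viral R..SD leader spliced onto host sequence at the
      3' junction (SD -> mouse).
    """
    gseq = genome_mod.sequences[row["chrom"]]
    Lm, Rm = int(row["left_jx_mod"]), int(row["right_jx_mod"])
    p, t = int(row["insertion_point"]), int(row["tsd_len"])
    pv = provirus.sequence
    vlen = provirus.elements["5U5"][1] - provirus.elements["5R"][0]  # R+U5 leader
    leader = pv[provirus.elements["5R"][0] : provirus.elements["SD"][1]]
    if row["orientation"] == "S":
        if kind == "u3_readin":
            return gseq[Lm - up : Lm + into], up, p + t
        if kind == "u5_promoter":
            return gseq[Rm - vlen : Rm + down], vlen, p
        if kind == "sd_splice":
            return leader + gseq[Rm : Rm + down], len(leader), p
    else:
        if kind == "u3_readin":
            return revcomp(gseq[Rm - into : Rm + up]), up, p
        if kind == "u5_promoter":
            return revcomp(gseq[Lm - down : Lm + vlen]), vlen, p + t
        if kind == "sd_splice":
            return leader + revcomp(gseq[Lm - down : Lm]), len(leader), p + t
    raise ValueError(f"unknown junction transcript kind {kind!r}")


def _truncated_normal(
    n: int, mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_library(
    genome_mod: Genome,
    junction_table: pd.DataFrame,
    provirus: Provirus,
    sites: list[PlantedProvirus],
    read_len: int = 101,
    frag_mean: float = 325.0,
    frag_sd: float = 50.0,
    frag_max: int = 600,
    orientation: str = "FR",
    background_rate: float = 0.0,
    seed: int = 0,
    sample: str = "s1",
    up: int = 400,
    into: int = 400,
    down: int = 800,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate a strand-specific paired-end library over planted junctions.

    Fragment counts per junction transcript are Poisson with the site's
    expression mean; fragments are placed uniformly along the transcript with
    lengths from Normal(frag_mean, frag_sd) truncated to [read_len, frag_max].
    With the default FR convention mate1 carries the transcript sense strand.
    Background fragments are drawn genome-wide at ``background_rate``
    fragments per kb.  The truth table records, per fragment, whether a mate
    covers the junction base (fusion read) or only the pair spans it.
    """
    if read_len > frag_mean:
        raise ValueError("read_len must be <= frag_mean")
    if orientation not in ("FR", "RF"):
        raise ValueError("orientation must be FR or RF")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    rows = []
    counter = 0

    def emit(tseq: str, start: int, flen: int, meta: dict) -> None:
        nonlocal counter
        frag = tseq[start : start + flen]
        m1 = frag[:read_len]
        m2 = revcomp(frag[-read_len:])
        if orientation == "RF":
            m1, m2 = m2, m1
        rid = f"{sample}:{counter:06d}"
        counter += 1
        pairs.append(ReadPair(id=rid, seq1=m1, seq2=m2, sample=sample))
        rows.append({"id": rid, "start": start, "frag_len": flen, **meta})

    # junction transcripts; the table may be reordered relative to `sites`
    by_key = {(s.chrom, s.insertion_point): s for s in sites}
    site_rows = junction_table.to_dict("records")
    if len(site_rows) != len(by_key):
        raise ValueError("junction table and site list disagree")
    for row in site_rows:
        site = by_key[(row["chrom"], row["insertion_point"])]
        for kind in JUNCTION_KINDS:
            mean = site.expression.get(kind, 0.0)
            if mean <= 0:
                continue
            tseq, j, orig = junction_transcript(
                genome_mod, provirus, row, kind, up=up, into=into, down=down
            )
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            flens = np.minimum(
                _truncated_normal(n, frag_mean, frag_sd, read_len, frag_max, rng),
                len(tseq),
            ).astype(int)
            for flen in flens:
                start = int(rng.integers(0, len(tseq) - flen + 1))
                m1_cov = start < j < start + read_len
                m2_cov = start + flen - read_len < j < start + flen
                spanning = start < j < start + flen
                emit(
                    tseq, start, int(flen),
                    {
                        "kind": kind,
                        "chrom": row["chrom"],
                        "junction_orig": orig,
                        "insertion_point": row["insertion_point"],
                        "orientation": site.orientation,
                        "m1_covers": m1_cov,
                        "m2_covers": m2_cov,
                        "spanning": spanning,
                        "junction_offset": j,
                    },
                )

    # background fragments from the (provirus-containing) genome
    if background_rate > 0:
        lens = np.array(list(genome_mod.lengths().values()), dtype=float)
        names = list(genome_mod.sequences)
        n_bg = int(rng.poisson(background_rate * lens.sum() / 1000.0))
        for _ in range(n_bg):
            chrom = names[rng.choice(len(names), p=lens / lens.sum())]
            seq = genome_mod.sequences[chrom]
            flen = int(
                _truncated_normal(1, frag_mean, frag_sd, read_len, frag_max, rng)[0]
            )
            flen = min(flen, len(seq))
            start = int(rng.integers(0, len(seq) - flen + 1))
            tseq = seq[start : start + flen]
            if rng.random() < 0.5:
                tseq = revcomp(tseq)
            emit(
                tseq, 0, flen,
                {"kind": "background", "chrom": chrom, "junction_orig": -1,
                 "insertion_point": -1, "orientation": ".",
                 "m1_covers": False, "m2_covers": False, "spanning": False,
                 "junction_offset": -1},
            )
    truth = pd.DataFrame(
        rows,
        columns=["id", "start", "frag_len", "kind", "chrom", "junction_orig",
                 "insertion_point", "orientation", "m1_covers", "m2_covers",
                 "spanning", "junction_offset"],
    )
    return pairs, truth


def write_fastq_pair(pairs: list[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual * len(p.seq1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual * len(p.seq2)}\n")


def read_fastq_pairs(path1, path2, sample: str = "") -> list[ReadPair]:
    def records(path):
        with open(path) as fh:
            while True:
                h = fh.readline()
                if not h:
                    return
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                yield h[1:].strip().rsplit("/", 1)[0], seq

    out = []
    for (id1, s1), (id2, s2) in zip(records(path1), records(path2)):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1} vs {id2}")
        out.append(ReadPair(id=id1, seq1=s1, seq2=s2, sample=sample))
    return out


# --- enrichment scenario ---------------------------------------------------


def simulate_enrichment_scenario(
    mask_len: int,
    n_peaks: int,
    peak_len: int,
    n_integrations: int,
    fold: float,
    seed: int,
    chrom: str = "chr1",
) -> tuple[dict[str, list[Interval]], dict[str, np.ndarray], ScenarioTruth]:
    """Plant peaks and integrations with a controlled in-peak enrichment fold.

    Peaks are placed without overlap on a single mappable chromosome of
    ``mask_len`` bp.  Each integration falls in the merged peak territory
    (fraction ``q`` of the mappable genome) with probability
    ``fold*q / (fold*q + (1-q))`` — a two-component mixture whose density
    inside peaks is ``fold`` times the outside density.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    if n_peaks * peak_len >= mask_len:
        raise ValueError("peaks do not fit in the mappable genome")
    rng = np.random.default_rng(seed)
    # non-overlapping placement via the gap trick: choose starts in the
    # shrunken coordinate space, then re-expand
    space = mask_len - n_peaks * peak_len
    starts = np.sort(rng.choice(space, size=n_peaks, replace=False))
    starts = starts + np.arange(n_peaks) * peak_len
    peaks = [(int(s), int(s + peak_len)) for s in starts]
    q = total_length(peaks) / mask_len
    p_in = fold * q / (fold * q + (1 - q)) if (fold * q + (1 - q)) > 0 else 1.0
    inside = rng.random(n_integrations) < p_in
    positions = np.empty(n_integrations, dtype=np.int64)
    # uniform inside merged peak territory
    cum = np.concatenate([[0], np.cumsum([e - s for s, e in peaks])])
    gaps = subtract_intervals([(0, mask_len)], peaks)
    gcum = np.concatenate([[0], np.cumsum([e - s for s, e in gaps])])
    for i, is_in in enumerate(inside):
        if is_in:
            u = rng.integers(0, cum[-1])
            k = int(np.searchsorted(cum, u, side="right") - 1)
            positions[i] = peaks[k][0] + (u - cum[k])
        else:
            u = rng.integers(0, gcum[-1])
            k = int(np.searchsorted(gcum, u, side="right") - 1)
            positions[i] = gaps[k][0] + (u - gcum[k])
    positions.sort()
    truth = ScenarioTruth(
        seed=seed,
        params={"mask_len": mask_len, "n_peaks": n_peaks, "peak_len": peak_len,
                "n_integrations": n_integrations, "q": q, "p_in": p_in},
        peaks=[{"chrom": chrom, "start": s, "end": e} for s, e in peaks],
        enrichment_fold=fold,
    )
    truth.params["n_inside"] = int(inside.sum())
    return {chrom: peaks}, {chrom: positions}, truth


def write_bed(intervals_by_chrom: dict[str, list[Interval]], path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals_by_chrom:
            for s, e in intervals_by_chrom[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_positions_bed(positions_by_chrom: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in positions_by_chrom.items():
            for p in pos:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# --- constructed signature pairs ------------------------------------------

#: the classifiable (element, direction) combinations; see docs/methods.md
SIGNATURE_CELLS = [
    ("U3", "MOUSE_TO_VIRUS"),
    ("U3", "VIRUS_TO_MOUSE"),
    ("U5", "VIRUS_TO_MOUSE"),
    ("U5", "MOUSE_TO_VIRUS"),
    ("SD", "VIRUS_TO_MOUSE"),
    ("SD", "MOUSE_TO_VIRUS"),
]
COVERAGE_CLASSES = ("FUSION_M1", "FUSION_M2", "SPANNING")


def make_signature_pair(
    element: str,
    coverage: str,
    direction: str,
    genome_mod: Genome,
    provirus: Provirus,
    row,
    read_len: int = 101,
    up: int = 400,
    into: int = 400,
) -> ReadPair:
    """Construct a read pair guaranteed to belong to one taxonomy cell.

    ``row`` is a junction-table row for a sense-orientation planted provirus.
    The transcript for the requested (element, direction) is assembled in the
    provirus frame and a fragment is placed so that the requested mate (or
    neither, for SPANNING) covers the junction base.
    """
    gseq = genome_mod.sequences[row["chrom"]]
    Lm, Rm = int(row["left_jx_mod"]), int(row["right_jx_mod"])
    pv = provirus.sequence
    el = provirus.elements
    leader = pv[el["5R"][0] : el["SD"][1]]
    if (element, direction) == ("U3", "MOUSE_TO_VIRUS"):
        tseq, j = gseq[Lm - up : Lm + into], up
    elif (element, direction) == ("U3", "VIRUS_TO_MOUSE"):
        # antisense transcription exiting the 5' junction into upstream host
        tseq, j = revcomp(gseq[Lm - up : Lm + into]), into
    elif (element, direction) == ("U5", "VIRUS_TO_MOUSE"):
        vlen = el["5U5"][1] - el["5R"][0]
        tseq, j = gseq[Rm - vlen - 250 : Rm + up], vlen + 250
    elif (element, direction) == ("U5", "MOUSE_TO_VIRUS"):
        # antisense read-in from downstream host into the 3' LTR
        tseq, j = revcomp(gseq[Rm - into : Rm + up]), up
    elif (element, direction) == ("SD", "VIRUS_TO_MOUSE"):
        tseq, j = leader + gseq[Rm : Rm + up], len(leader)
    elif (element, direction) == ("SD", "MOUSE_TO_VIRUS"):
        # host donor spliced onto the env splice acceptor
        tseq = gseq[Lm - up : Lm] + pv[el["env_SA"][0] : el["env_SA"][0] + into]
        j = up
    else:
        raise ValueError(f"invalid cell ({element}, {direction})")
    flen = 300
    if coverage == "FUSION_M1":
        start = j - 50
    elif coverage == "FUSION_M2":
        # mate1 fully viral, mate2 covering the junction; the viral extent can
        # be as short as the 186-bp R..SD leader, so adapt the insert size
        start = max(0, j - 250)
        flen = (j - start) + 50
    elif coverage == "SPANNING":
        # with a short viral extent (the R..SD leader) the fully-viral mate
        # must abut the junction to remain attributable to the SD anchor
        start = j - 150 if j >= 250 else j - 101
    else:
        raise ValueError(f"unknown coverage class {coverage!r}")
    if start < 0 or start + flen > len(tseq):
        raise ValueError("transcript too short for requested placement")
    frag = tseq[start : start + flen]
    rid = f"cell:{element}:{coverage}:{direction}"
    return ReadPair(id=rid, seq1=frag[:read_len], seq2=revcomp(frag[-read_len:]))


# --- full mapping cohort ---------------------------------------------------


@dataclass
class MappingCohort:
    genome: Genome
    provirus: Provirus
    sample_sites: dict[str, list[PlantedProvirus]]
    sample_pairs: dict[str, list[ReadPair]]
    sample_truth: dict[str, pd.DataFrame]
    shared_sites: list[PlantedProvirus]
    truth: ScenarioTruth


def simulate_mapping_cohort(
    n_samples: int = 3,
    n_unique: int = 20,
    n_shared: int = 3,
    genome_len: int = 2_000_000,
    n_chrom: int = 2,
    gc: float = 0.42,
    decoy_spec: tuple = ((0.95, 2), (0.9, 2), (0.85, 2)),
    expression_mean: float = 50.0,
    background_rate: float = 0.05,
    tsd_len: int = 4,
    seed: int = 0,
) -> MappingCohort:
    """A multi-tumor scenario for end-to-end integration mapping.

    Each sample receives ``n_unique`` private proviruses plus ``n_shared``
    proviruses at positions common to every sample — the stand-in for
    transcribed endogenous retrovirus-like loci that the cross-sample filter
    must remove.  Sites are spread over the genome with >= 5 kb spacing so
    private sites never collide across samples.
    """
    rng = np.random.default_rng(seed)
    lengths = [genome_len // n_chrom] * n_chrom
    provirus = make_provirus(seed=int(rng.integers(2**31)))
    genome, truth = make_genome(
        n_chrom, lengths, gc, list(decoy_spec), provirus.ltr_seq,
        seed=int(rng.integers(2**31)),
    )
    # lay out candidate insertion slots away from decoys and each other
    n_sites = n_shared + n_samples * n_unique
    spacing = 5_000
    margin = 2_000
    slots: list[tuple[str, int]] = []
    occupied = {c: [(d["start"] - spacing, d["end"] + spacing)
                    for d in truth.decoys if d["chrom"] == c]
                for c in genome.sequences}
    chroms = list(genome.sequences)
    attempts = 0
    while len(slots) < n_sites and attempts < 100_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(margin, len(genome.sequences[chrom]) - margin))
        if any(s <= p < e for s, e in occupied[chrom]):
            continue
        slots.append((chrom, p))
        occupied[chrom].append((p - spacing, p + spacing))
    if len(slots) < n_sites:
        raise RuntimeError("could not lay out insertion sites; genome too small")
    expr = {k: expression_mean for k in JUNCTION_KINDS}
    mk = lambda cp: PlantedProvirus(
        cp[0], cp[1],
        orientation="S" if rng.random() < 0.5 else "AS",
        tsd_len=tsd_len, expression=dict(expr),
    )
    shared = [mk(slots[i]) for i in range(n_shared)]
    sample_sites: dict[str, list[PlantedProvirus]] = {}
    cursor = n_shared
    for s in range(n_samples):
        name = f"tumor{s + 1}"
        private = [mk(slots[i]) for i in range(cursor, cursor + n_unique)]
        cursor += n_unique
        sample_sites[name] = shared + private
    sample_pairs: dict[str, list[ReadPair]] = {}
    sample_truth: dict[str, pd.DataFrame] = {}
    for name, sites in sample_sites.items():
        gmod, table = plant_proviruses(genome, provirus, sites)
        pairs, ftruth = simulate_library(
            gmod, table, provirus, sites,
            background_rate=background_rate,
            seed=int(rng.integers(2**31)), sample=name,
        )
        sample_pairs[name] = pairs
        sample_truth[name] = ftruth
    truth.proviruses = {
        name: [
            {"chrom": s.chrom, "insertion_point": s.insertion_point,
             "orientation": s.orientation, "tsd_len": s.tsd_len,
             "shared": s in shared}
            for s in sites
        ]
        for name, sites in sample_sites.items()
    }
    truth.params.update({"n_samples": n_samples, "n_unique": n_unique,
                         "n_shared": n_shared, "expression_mean": expression_mean})
    return MappingCohort(genome, provirus, sample_sites, sample_pairs,
                         sample_truth, shared, truth)


# --- deregulation pattern scenarios ---------------------------------------


def make_deregulation_scenario(pattern: str, seed: int = 0):
    """Construct one coverage-track scenario per activation pattern.

    Returns a dict with tumor/control tracks, gene models, chimeric-pair
    signatures at the locus, the provirus position, the names of genes whose
    activation is chimeric, and the designed label set.  Patterns:
    ``bidirectional``, ``tandem``, ``sense_antisense``, ``distal_target``,
    ``combination``.
    """
    from .annotation import GeneModel
    from .mapper import PESignatureClass
    from .patterns import CoverageTrack

    chrom, length, bin_size = "chr1", 600_000, 1_000
    nbin = length // bin_size
    pos = 300_000

    def blank():
        return np.zeros(nbin), np.zeros(nbin)

    t_plus, t_minus = blank()
    c_plus, c_minus = blank()

    def paint(arrs, start, end, level):
        arrs[start // bin_size : end // bin_size] += level

    def strand_arrays(which, strand):
        if which == "tumor":
            return t_plus if strand == "+" else t_minus
        return c_plus if strand == "+" else c_minus

    def baseline_gene(g, level=2.0):
        for which in ("tumor", "control"):
            paint(strand_arrays(which, g.strand), g.tx_start, g.tx_end, level)

    def activate_gene(g, level=20.0, upto: int | None = None):
        end = g.tx_end if upto is None else upto
        paint(strand_arrays("tumor", g.strand), g.tx_start, end, level)

    genes: list = []
    signatures: set = set()
    chimeric_genes: tuple[str, ...] = ()
    u5 = PESignatureClass("U5", "FUSION_M1", "VIRUS_TO_MOUSE")
    sd = PESignatureClass("SD", "FUSION_M1", "VIRUS_TO_MOUSE")
    u3_span = PESignatureClass("U3", "SPANNING", "MOUSE_TO_VIRUS")

    if pattern == "bidirectional":
        g = GeneModel("Klf7", chrom, "+", 230_000, 280_000)
        genes = [g]
        baseline_gene(g)
        activate_gene(g)
        paint(t_minus, 320_000, 485_000, 3.0)  # 165-kb unannotated activation
        signatures = {u5, u3_span}
        expected = {"BIDIRECTIONAL", "LOCAL_PROMOTER_INSERTION"}
    elif pattern == "tandem":
        ccr9 = GeneModel("Ccr9", chrom, "-", 280_000, 295_000)
        lztfl1 = GeneModel("Lztfl1", chrom, "-", 230_000, 250_000)
        slc = GeneModel("Slc6a20a", chrom, "-", 200_000, 225_000)
        genes = [ccr9, lztfl1, slc]
        for g in genes:
            baseline_gene(g)
        activate_gene(lztfl1)
        activate_gene(slc)
        signatures = {u3_span}
        expected = {"TANDEM", "DISTAL_TARGET"}
    elif pattern == "sense_antisense":
        syn2 = GeneModel("Syn2", chrom, "+", 311_200, 360_000)
        ak = GeneModel("AK038749", chrom, "-", 303_000, 311_000)
        genes = [syn2, ak]
        for g in genes:
            baseline_gene(g, level=0.0)
        activate_gene(syn2)
        activate_gene(ak)
        signatures = {u3_span}
        expected = {"SENSE_ANTISENSE"}
    elif pattern == "distal_target":
        col4a5 = GeneModel("Col4a5", chrom, "+", 250_000, 350_000)
        irs4 = GeneModel("Irs4", chrom, "+", 420_000, 450_000)
        genes = [col4a5, irs4]
        for g in genes:
            baseline_gene(g)
        activate_gene(irs4)
        signatures = {u3_span}
        expected = {"DISTAL_TARGET"}
    elif pattern == "combination":
        celf2 = GeneModel("Celf2", chrom, "+", 100_000, 200_000)
        genes = [celf2]
        baseline_gene(celf2)
        activate_gene(celf2, upto=195_000)
        paint(t_plus, 60_000, 80_000, 3.0)  # non-chimeric far-upstream variant
        signatures = {u5, sd}
        chimeric_genes = ("Celf2",)
        expected = {"COMBINATION", "LOCAL_PROMOTER_INSERTION"}
    else:
        raise ValueError(f"unknown pattern scenario {pattern!r}")

    if pattern == "combination":
        pos = 195_000
    tumor = CoverageTrack("tumor", chrom, 0, bin_size, t_plus, t_minus)
    controls = [
        CoverageTrack("ctrl1", chrom, 0, bin_size, c_plus.copy(), c_minus.copy()),
        CoverageTrack("ctrl2", chrom, 0, bin_size, c_plus.copy(), c_minus.copy()),
    ]
    return {
        "tumor": tumor,
        "controls": controls,
        "genes": genes,
        "signatures": signatures,
        "provirus_position": pos,
        "chimeric_genes": chimeric_genes,
        "expected_labels": expected,
    }
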