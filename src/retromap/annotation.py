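"""Gene assignment, prior-dataset distances, and gene-set overlap testing."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .intervals import Interval


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class GeneModel:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValueError(f"{self.name}: tx_end must exceed tx_start")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -")
        self.exons = sorted(self.exons)
        prev = self.tx_start
        for s, e in self.exons:
            if s < prev or e > self.tx_end or e <= s:
                raise ValueError(f"{self.name}: exons must be sorted, disjoint, in bounds")
            prev = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class GeneAssignment:
    gene: str
    distance: float  # 0 if inside the gene body; inf when no gene on chrom
    location: str  # exon | intron | upstream | downstream | none
    relative_orientation: str  # sense | antisense | "."
    tie: bool = False
    also: list[str] = field(default_factory=list)  # other zero-distance genes


def read_refflat(path) -> list[GeneModel]:
    """refFlat-style TSV: geneName chrom strand txStart txEnd exonStarts exonEnds."""
    genes = []
    df = pd.read_csv(
        path, sep="\t",
        names=["name", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"],
        comment="#",
    )
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",") if x]
        genes.append(
            GeneModel(row.name, row.chrom, row.strand, int(row.tx_start),
                      int(row.tx_end), list(zip(starts, ends)))
        )
    return genes


def write_refflat(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            ss = ",".join(str(s) for s, _ in g.exons) + ","
            ee = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{ss}\t{ee}\n")


def nearest_gene(
    position: int,
    chrom: str,
    provirus_orientation: str,
    genes: list[GeneModel],
) -> GeneAssignment:
    """Assign the nearest gene to an integration.

    Distance is 0 inside the gene body, else the gap to the nearer body
    boundary.  Among genes containing the position, the primary is the
    longest transcript (others are reported in ``also``); equal nonzero
    distances are broken by smaller TSS distance, then name, with the tie
    flag set.
    """
    cands = [g for g in genes if g.chrom == chrom]
    if not cands:
        return GeneAssignment("", float("inf"), "none", ".", False)
    dists = []
    for g in cands:
        if g.tx_start <= position < g.tx_end:
            d = 0
        else:
            d = min(abs(position - g.tx_start), abs(position - (g.tx_end - 1)))
        dists.append(d)
    dmin = min(dists)
    nearest = [g for g, d in zip(cands, dists) if d == dmin]
    if dmin == 0:
        nearest.sort(key=lambda g: (-g.length, g.name))
        primary = nearest[0]
        also = [g.name for g in nearest[1:]]
        tie = len(nearest) > 1
    else:
        nearest.sort(key=lambda g: (abs(position - g.tss), g.name))
        primary = nearest[0]
        also = []
        tie = len(nearest) > 1
    g = primary
    if dmin == 0:
        inside_exon = any(s <= position < e for s, e in g.exons)
        location = "exon" if inside_exon else "intron"
    else:
        before = position < g.tx_start
        if g.strand == "+":
            location = "upstream" if before else "downstream"
        else:
            location = "downstream" if before else "upstream"
    rel = "sense" if (provirus_orientation == "S") == (g.strand == "+") else "antisense"
    return GeneAssignment(g.name, float(dmin), location, rel, tie, also)


def distance_to_prior(
    calls: pd.DataFrame,
    prior_sites: dict[str, np.ndarray],
    flag_within: int = 10_000,
) -> pd.DataFrame:
    """Per-call absolute distance to the nearest prior integration site.

    ``calls`` needs ``chrom`` and ``position`` columns; adds ``prior_distance``
    and a ``near_prior`` flag at the 10-kb threshold.
    """
    out = calls.copy()
    dists = np.full(len(out), np.inf)
    for chrom, sub in out.groupby("chrom"):
        sites = np.sort(np.asarray(prior_sites.get(chrom, []), dtype=np.int64))
        if sites.size == 0:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(sites, pos)
        left = np.clip(idx - 1, 0, sites.size - 1)
        right = np.clip(idx, 0, sites.size - 1)
        d = np.minimum(np.abs(pos - sites[left]), np.abs(pos - sites[right]))
        dists[sub.index] = d
    out["prior_distance"] = dists
    out["near_prior"] = dists <= flag_within
    return out


def gene_set_overlap_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), computed in log space.

    ``k`` genes shared between a set of ``n`` and a set of ``K`` drawn from a
    universe of ``N`` annotations.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    j = np.arange(k, min(n, K) + 1)
    log_pmf = (
        _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    )
    return float(min(1.0, math.exp(logsumexp(log_pmf))))
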