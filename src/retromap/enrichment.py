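"""Integration-site colocalization with ChIP-seq features.

The central statistic: extend each peak by a pad (default 1,250 bp), merge,
and count integrations whose 1-bp coordinate falls in the merged territory.
Significance comes from a matched random null — each iteration replaces the
real peaks with the same number of intervals of the dataset's median peak
length, placed uniformly and without overlap in the mappable genome — and
the empirical p-value is the add-one rank estimator (r+1)/(n_iter+1), whose
floor 1/(n_iter+1) is below 0.001 at the standard 1,000 iterations.

Also here: the TSS distance partition (immediate < 3 kb, intermediate
3-10 kb, distal > 10 kb), genome-fraction curves over pad grids, enhancer
midpoint distance profiles, and the 2,500-bp-bin reduced integration set
that removes highly tagged regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import (
    Interval,
    merge_intervals,
    pad_intervals,
    points_in_intervals,
    total_length,
)

Positions = "dict[str, np.ndarray]"
IntervalMap = "dict[str, list[Interval]]"


@dataclass
class ChIPFeatureSet:
    marker: str
    tissue: str
    peaks: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.peaks.items():
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"invalid peak ({s}, {e}) on {chrom}")
            self.peaks[chrom] = sorted(ivs)

    def lengths(self) -> np.ndarray:
        return np.array([e - s for ivs in self.peaks.values() for s, e in ivs])

    def total_bp(self) -> int:
        return int(self.lengths().sum())

    def median_length(self) -> int:
        return int(round(float(np.median(self.lengths()))))

    def n_peaks(self) -> int:
        return sum(len(v) for v in self.peaks.values())

    @classmethod
    def from_bed(cls, path, marker: str = "", tissue: str = "") -> "ChIPFeatureSet":
        peaks: dict[str, list[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                peaks.setdefault(f[0], []).append((int(f[1]), int(f[2])))
        return cls(marker, tissue, peaks)


@dataclass
class TSSPartition:
    counts: dict[str, int]
    medians: dict[str, float]
    categories: dict[str, np.ndarray]  # chrom -> per-integration label array
    n_dropped: int = 0

    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()} if total else {}


def _nearest_site_distance(pos: np.ndarray, sites: np.ndarray) -> np.ndarray:
    sites = np.sort(sites)
    idx = np.searchsorted(sites, pos)
    left = np.clip(idx - 1, 0, sites.size - 1)
    right = np.clip(idx, 0, sites.size - 1)
    return np.minimum(np.abs(pos - sites[left]), np.abs(pos - sites[right]))


def categorize_by_tss(
    integrations: dict[str, np.ndarray],
    tss: dict[str, np.ndarray],
    bounds: tuple[int, int] = (3_000, 10_000),
) -> TSSPartition:
    """Partition integrations by distance to the nearest TSS.

    immediate: d < bounds[0]; intermediate: bounds[0] <= d <= bounds[1];
    distal: d > bounds[1].  Integrations on chromosomes without any TSS are
    dropped with a warning.
    """
    lo, hi = bounds
    cats: dict[str, np.ndarray] = {}
    dists_all: dict[str, list] = {"immediate": [], "intermediate": [], "distal": []}
    n_dropped = 0
    for chrom, pos in integrations.items():
        pos = np.asarray(pos, dtype=np.int64)
        sites = np.asarray(tss.get(chrom, []), dtype=np.int64)
        if sites.size == 0:
            if pos.size:
                warnings.warn(f"no TSS on {chrom}; {pos.size} integrations dropped")
                n_dropped += pos.size
            cats[chrom] = np.array([], dtype=object)
            continue
        d = _nearest_site_distance(pos, sites)
        lab = np.where(d < lo, "immediate", np.where(d <= hi, "intermediate", "distal"))
        cats[chrom] = lab.astype(object)
        for name in dists_all:
            dists_all[name].extend(d[lab == name].tolist())
    counts = {k: len(v) for k, v in dists_all.items()}
    medians = {k: (float(np.median(v)) if v else float("nan")) for k, v in dists_all.items()}
    return TSSPartition(counts, medians, cats, n_dropped)


def colocalize(
    integrations: dict[str, np.ndarray],
    features: ChIPFeatureSet,
    pad: int = 1_250,
) -> tuple[int, float, dict[str, np.ndarray]]:
    """Count integrations inside the pad-extended, merged peak territory.

    Returns (count, fraction, per-chromosome boolean flags).
    """
    count = 0
    total = 0
    flags: dict[str, np.ndarray] = {}
    for chrom, pos in integrations.items():
        pos = np.asarray(pos, dtype=np.int64)
        total += pos.size
        territory = pad_intervals(features.peaks.get(chrom, []), pad)
        inside = points_in_intervals(pos, territory)
        flags[chrom] = inside
        count += int(inside.sum())
    fraction = count / total if total else 0.0
    return count, fraction, flags


def sample_matched_random_features(
    features: ChIPFeatureSet,
    mask: dict[str, list[Interval]],
    rng: np.random.Generator | int,
    max_rounds: int = 1_000,
) -> ChIPFeatureSet:
    """Random intervals matched to the feature set's size and median length.

    Emits m = round(total feature bp / median peak length) intervals of the
    median length, uniform over the mappable mask, mutually non-overlapping
    ("without replacement").  Deterministic given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    L = features.median_length()
    m = int(round(features.total_bp() / L))
    slots = []  # (chrom, slot_start, n_slots) per mask interval able to host one interval
    mask_bp = 0
    for chrom, ivs in mask.items():
        for s, e in merge_intervals(ivs):
            mask_bp += e - s
            if e - s >= L:
                slots.append((chrom, s, e - s - L + 1))
    space = int(sum(n for _, _, n in slots))
    if mask_bp < m * L or space < m:
        raise ValueError("mappable genome smaller than total feature length")
    cum = np.concatenate([[0], np.cumsum([n for _, _, n in slots])])
    slot_chrom = [c for c, _, _ in slots]
    slot_start = np.array([s for _, s, _ in slots], dtype=np.int64)

    draws = np.sort(rng.integers(0, space, size=m))
    for _round in range(max_rounds):
        draws.sort()
        k = np.searchsorted(cum, draws, side="right") - 1
        # conflict: neighbours in the same mask slot region closer than L in
        # genome space (slot units are 1 bp apart within a slot)
        bad = np.zeros(m, dtype=bool)
        for i in range(1, m):
            if k[i] != k[i - 1]:
                continue  # different mask intervals cannot collide
            p1 = slot_start[k[i]] + (draws[i] - cum[k[i]])
            p0 = slot_start[k[i - 1]] + (draws[i - 1] - cum[k[i - 1]])
            if p1 - p0 < L:
                bad[i] = True
        if not bad.any():
            peaks: dict[str, list[Interval]] = {}
            for i in range(m):
                chrom = slot_chrom[k[i]]
                p = int(slot_start[k[i]] + (draws[i] - cum[k[i]]))
                peaks.setdefault(chrom, []).append((p, p + L))
            return ChIPFeatureSet(f"random[{features.marker}]", features.tissue, peaks)
        n_bad = int(bad.sum())
        draws = np.concatenate([draws[~bad], rng.integers(0, space, size=n_bad)])
    raise RuntimeError(
        "could not place non-overlapping matched random intervals; "
        "feature set too dense for the mask"
    )


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray
    fold: float
    p_value: float
    pad: int
    n_iter: int
    seed: int
    saturated: bool = False

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1)) if len(self.null_counts) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_value": self.p_value,
            "pad": self.pad,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def enrichment_test(
    integrations: dict[str, np.ndarray],
    features: ChIPFeatureSet,
    mask: dict[str, list[Interval]],
    pad: int = 1_250,
    n_iter: int = 1_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed colocalization vs the matched random-feature null.

    fold = observed / mean(null); empirical p = (#{null >= observed} + 1) /
    (n_iter + 1).  A zero null mean yields an infinite fold with a flag.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    observed, _, _ = colocalize(integrations, features, pad)
    null_counts = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        random_set = sample_matched_random_features(features, mask, rng)
        null_counts[i], _, _ = colocalize(integrations, random_set, pad)
    null_mean = float(np.mean(null_counts))
    saturated = null_mean == 0
    fold = float("inf") if saturated else observed / null_mean
    p = (int(np.sum(null_counts >= observed)) + 1) / (n_iter + 1)
    return EnrichmentResult(observed, null_counts, fold, p, pad, n_iter, seed, saturated)


def genome_fraction(
    features: ChIPFeatureSet,
    pads: list[int],
    mask: dict[str, list[Interval]],
) -> dict[int, float]:
    """Fraction of the mappable genome covered by pad-extended peak territory."""
    from .intervals import intersect_intervals

    mask_bp = sum(total_length(merge_intervals(ivs)) for ivs in mask.values())
    out = {}
    for pad in pads:
        if pad < 0:
            raise ValueError("pads must be >= 0")
        covered = 0
        for chrom, ivs in mask.items():
            territory = pad_intervals(features.peaks.get(chrom, []), pad)
            covered += total_length(intersect_intervals(territory, merge_intervals(ivs)))
        out[pad] = covered / mask_bp if mask_bp else 0.0
    return out


def midpoint_distance_profile(
    integrations: dict[str, np.ndarray],
    features: ChIPFeatureSet,
    bin_size: int = 200,
    max_range: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of distances to the nearest peak midpoint.

    Returns (bin_edges, counts, n_beyond_range).
    """
    if features.n_peaks() == 0:
        raise ValueError("feature set is empty")
    dists = []
    for chrom, pos in integrations.items():
        pos = np.asarray(pos, dtype=np.int64)
        peaks = features.peaks.get(chrom, [])
        if not peaks or pos.size == 0:
            if pos.size:
                dists.append(np.full(pos.size, np.inf))
            continue
        mids = np.array([(s + e) // 2 for s, e in peaks], dtype=np.int64)
        dists.append(_nearest_site_distance(pos, np.sort(mids)).astype(float))
    d = np.concatenate(dists) if dists else np.array([])
    edges = np.arange(0, max_range + bin_size, bin_size)
    in_range = d <= max_range
    counts, _ = np.histogram(d[in_range], bins=edges)
    return edges, counts, int((~in_range).sum())


@dataclass
class ReducedIntegrationSet:
    coordinates: dict[str, np.ndarray]
    multiplicity: dict[str, np.ndarray]  # 1 or 2 sites behind each coordinate
    n_singletons: int = 0
    n_pairs: int = 0
    n_excluded_clusters: int = 0

    def n_coordinates(self) -> int:
        return sum(len(v) for v in self.coordinates.values())

    @property
    def singleton_fraction(self) -> float:
        n = self.n_coordinates()
        return self.n_singletons / n if n else float("nan")

    def positions(self) -> dict[str, np.ndarray]:
        return self.coordinates


def reduce_integration_set(
    integrations: dict[str, np.ndarray], bin_size: int = 2_500
) -> ReducedIntegrationSet:
    """De-cluster integrations on a fixed genome grid of ``bin_size`` bins.

    Bins (anchored at coordinate 0) with one site emit that site; bins with
    two sites emit the integer midpoint; bins with more than two sites are
    excluded entirely.
    """
    coords: dict[str, np.ndarray] = {}
    mult: dict[str, np.ndarray] = {}
    n_single = n_pair = n_excl = 0
    for chrom, pos in integrations.items():
        pos = np.sort(np.asarray(pos, dtype=np.int64))
        bins = pos // bin_size
        out_pos = []
        out_mult = []
        for b in np.unique(bins):
            members = pos[bins == b]
            if members.size == 1:
                out_pos.append(int(members[0]))
                out_mult.append(1)
                n_single += 1
            elif members.size == 2:
                out_pos.append(int((members[0] + members[1]) // 2))
                out_mult.append(2)
                n_pair += 1
            else:
                n_excl += 1
        coords[chrom] = np.array(out_pos, dtype=np.int64)
        mult[chrom] = np.array(out_mult, dtype=np.int64)
    return ReducedIntegrationSet(coords, mult, n_single, n_pair, n_excl)
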