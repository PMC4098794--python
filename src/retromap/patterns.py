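"""Rule-based classification of provirus-induced transcription patterns.

A provirus can deregulate its locus in several distinguishable ways:
local activation by retroviral promoter insertion at the 3' LTR, enhancer
activation of genes on both genomic sides (bidirectional), tandem activation
of adjacent same-strand distal genes, sense/antisense activation of
opposite-strand units sharing a promoter region, activation of a distal
gene while the direct integration target stays silent, and combinations of
promoter insertion, chimeric splicing and enhancer activation by a single
provirus.  The patterns are qualitative in origin; the thresholds used to
operationalize them (activation fold, null fold, sense/antisense proximity)
are package decisions, configurable and surfaced in reports.

Coverage is compared between one tumor and the mean of control tumors as
strand-specific binned tracks scaled to a common library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel

PATTERN_LABELS = (
    "LOCAL_PROMOTER_INSERTION",
    "BIDIRECTIONAL",
    "TANDEM",
    "SENSE_ANTISENSE",
    "DISTAL_TARGET",
    "COMBINATION",
)


@dataclass
class Thresholds:
    f_act: float = 5.0  # fold at or above which a window/gene counts as activated
    f_null: float = 2.0  # fold below which a gene counts as not activated
    eps: float = 0.5  # pseudocount in scaled coverage units
    sa_proximity: int = 10_000  # max TSS separation for sense/antisense units


@dataclass
class CoverageTrack:
    """Strand-specific binned coverage for one sample over one chromosome."""

    sample: str
    chrom: str
    start: int
    bin_size: int
    plus: np.ndarray
    minus: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape:
            raise ValueError("plus/minus arrays must have equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise ValueError("coverage must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.bin_size * len(self.plus)

    def scaled(self, strand: str) -> np.ndarray:
        arr = self.plus if strand == "+" else self.minus
        return arr * self.scale_factor

    def window_sum(self, start: int, end: int, strand: str) -> float:
        """Scaled coverage summed over [start, end) (clipped to the track)."""
        lo = max(0, (start - self.start) // self.bin_size)
        hi = max(0, min(len(self.plus), -(-(end - self.start) // self.bin_size)))
        return float(self.scaled(strand)[lo:hi].sum())


def library_scale_factor(total_fragments: int) -> float:
    """Per-million library scaling, the stand-in for external scale factors."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    return 1e6 / total_fragments


def _check_aligned(tumor: CoverageTrack, controls: list[CoverageTrack]) -> None:
    if not controls:
        raise ValueError("at least one control track required")
    for c in controls:
        if (c.chrom, c.start, c.bin_size, len(c.plus)) != (
            tumor.chrom, tumor.start, tumor.bin_size, len(tumor.plus)
        ):
            raise ValueError("control track bins are not aligned with the tumor track")


def control_mean(controls: list[CoverageTrack]) -> CoverageTrack:
    plus = np.mean([c.scaled("+") for c in controls], axis=0)
    minus = np.mean([c.scaled("-") for c in controls], axis=0)
    c0 = controls[0]
    return CoverageTrack("control_mean", c0.chrom, c0.start, c0.bin_size,
                         plus, minus, scale_factor=1.0)


def flank_fold_change(
    tumor: CoverageTrack,
    controls: list[CoverageTrack],
    provirus_position: int,
    window: int = 10_000,
    span: int = 200_000,
    eps: float = 0.5,
) -> pd.DataFrame:
    """Tumor/control fold change in windows tiling ±span around the provirus.

    fold = (tumor + eps) / (control_mean + eps) per window per strand, on
    library-scaled coverage.
    """
    _check_aligned(tumor, controls)
    ctrl = control_mean(controls)
    rows = []
    for wstart in range(provirus_position - span, provirus_position + span, window):
        wend = wstart + window
        for strand in "+-":
            t = tumor.window_sum(wstart, wend, strand)
            c = ctrl.window_sum(wstart, wend, strand)
            rows.append(
                {
                    "window_start": wstart,
                    "window_end": wend,
                    "strand": strand,
                    "side": "left" if wend <= provirus_position else (
                        "right" if wstart >= provirus_position else "center"),
                    "tumor": t,
                    "control": c,
                    "fold": (t + eps) / (c + eps),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class UnannotatedRegion:
    chrom: str
    start: int
    end: int
    strand: str
    tumor_cov: float
    control_cov: float
    chimeric: bool = False  # linked to chimeric (virus-fused) transcription?

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def detect_unannotated_transcription(
    tumor: CoverageTrack,
    controls: list[CoverageTrack],
    annotations: list[GeneModel],
    min_len: int = 1_000,
    min_cov: float = 1.0,
    max_control_cov: float = 0.2,
) -> list[UnannotatedRegion]:
    """Strand-resolved runs of tumor transcription outside annotated genes.

    A region is a maximal run of bins with tumor coverage >= min_cov,
    control mean <= max_control_cov, no overlap with any annotated gene
    body, and total length >= min_len.
    """
    if min_len <= 0 or min_cov <= 0:
        raise ValueError("thresholds must be > 0")
    _check_aligned(tumor, controls)
    ctrl = control_mean(controls)
    nbin = len(tumor.plus)
    gene_mask = np.zeros(nbin, dtype=bool)
    for g in annotations:
        if g.chrom != tumor.chrom:
            continue
        lo = max(0, (g.tx_start - tumor.start) // tumor.bin_size)
        hi = max(0, min(nbin, -(-(g.tx_end - tumor.start) // tumor.bin_size)))
        gene_mask[lo:hi] = True
    out = []
    for strand in "+-":
        t = tumor.scaled(strand)
        c = ctrl.scaled(strand)
        good = (t >= min_cov) & (c <= max_control_cov) & ~gene_mask
        i = 0
        while i < nbin:
            if not good[i]:
                i += 1
                continue
            j = i
            while j < nbin and good[j]:
                j += 1
            length = (j - i) * tumor.bin_size
            if length >= min_len:
                out.append(
                    UnannotatedRegion(
                        tumor.chrom,
                        tumor.start + i * tumor.bin_size,
                        tumor.start + j * tumor.bin_size,
                        strand,
                        float(t[i:j].mean()),
                        float(c[i:j].mean()),
                    )
                )
            i = j
    return out


@dataclass
class GeneEvidence:
    model: GeneModel
    fold: float
    chimeric: bool = False  # activation explained by virus-fused transcripts?

    @property
    def name(self) -> str:
        return self.model.name


@dataclass
class PatternCall:
    labels: set[str] = field(default_factory=set)
    evidence: dict[str, list] = field(default_factory=dict)

    def add(self, label: str, record) -> None:
        if label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {label!r}")
        self.labels.add(label)
        self.evidence.setdefault(label, []).append(record)


def _gene_side(g: GeneModel, position: int) -> str | None:
    if g.tx_end <= position:
        return "left"
    if g.tx_start > position:
        return "right"
    return None  # gene body spans the provirus


def _gene_distance(g: GeneModel, position: int) -> int:
    if g.tx_start <= position < g.tx_end:
        return 0
    return min(abs(position - g.tx_start), abs(position - (g.tx_end - 1)))


def classify_pattern(
    provirus_position: int,
    signatures: set,
    fold_table: pd.DataFrame,
    unannotated_regions: list[UnannotatedRegion],
    genes: list[GeneEvidence],
    thresholds: Thresholds | None = None,
) -> PatternCall:
    """Evaluate the pattern rules at one provirus locus; labels are a set.

    * LOCAL_PROMOTER_INSERTION — a U5 virus-to-mouse signature is present.
    * BIDIRECTIONAL — activated evidence (window, region or gene at fold >=
      f_act) on both genomic sides of the provirus.
    * TANDEM — >= 2 activated genes on one side sharing a strand.
    * SENSE_ANTISENSE — two activated units on opposite strands with TSSs
      within the proximity limit.
    * DISTAL_TARGET — the nearest gene is not activated (fold < f_null)
      while an activated gene lies beyond it.
    * COMBINATION — promoter insertion plus an SD chimeric-splice signature
      plus an activated non-chimeric unit at the locus.
    """
    th = thresholds or Thresholds()
    if fold_table is None or genes is None:
        raise ValueError("classify_pattern requires fold_table and gene evidence")
    call = PatternCall()

    def sig_match(element: str, direction: str | None = None) -> list:
        out = []
        for s in signatures:
            if s.element == element and (direction is None or s.direction == direction):
                out.append(s)
        return out

    # local promoter insertion
    for s in sig_match("U5", "VIRUS_TO_MOUSE"):
        call.add("LOCAL_PROMOTER_INSERTION", s.label())

    activated_genes = [g for g in genes if g.fold >= th.f_act]
    act_windows = fold_table[fold_table["fold"] >= th.f_act]

    # evidence of activation per genomic side
    sides: dict[str, list] = {"left": [], "right": []}
    for _, w in act_windows.iterrows():
        if w["side"] in sides:
            sides[w["side"]].append(("window", int(w["window_start"]), w["strand"]))
    for r in unannotated_regions:
        side = "left" if r.end <= provirus_position else (
            "right" if r.start > provirus_position else None)
        if side:
            sides[side].append(("region", r.start, r.strand))
    for g in activated_genes:
        side = _gene_side(g.model, provirus_position)
        if side:
            sides[side].append(("gene", g.name, g.model.strand))
    if sides["left"] and sides["right"]:
        call.add("BIDIRECTIONAL", {"left": sides["left"], "right": sides["right"]})

    # tandem: two activated genes, same side, same strand
    for side in ("left", "right"):
        per_strand: dict[str, list[GeneEvidence]] = {}
        for g in activated_genes:
            if _gene_side(g.model, provirus_position) == side:
                per_strand.setdefault(g.model.strand, []).append(g)
        for strand, gs in sorted(per_strand.items()):
            if len(gs) >= 2:
                call.add("TANDEM", {"side": side, "strand": strand,
                                    "genes": [g.name for g in gs]})

    # sense/antisense: activated units on opposite strands, TSSs close
    units = [(g.name, g.model.strand, g.model.tss) for g in activated_genes]
    units += [
        (f"region:{r.chrom}:{r.start}-{r.end}", r.strand, r.tss)
        for r in unannotated_regions
    ]
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            ni, si, ti = units[i]
            nj, sj, tj = units[j]
            if si != sj and abs(ti - tj) <= th.sa_proximity:
                call.add("SENSE_ANTISENSE", {"units": [ni, nj],
                                             "tss_gap": abs(ti - tj)})

    # distal target: nearest gene silent, activated gene beyond it
    if genes:
        nearest = min(genes, key=lambda g: (_gene_distance(g.model, provirus_position),
                                            g.name))
        nd = _gene_distance(nearest.model, provirus_position)
        nside = _gene_side(nearest.model, provirus_position)
        if nearest.fold < th.f_null:
            for g in activated_genes:
                gd = _gene_distance(g.model, provirus_position)
                gside = _gene_side(g.model, provirus_position)
                if gd > nd and (nside is None or gside == nside):
                    call.add("DISTAL_TARGET", {"silent": nearest.name,
                                               "activated": g.name,
                                               "distance": gd})

    # combination: promoter insertion + chimeric splice + activated
    # non-chimeric unit
    if "LOCAL_PROMOTER_INSERTION" in call.labels and sig_match("SD"):
        nonchim = [g.name for g in activated_genes if not g.chimeric]
        nonchim += [
            f"region:{r.chrom}:{r.start}-{r.end}"
            for r in unannotated_regions if not r.chimeric
        ]
        if nonchim:
            call.add("COMBINATION", {"non_chimeric_units": nonchim,
                                     "sd_signatures": [s.label() for s in sig_match("SD")]})
    return call


def gene_fold_changes(
    tumor: CoverageTrack,
    controls: list[CoverageTrack],
    genes: list[GeneModel],
    eps: float = 0.5,
    chimeric_genes: tuple[str, ...] = (),
) -> list[GeneEvidence]:
    """Per-gene tumor/control fold over the gene body on the gene strand."""
    _check_aligned(tumor, controls)
    ctrl = control_mean(controls)
    out = []
    for g in genes:
        t = tumor.window_sum(g.tx_start, g.tx_end, g.strand)
        c = ctrl.window_sum(g.tx_start, g.tx_end, g.strand)
        out.append(GeneEvidence(g, (t + eps) / (c + eps), g.name in chimeric_genes))
    return out


def evaluate_locus(
    tumor: CoverageTrack,
    controls: list[CoverageTrack],
    genes: list[GeneModel],
    signatures: set,
    provirus_position: int,
    thresholds: Thresholds | None = None,
    chimeric_genes: tuple[str, ...] = (),
    window: int = 10_000,
    span: int = 200_000,
    min_cov: float = 1.0,
    max_control_cov: float = 0.2,
    min_len: int = 1_000,
) -> PatternCall:
    """Full per-locus pipeline: folds, unannotated regions, then the rules."""
    th = thresholds or Thresholds()
    folds = flank_fold_change(tumor, controls, provirus_position,
                              window=window, span=span, eps=th.eps)
    regions = detect_unannotated_transcription(
        tumor, controls, genes, min_len=min_len,
        min_cov=min_cov, max_control_cov=max_control_cov,
    )
    gene_ev = gene_fold_changes(tumor, controls, genes, eps=th.eps,
                                chimeric_genes=chimeric_genes)
    return classify_pattern(provirus_position, signatures, folds, regions,
                            gene_ev, th)
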