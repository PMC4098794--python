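#!/usr/bin/env python
"""Annotate the called integrations: nearest gene, gene-relative location and
orientation, distance to a prior (splinkerette-style) integration list, and a
hypergeometric test of gene-set overlap between the two screens.

Gene models and the prior list are synthetic, generated alongside the cohort
genome so distances and overlaps have known structure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from retromap import simulate as sim
from retromap.annotation import (
    GeneModel,
    distance_to_prior,
    gene_set_overlap_test,
    nearest_gene,
    write_refflat,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def synthetic_genes(genome, rng, n_per_mb=60):
    genes = []
    i = 0
    for chrom, seq in genome.sequences.items():
        n = int(len(seq) / 1e6 * n_per_mb)
        for _ in range(n):
            start = int(rng.integers(0, len(seq) - 20_000))
            length = int(rng.integers(2_000, 20_000))
            n_ex = int(rng.integers(1, 6))
            bounds = np.sort(rng.choice(length, size=2 * n_ex, replace=False))
            exons = [(start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
                     for j in range(n_ex)]
            exons = [(s, e) for s, e in exons if e > s]
            genes.append(GeneModel(
                f"gene{i:04d}", chrom, "+" if rng.random() < 0.5 else "-",
                start, start + length, exons or [(start, start + length)],
            ))
            i += 1
    return genes


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    calls = pd.read_csv(RESULTS / "integration_calls.tsv", sep="\t")
    cohort = sim.simulate_mapping_cohort(
        n_samples=3, n_unique=20, n_shared=3, genome_len=2_000_000, seed=SEED
    )
    rng = np.random.default_rng(SEED + 100)
    genes = synthetic_genes(cohort.genome, rng)
    write_refflat(genes, RESULTS / "synthetic_genes.refflat")

    # a prior screen: half of the true loci plus scattered sites
    true_loci = sorted({(s.chrom, s.insertion_point)
                        for sites in cohort.sample_sites.values() for s in sites})
    prior: dict[str, list[int]] = {}
    for chrom, p in true_loci:
        if rng.random() < 0.5:
            prior.setdefault(chrom, []).append(p + int(rng.integers(-50, 51)))
    for chrom, seq in cohort.genome.sequences.items():
        extra = rng.integers(0, len(seq), size=30)
        prior.setdefault(chrom, []).extend(int(x) for x in extra)
    prior_arr = {c: np.sort(np.array(v)) for c, v in prior.items()}

    rows = []
    for rec in calls.itertuples(index=False):
        a = nearest_gene(rec.pos - 1, rec.chrom, rec.orientation, genes)
        rows.append({
            "sample": rec.sample, "chrom": rec.chrom, "pos": rec.pos,
            "orientation": rec.orientation, "fusion": rec.fusion,
            "nearest_gene": a.gene, "distance": a.distance,
            "location": a.location, "relative_orientation": a.relative_orientation,
        })
    annotated = pd.DataFrame(rows)
    annotated["position"] = annotated["pos"] - 1
    annotated = distance_to_prior(annotated, prior_arr).drop(columns="position")
    annotated.to_csv(RESULTS / "annotated_integrations.tsv", sep="\t", index=False)

    # gene-set overlap between this screen and the prior screen
    rna_genes = {r["nearest_gene"] for r in rows if r["nearest_gene"]}
    prior_genes = {
        nearest_gene(int(p), chrom, "S", genes).gene
        for chrom, ps in prior_arr.items() for p in ps
    } - {""}
    overlap = len(rna_genes & prior_genes)
    p = gene_set_overlap_test(overlap, len(rna_genes), len(prior_genes), len(genes))
    n_near = int(annotated["near_prior"].sum())
    print(f"{len(annotated)} integrations annotated; "
          f"{n_near} within 10 kb of a prior site")
    print(f"gene-set overlap {overlap}/{len(rna_genes)} vs prior "
          f"{len(prior_genes)} of {len(genes)} genes: "
          f"hypergeometric P = {p:.3e}")
    with open(RESULTS / "gene_overlap_test.json", "w") as fh:
        import json
        json.dump({"overlap": overlap, "n_rna": len(rna_genes),
                   "n_prior": len(prior_genes), "universe": len(genes),
                   "p_value": p}, fh, indent=1)


if __name__ == "__main__":
    main()
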