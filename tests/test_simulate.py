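"""Generator ground truth: determinism, composition, and junction geometry."""

import numpy as np
import pytest

from retromap import simulate as sim
from retromap.genome import revcomp


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestMakeGenome:
    def test_deterministic_given_seed(self, provirus):
        a, _ = sim.make_genome(2, [12_000, 15_000], 0.5, [(0.9, 1)],
                               provirus.ltr_seq, seed=7)
        b, _ = sim.make_genome(2, [12_000, 15_000], 0.5, [(0.9, 1)],
                               provirus.ltr_seq, seed=7)
        assert a.sequences == b.sequences

    def test_gc_within_binomial_band(self, provirus):
        n = 1_000_000
        g, _ = sim.make_genome(1, [n], 0.5, [], provirus.ltr_seq, seed=3)
        gc = sum(g.sequences["chr1"].count(b) for b in "GC")
        sigma = (n * 0.5 * 0.5) ** 0.5
        assert abs(gc - n * 0.5) < 3 * sigma

    def test_decoy_hamming_distance_matches_identity(self, provirus):
        ltr = provirus.ltr_seq
        assert len(ltr) == 400
        g, truth = sim.make_genome(1, [50_000], 0.42, [(0.95, 1)], ltr, seed=9)
        d = truth.decoys[0]
        body = g.sequences[d["chrom"]][d["start"] : d["end"]]
        if d["strand"] == "-":
            body = revcomp(body)
        assert abs(hamming(body, ltr) - 20) <= 1

    def test_validation_errors(self, provirus):
        with pytest.raises(ValueError):
            sim.make_genome(1, [5_000], 0.5, [], provirus.ltr_seq, seed=0)
        with pytest.raises(ValueError):
            sim.make_genome(1, [20_000], 0.5, [(0.3, 1)], provirus.ltr_seq, seed=0)


class TestPlantProviruses:
    def test_zero_sites_leaves_genome_unchanged(self, provirus):
        g, _ = sim.make_genome(1, [20_000], 0.5, [], provirus.ltr_seq, seed=2)
        gmod, table = sim.plant_proviruses(g, provirus, [])
        assert gmod.sequences == g.sequences
        assert len(table) == 0

    def test_sense_insertion_geometry(self, planted, provirus):
        genome, gmod, table, site = planted
        row = table.iloc[0]
        grown = len(gmod.sequences["chr1"]) - len(genome.sequences["chr1"])
        assert grown == len(provirus) + site.tsd_len
        Lm, Rm = row["left_jx_mod"], row["right_jx_mod"]
        # left junction is host/U3, right junction is U5/host
        assert gmod.sequences["chr1"][Lm : Lm + 50] == provirus.sequence[:50]
        assert gmod.sequences["chr1"][Rm - 50 : Rm] == provirus.sequence[-50:]
        # TSD duplicated on both sides
        p, t = site.insertion_point, site.tsd_len
        tsd = genome.sequences["chr1"][p : p + t]
        assert gmod.sequences["chr1"][Lm - t : Lm] == tsd
        assert gmod.sequences["chr1"][Rm : Rm + t] == tsd

    def test_antisense_insertion_mirrors_element_order(self, provirus):
        g, _ = sim.make_genome(1, [30_000], 0.5, [], provirus.ltr_seq, seed=4)
        site = sim.PlantedProvirus("chr1", 15_000, "AS", 4)
        gmod, table = sim.plant_proviruses(g, provirus, [site])
        row = table.iloc[0]
        body = gmod.sequences["chr1"][row["left_jx_mod"] : row["right_jx_mod"]]
        assert body == revcomp(provirus.sequence)
        # the right junction abuts reverse-complemented U3
        assert body[-50:] == revcomp(provirus.sequence[:50])

    def test_site_in_n_region_rejected(self, provirus):
        g, _ = sim.make_genome(1, [30_000], 0.5, [], provirus.ltr_seq, seed=4)
        seq = g.sequences["chr1"]
        g.sequences["chr1"] = seq[:15_000] + "N" * 100 + seq[15_100:]
        with pytest.raises(ValueError, match="N region"):
            sim.plant_proviruses(g, provirus, [sim.PlantedProvirus("chr1", 15_050)])


class TestSimulateLibrary:
    def test_silent_sites_make_empty_library(self, planted, provirus):
        _, gmod, table, site = planted
        quiet = sim.PlantedProvirus(
            site.chrom, site.insertion_point, site.orientation, site.tsd_len,
            expression={k: 0.0 for k in sim.JUNCTION_KINDS},
        )
        pairs, truth = sim.simulate_library(gmod, table, provirus, [quiet], seed=0)
        assert pairs == [] and len(truth) == 0

    def test_reads_have_default_length_101(self, planted, provirus):
        _, gmod, table, site = planted
        pairs, truth = sim.simulate_library(gmod, table, provirus, [site], seed=1)
        assert pairs
        assert all(len(p.seq1) == 101 and len(p.seq2) == 101 for p in pairs)
        assert len(truth) == len(pairs)

    def test_fastq_roundtrip_record_count(self, planted, provirus, tmp_path):
        _, gmod, table, site = planted
        pairs, truth = sim.simulate_library(gmod, table, provirus, [site], seed=1)
        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        sim.write_fastq_pair(pairs, f1, f2)
        n_records = sum(1 for line in open(f1)) / 4 + sum(1 for line in open(f2)) / 4
        assert n_records == 2 * len(truth)
        back = sim.read_fastq_pairs(f1, f2)
        assert [(p.id, p.seq1, p.seq2) for p in back] == [
            (p.id, p.seq1, p.seq2) for p in pairs
        ]

    def test_fusion_read_count_matches_monte_carlo_expectation(
        self, planted, provirus
    ):
        """Observed fusion reads vs a 1e5-fragment Monte-Carlo placement oracle."""
        _, gmod, table, site = planted
        mean = 2_000.0
        loud = sim.PlantedProvirus(
            site.chrom, site.insertion_point, site.orientation, site.tsd_len,
            expression={"u3_readin": mean, "u5_promoter": 0.0, "sd_splice": 0.0},
        )
        pairs, truth = sim.simulate_library(gmod, table, provirus, [loud], seed=2)
        observed = int((truth.m1_covers | truth.m2_covers).sum())
        # oracle: same fragment geometry, independent placement draws
        tseq, j, _ = sim.junction_transcript(gmod, provirus, table.iloc[0], "u3_readin")
        rng = np.random.default_rng(99)
        n_mc = 100_000
        flens = np.clip(np.round(rng.normal(325, 50, n_mc)), 101, 600).astype(int)
        flens = np.minimum(flens, len(tseq))
        starts = (rng.random(n_mc) * (len(tseq) - flens + 1)).astype(int)
        covers = ((starts < j) & (j < starts + 101)) | (
            (starts + flens - 101 < j) & (j < starts + flens)
        )
        p_hat = covers.mean()
        sigma = (mean * p_hat) ** 0.5
        assert abs(observed - mean * p_hat) < 3 * sigma

    def test_fusion_truth_consistent_with_read_sequences(self, planted, provirus):
        """String-search the host 30-mer abutting the junction back into the
        pre-integration genome: it must end at the recorded coordinate."""
        genome, gmod, table, site = planted
        pairs, truth = sim.simulate_library(gmod, table, provirus, [site], seed=6)
        host = genome.sequences["chr1"]
        by_id = {p.id: p for p in pairs}
        checked = 0
        for rec in truth.itertuples(index=False):
            if not rec.m1_covers or rec.kind == "background":
                continue
            off = rec.junction_offset - rec.start  # junction offset within mate1
            if not 30 <= off <= 71:
                continue
            m1 = by_id[rec.id].seq1
            if rec.kind == "u3_readin":
                mouse_kmer = m1[off - 30 : off]  # host side precedes the virus
                hit = host.find(mouse_kmer)
                assert hit != -1 and hit + 30 == rec.junction_orig
            else:  # u5_promoter / sd_splice: host side follows the junction
                mouse_kmer = m1[off : off + 30]
                hit = host.find(mouse_kmer)
                assert hit == rec.junction_orig
            checked += 1
        assert checked >= 5


class TestEnrichmentScenario:
    def test_same_seed_identical_bed(self, tmp_path):
        out = []
        for rep in range(2):
            peaks, ints, _ = sim.simulate_enrichment_scenario(
                200_000, 20, 300, 500, 5.0, seed=42
            )
            p = tmp_path / f"peaks{rep}.bed"
            sim.write_bed(peaks, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_uniform_case_in_peak_fraction(self):
        peaks, ints, truth = sim.simulate_enrichment_scenario(
            1_000_000, 50, 400, 10_000, 1.0, seed=1
        )
        q = truth.params["q"]
        n_in = truth.params["n_inside"]
        sigma = (10_000 * q * (1 - q)) ** 0.5
        assert abs(n_in - 10_000 * q) < 3 * sigma

    def test_planted_fold_matches_closed_form_mixture(self):
        # fold=10 at q=0.02: expected in-peak fraction 0.2/(0.2+0.98)
        peaks, ints, truth = sim.simulate_enrichment_scenario(
            1_000_000, 50, 400, 10_000, 10.0, seed=2
        )
        q = truth.params["q"]
        assert q == pytest.approx(0.02)
        expected = 10 * q / (10 * q + (1 - q))
        n_in = truth.params["n_inside"]
        sigma = (10_000 * expected * (1 - expected)) ** 0.5
        assert abs(n_in - 10_000 * expected) < 3 * sigma

    def test_peaks_fit_validation(self):
        with pytest.raises(ValueError):
            sim.simulate_enrichment_scenario(10_000, 100, 200, 10, 1.0, seed=0)


class TestScenarioTruthRoundtrip:
    def test_truth_serializes_and_regenerates(self, provirus, tmp_path):
        g1, t1 = sim.make_genome(1, [20_000], 0.5, [(0.9, 1)], provirus.ltr_seq, seed=13)
        path = tmp_path / "truth.json"
        t1.to_json(path)
        t2 = sim.ScenarioTruth.from_json(path)
        g2, _ = sim.make_genome(
            t2.params["n_chrom"], t2.params["lengths"], t2.params["gc"],
            [tuple(d) for d in t2.params["decoy_spec"]], provirus.ltr_seq,
            seed=t2.seed,
        )
        assert g1.sequences == g2.sequences
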