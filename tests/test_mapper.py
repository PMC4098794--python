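"""Prefix filtering, pair classification, integration calling, endogenous
filtering."""

import random

import numpy as np
import pytest

from retromap import simulate as sim
from retromap.align import SeedIndex, split_align_read
from retromap.genome import revcomp
from retromap.ltr_reference import build_chimera_reference, scan_ltr_like
from retromap.mapper import (
    PairEvidence,
    PESignatureClass,
    call_integrations,
    classify_pair,
    classify_pairs,
    filter_endogenous,
    prefix_filter,
)


@pytest.fixture(scope="module")
def chimera_ref(planted, provirus):
    genome, _, _, _ = planted
    regions = scan_ltr_like(genome, provirus.ltr_seq)
    return build_chimera_reference(regions, genome, [provirus])


class TestPrefixFilter:
    def test_both_viral_prefixes_dropped(self, chimera_ref, provirus):
        pair = sim.ReadPair("p", provirus.sequence[:101], provirus.sequence[500:601])
        kept, stats = prefix_filter([pair], chimera_ref)
        assert kept == [] and stats["dropped_both"] == 1

    def test_neither_prefix_matching_dropped(self, chimera_ref, planted):
        genome, _, _, _ = planted
        s = genome.sequences["chr1"]
        pair = sim.ReadPair("p", s[1_000:1_101], revcomp(s[1_300:1_401]))
        kept, stats = prefix_filter([pair], chimera_ref)
        assert kept == [] and stats["dropped_neither"] == 1

    def test_junction_pair_kept_with_exact_kmer_oracle(
        self, chimera_ref, planted, provirus
    ):
        """One mate leading in the LTR, the other in unique host sequence."""
        _, gmod, table, _ = planted
        Rm = table.iloc[0]["right_jx_mod"]
        viral = gmod.sequences["chr1"][Rm - 150 : Rm - 49]  # inside 3' LTR
        host = revcomp(gmod.sequences["chr1"][Rm + 200 : Rm + 301])
        pair = sim.ReadPair("p", viral, host)
        kept, _ = prefix_filter([pair], chimera_ref)
        assert kept == [pair]
        # oracle: exact 25-mer membership over reference entries
        all_ref = [e.sequence for e in chimera_ref.entries]
        def hits(prefix):
            return any(prefix in s or revcomp(prefix) in s for s in all_ref)
        assert hits(viral[:25]) and not hits(host[:25])

    def test_malformed_records_skipped(self, chimera_ref):
        pair = sim.ReadPair("p", "ACGT", "ACGT")
        kept, stats = prefix_filter([pair], chimera_ref)
        assert kept == [] and stats["malformed"] == 1


class TestClassifyPair:
    def _classify(self, pair, index, provirus):
        s1 = split_align_read(pair.seq1, index, pair.id, 1)
        s2 = split_align_read(pair.seq2, index, pair.id, 2)
        return classify_pair(s1, s2, provirus, pair.id)

    def test_promoter_insertion_signature(self, planted, planted_index, provirus):
        """Mate1 spanning the U5/host junction, transcription virus->mouse:
        the hallmark of retroviral promoter insertion."""
        _, gmod, table, _ = planted
        pair = sim.make_signature_pair(
            "U5", "FUSION_M1", "VIRUS_TO_MOUSE", gmod, provirus, table.iloc[0]
        )
        ev = self._classify(pair, planted_index, provirus)
        assert ev.status == "chimeric"
        assert ev.signature == PESignatureClass("U5", "FUSION_M1", "VIRUS_TO_MOUSE")
        assert ev.orientation == "S"

    def test_spanning_u3_pair(self, planted, planted_index, provirus):
        _, gmod, table, _ = planted
        pair = sim.make_signature_pair(
            "U3", "SPANNING", "MOUSE_TO_VIRUS", gmod, provirus, table.iloc[0]
        )
        ev = self._classify(pair, planted_index, provirus)
        assert ev.signature == PESignatureClass("U3", "SPANNING", "MOUSE_TO_VIRUS")
        assert ev.approximate

    def test_both_mates_fully_viral_not_chimeric(self, planted_index, provirus):
        pair = sim.ReadPair("p", provirus.sequence[1_000:1_101],
                            revcomp(provirus.sequence[1_200:1_301]))
        ev = self._classify(pair, planted_index, provirus)
        assert ev.status == "not_chimeric"

    def test_exhaustive_cell_inversion(self, planted, planted_index, provirus):
        """Every constructed taxonomy cell classifies back to itself."""
        _, gmod, table, _ = planted
        row = table.iloc[0]
        for element, direction in sim.SIGNATURE_CELLS:
            for coverage in sim.COVERAGE_CLASSES:
                pair = sim.make_signature_pair(
                    element, coverage, direction, gmod, provirus, row
                )
                ev = self._classify(pair, planted_index, provirus)
                assert ev.status == "chimeric", (element, coverage, direction)
                assert ev.signature == PESignatureClass(element, coverage, direction)


def _evidence(position, coverage="FUSION_M1", mouse_len=80, margin=5.0,
              sample="s1", element="U5", direction="VIRUS_TO_MOUSE",
              orientation="S", rid="r"):
    return PairEvidence(
        read_id=rid, sample=sample, status="chimeric",
        signature=PESignatureClass(element, coverage, direction),
        chrom="chr1", position=position, approximate=coverage == "SPANNING",
        mouse_len=mouse_len, mouse_margin=margin, orientation=orientation,
    )


class TestCallIntegrations:
    def test_39bp_host_segment_is_no_call(self):
        """The 40-bp unambiguous-sequence rule, at the boundary."""
        ev = [_evidence(1_000, mouse_len=39)]
        calls, unsupported = call_integrations(ev, min_unambig=40)
        assert calls == []
        assert len(unsupported) == 1
        ev40 = [_evidence(1_000, mouse_len=40)]
        calls40, _ = call_integrations(ev40, min_unambig=40)
        assert len(calls40) == 1

    def test_five_concordant_fusion_pairs_one_call(self):
        ev = [_evidence(5_000, rid=f"r{i}") for i in range(5)]
        calls, _ = call_integrations(ev)
        assert len(calls) == 1
        c = calls[0]
        assert c.n_pairs == 5 and c.n_fusion_reads == 5 and c.fusion_supported
        assert c.position == 5_000 and c.relative_coverage == 1.0

    def test_zero_margin_cluster_unsupported(self):
        ev = [_evidence(2_000, margin=0.0)]
        calls, unsupported = call_integrations(ev)
        assert calls == [] and len(unsupported) == 1

    def test_spanning_pairs_attach_to_fusion_cluster(self):
        ev = [_evidence(5_000, rid="f1"),
              _evidence(4_700, coverage="SPANNING", rid="s1"),
              _evidence(5_350, coverage="SPANNING", rid="s2")]
        calls, _ = call_integrations(ev)
        assert len(calls) == 1
        assert calls[0].n_pairs == 3 and calls[0].n_fusion_reads == 1
        assert calls[0].position == 5_000

    def test_spanning_only_cluster_is_approximate_call(self):
        ev = [_evidence(8_000 + d, coverage="SPANNING", rid=f"s{d}")
              for d in (0, 150, 300)]
        calls, _ = call_integrations(ev)
        assert len(calls) == 1
        assert calls[0].approximate and not calls[0].fusion_supported

    def test_order_independent_and_deterministic(self, rng):
        base = [_evidence(1_000 + i % 3, rid=f"a{i}") for i in range(6)]
        base += [_evidence(40_000 + (i % 2), rid=f"b{i}", element="U3",
                           direction="MOUSE_TO_VIRUS") for i in range(4)]
        calls1, _ = call_integrations(list(base))
        shuffled = list(base)
        random.Random(7).shuffle(shuffled)
        calls2, _ = call_integrations(shuffled)
        key = lambda c: (c.sample, c.chrom, c.position)
        assert sorted((key(c) for c in calls1)) == sorted((key(c) for c in calls2))

    def test_relative_coverage_averages_one(self):
        ev = ([_evidence(1_000, rid=f"r{i}") for i in range(7)]
              + [_evidence(50_000, rid=f"q{i}") for i in range(3)]
              + [_evidence(90_000, rid="z")])
        calls, _ = call_integrations(ev)
        assert np.mean([c.relative_coverage for c in calls]) == pytest.approx(1.0)


class TestFilterEndogenous:
    def test_single_sample_unchanged(self):
        calls, _ = call_integrations([_evidence(1_000)])
        filtered, removed = filter_endogenous(calls)
        assert filtered == calls and len(removed) == 0

    def test_locus_in_all_samples_removed_everywhere(self):
        ev = [_evidence(9_999 + i, sample=f"s{i}", rid=f"r{i}") for i in range(4)]
        calls, _ = call_integrations(ev)
        assert len(calls) == 4
        filtered, removed = filter_endogenous(calls, position_tol=10)
        assert filtered == []
        assert removed.iloc[0]["n_samples"] == 4

    def test_private_calls_survive(self):
        ev = [_evidence(1_000, sample="s1"), _evidence(70_000, sample="s2")]
        calls, _ = call_integrations(ev)
        filtered, removed = filter_endogenous(calls)
        assert len(filtered) == 2 and len(removed) == 0


def test_full_pipeline_recovers_decoy_transcription(provirus):
    """Three samples share one transcribed locus: only it is removed."""
    genome, _ = sim.make_genome(1, [200_000], 0.45, [], provirus.ltr_seq, seed=77)
    shared = sim.PlantedProvirus("chr1", 100_000, "S", 4)
    rng = np.random.default_rng(1)
    all_calls = []
    uniques = {}
    for i, upos in enumerate((30_000, 60_000, 150_000)):
        name = f"t{i}"
        unique = sim.PlantedProvirus("chr1", upos, "AS", 4)
        uniques[name] = unique
        gmod, table = sim.plant_proviruses(genome, provirus, [shared, unique])
        pairs, _ = sim.simulate_library(
            gmod, table, provirus, [shared, unique],
            seed=int(rng.integers(2**31)), sample=name,
        )
        idx = SeedIndex.from_genome(genome, provirus)
        ev = classify_pairs(pairs, idx, provirus)
        calls, _ = call_integrations(ev)
        all_calls.extend(calls)
    filtered, removed = filter_endogenous(all_calls)
    assert len(removed) == 1
    assert abs(removed.iloc[0]["position"] - 100_000) <= 4
    assert len(filtered) == 3
    for c in filtered:
        u = uniques[c.sample]
        assert min(abs(c.position - u.insertion_point),
                   abs(c.position - (u.insertion_point + 4))) <= 4
        assert c.orientation == "AS"
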