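import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocoupler import pasdb
from isocoupler.core import GenomeInterval, ReadAlignment, SiteRecord, ValidationError
from isocoupler.simulate import simulate_gene_models, SimGeneSpec
from oracles import linkage_clusters_oracle


def _tailed_read(pos, strand="+", chrom="c", rid=None, length=50):
    if strand == "+":
        block = GenomeInterval(chrom, pos - length, pos, "+")
    else:
        block = GenomeInterval(chrom, pos, pos + length, "-")
    return ReadAlignment(
        rid or f"r{pos}_{np.random.randint(1 << 30)}",
        [block], has_polya=True, tail_length=50,
    )


class TestBuildPasDatabase:
    def test_two_reads_one_cluster(self):
        reads = [_tailed_read(100, rid="a"), _tailed_read(100, rid="b")]
        (c,) = pasdb.build_pas_database(reads)
        assert (c.position, c.support) == (100, 2)

    def test_window_chain_and_min_support(self):
        reads = [_tailed_read(p, rid=f"r{i}") for i, p in enumerate([100, 110, 135])]
        clusters = pasdb.build_pas_database(reads, window=20, min_support=2)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_positions) == [100, 110]

    def test_empty(self):
        assert pasdb.build_pas_database([]) == []

    def test_rejects_tailless(self):
        r = ReadAlignment("r", [GenomeInterval("c", 0, 10, "+")], has_polya=False)
        with pytest.raises(ValidationError):
            pasdb.build_pas_database([r])

    def test_representative_modal_then_distal(self):
        reads = [_tailed_read(p, rid=f"r{i}") for i, p in enumerate([100, 100, 105, 105, 90])]
        (c,) = pasdb.build_pas_database(reads)
        assert c.position == 105  # tie on mode 100/105 -> 3'-most on +
        reads_m = [
            _tailed_read(p, strand="-", rid=f"m{i}")
            for i, p in enumerate([100, 100, 105, 105])
        ]
        (cm,) = pasdb.build_pas_database(reads_m)
        assert cm.position == 100  # 3'-most on - strand is the smaller coord

    def test_support_conservation(self):
        rng = np.random.default_rng(0)
        positions = sorted(rng.integers(1000, 2000, size=40).tolist())
        reads = [_tailed_read(p, rid=f"r{i}") for i, p in enumerate(positions)]
        clusters = pasdb.build_pas_database(reads, window=20, min_support=2)
        kept = sum(c.support for c in clusters)
        dropped = sum(
            len(g)
            for g in linkage_clusters_oracle(positions, 20)
            if len(g) < 2
        )
        assert kept + dropped == len(reads)

    @given(
        st.lists(st.integers(0, 400), min_size=1, max_size=15),
        st.integers(1, 30),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_linkage(self, positions, window):
        reads = [_tailed_read(p + 500, rid=f"r{i}") for i, p in enumerate(positions)]
        clusters = pasdb.build_pas_database(reads, window=window, min_support=1)
        got = sorted(sorted(c.member_positions) for c in clusters)
        want = linkage_clusters_oracle([p + 500 for p in positions], window)
        assert got == want


class TestCluster3Seq:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "strand", "pos", "count"])

    def test_low_coverage_dropped(self):
        cov = self._frame([("c", "+", 100, 4)])
        assert pasdb.cluster_3seq_sites(cov) == []

    def test_merge_within_15(self):
        cov = self._frame([("c", "+", 100, 6), ("c", "+", 114, 7)])
        (c,) = pasdb.cluster_3seq_sites(cov)
        assert sorted(c.member_positions) == [100, 114]
        assert c.support == 13

    def test_split_beyond_15(self):
        cov = self._frame([("c", "+", 100, 6), ("c", "+", 116, 7)])
        assert len(pasdb.cluster_3seq_sites(cov)) == 2


class TestInternalPrimingMask:
    def _genome_with(self, upstream, pos=500, total=1000):
        seq = list("C" * total)
        seq[pos - len(upstream) : pos] = list(upstream)
        return {"c": "".join(seq)}

    def _far_transcript(self):
        return []

    def test_eight_as_blacklisted(self):
        genome = self._genome_with("AAAAAAAATC")
        mask = pasdb.internal_priming_mask(genome, [])
        assert 500 in mask[("c", "+")]

    def test_seven_as_not_blacklisted(self):
        genome = self._genome_with("AAAAAAATTC")
        mask = pasdb.internal_priming_mask(genome, [])
        assert 500 not in mask[("c", "+")]

    def test_tes_exemption(self):
        genome = self._genome_with("AAAAAAAAAA")
        from isocoupler.core import TranscriptModel

        tx = TranscriptModel("t", "g", [GenomeInterval("c", 200, 600, "+")])
        # TES at 600, |600-500| = 100 <= 250 -> exempt
        mask = pasdb.internal_priming_mask(genome, [tx])
        assert 500 not in mask[("c", "+")]
        far = TranscriptModel("t2", "g2", [GenomeInterval("c", 800, 900, "+")])
        mask2 = pasdb.internal_priming_mask(genome, [far])
        assert 500 in mask2[("c", "+")]

    def test_minus_strand_t_run(self):
        seq = "C" * 500 + "T" * 10 + "C" * 490
        mask = pasdb.internal_priming_mask({"c": seq}, [])
        assert 500 in mask[("c", "-")]
        assert 500 not in mask[("c", "+")]

    def test_missing_chrom_errors(self):
        from isocoupler.core import TranscriptModel

        tx = TranscriptModel("t", "g", [GenomeInterval("chrX", 10, 20, "+")])
        with pytest.raises(ValidationError, match="chrX"):
            pasdb.internal_priming_mask({"c": "ACGT" * 100}, [tx])


class TestSignalScan:
    def test_hierarchy_prefers_top_rank(self):
        seq = "C" * 10 + "ATTAAA" + "C" * 10 + "AATAAA" + "C" * 18
        call = pasdb.scan_polya_signal(seq, 50)
        assert call.signal == "AATAAA"

    def test_last_ranked(self):
        seq = "C" * 20 + "TTTAAA" + "C" * 24
        assert pasdb.scan_polya_signal(seq, 50).signal == "TTTAAA"

    def test_none(self):
        assert pasdb.scan_polya_signal("GC" * 25, 50).signal == "none"

    def test_window_too_long_errors(self):
        with pytest.raises(ValidationError):
            pasdb.scan_polya_signal("ACGT", 20)

    def test_offset_of_closest_occurrence(self):
        seq = "AATAAA" + "C" * 14
        call = pasdb.scan_polya_signal(seq, 20)
        assert call.offset == 14


class TestNucleotideProfile:
    def test_columns_sum_to_one_and_indicator(self):
        genome = {"c": "ACGT" * 200}
        sites = [SiteRecord("c", 400, "+", "p0")]
        prof = pasdb.nucleotide_profile(sites, genome, flank=10)
        assert np.allclose(prof.sum(axis=0), 1.0)
        assert set(np.unique(prof.values)) <= {0.0, 1.0}
        # offset 0 = first base at/after the boundary: genome[400] == 'A'
        assert prof.loc["A", 0] == 1.0

    def test_edge_site_skipped(self):
        genome = {"c": "ACGT" * 10}
        sites = [SiteRecord("c", 2, "+", "p0"), SiteRecord("c", 20, "+", "p1")]
        prof = pasdb.nucleotide_profile(sites, genome, flank=10)
        assert np.allclose(prof.sum(axis=0), 1.0)  # only p1 counted

    def test_downstream_a_rich_fixture(self):
        up = "CGCG" * 25
        down = "A" * 60 + "CG" * 20 + "C"
        genome = {"c": up + down}
        sites = [SiteRecord("c", 100, "+", "p0")]
        prof = pasdb.nucleotide_profile(sites, genome, flank=50)
        a_down = prof.loc["A", range(0, 51)].mean()
        a_up = prof.loc["A", range(-50, 0)].mean()
        assert a_down > a_up


class TestTails:
    def _reads(self, tails):
        out = []
        for i, t in enumerate(tails):
            out.append(
                ReadAlignment(
                    f"r{i}", [GenomeInterval("c", 0, 100, "+")],
                    has_polya=True, tail_length=t,
                )
            )
        return out

    def test_odd_median(self):
        reads = self._reads([50, 100, 150])
        tab = pasdb.summarize_tail_lengths(reads, {f"r{i}": "g" for i in range(3)})
        assert tab.median_tail_length.iloc[0] == 100

    def test_even_median(self):
        reads = self._reads([50, 100])
        tab = pasdb.summarize_tail_lengths(reads, {f"r{i}": "g" for i in range(2)})
        assert tab.median_tail_length.iloc[0] == 75

    def test_single_read(self):
        reads = self._reads([42])
        tab = pasdb.summarize_tail_lengths(reads, {"r0": "g"})
        assert tab.median_tail_length.iloc[0] == 42

    def test_empty_groups_omitted(self):
        reads = self._reads([42])
        tab = pasdb.summarize_tail_lengths(reads, {})
        assert tab.empty


class TestPileups:
    def _reads_at(self, pos, n, strand="+"):
        return [
            ReadAlignment(
                f"r{pos}_{i}",
                [GenomeInterval("c", pos, pos + 200, "+")]
                if strand == "+"
                else [GenomeInterval("c", pos - 200, pos, "-")],
            )
            for i in range(n)
        ]

    def test_cpm_threshold_strict(self):
        # library of 1000 reads; the 31-read bin sits at exactly 31000 CPM
        reads = self._reads_at(100, 31) + self._reads_at(5000, 969)
        tab = pasdb.call_5prime_pileups(reads, [], window=50, min_cpm=31000)
        assert not (tab.bin_start == 100).any()  # strict inequality drops it
        tab2 = pasdb.call_5prime_pileups(reads, [], window=50, min_cpm=30999)
        assert (tab2.bin_start == 100).any()

    def test_tss_overlap_flag(self):
        reads = self._reads_at(100, 10)
        tss = [SiteRecord("c", 140, "+", "t0")]
        tab = pasdb.call_5prime_pileups(reads, tss, window=50, min_cpm=1)
        assert tab.tss_overlap.iloc[0]
        tss_far = [SiteRecord("c", 400, "+", "t0")]
        tab2 = pasdb.call_5prime_pileups(reads, tss_far, window=50, min_cpm=1)
        assert not tab2.tss_overlap.iloc[0]

    def test_empty_library_errors(self):
        with pytest.raises(ValidationError):
            pasdb.call_5prime_pileups([], [])


class TestBlacklistOnSimulated(object):
    def test_planted_ip_detected_true_pas_spared(self, cfg):
        models, _, _, truth, genome = simulate_gene_models(
            4, SimGeneSpec(), cfg, seed=33
        )
        mask = pasdb.internal_priming_mask(genome, models)
        for gene in truth.genes.values():
            key = (gene.chrom, gene.strand)
            assert gene.ip_pos in mask[key]
            for p in gene.pas_pos:
                assert p not in mask[key]
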