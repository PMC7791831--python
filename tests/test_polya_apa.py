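"""Poly(A)-site clustering, isoform roles, and APA-methylation coupling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _helpers import connected_components_clusters
from nanostoich.polya_apa import (
    PolyACluster,
    ReadEndRecord,
    apa_fold_change_table,
    apa_methylation_fold_change,
    apa_polya_length_screen,
    assign_proximal_distal,
    attach_cluster_m6a,
    cluster_polya_sites,
    read_polya_tsv,
)
from nanostoich.quantify import ReadSiteCall


def records_for(positions, gene="g1", strand="+", lengths=None):
    lengths = lengths or [50.0] * len(positions)
    return [
        ReadEndRecord(f"r{i}", gene, "chr1", int(p), strand, float(l), "PASS")
        for i, (p, l) in enumerate(zip(positions, lengths))
    ]


class TestClustering:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([100, 110, 150], [[100, 110], [150]]),  # gap 40 > 24
            ([100, 124, 148], [[100, 124, 148]]),  # inclusive at exactly 24
            ([100], [[100]]),
            ([], []),
        ],
    )
    def test_chaining_examples(self, positions, expected):
        clusters = cluster_polya_sites(records_for(positions))
        got = sorted(sorted(c.positions) for c in clusters)
        assert got == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 300), min_size=0, max_size=10))
    def test_equals_connected_components_oracle(self, positions):
        clusters = cluster_polya_sites(records_for(positions))
        got = sorted(sorted(c.positions) for c in clusters)
        assert got == connected_components_clusters(positions)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=1, max_size=12),
           st.integers(-1000, 1000))
    def test_order_independence_and_translation_invariance(self, positions, delta):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(positions))
        base = sorted(sorted(c.positions) for c in cluster_polya_sites(records_for(positions)))
        shuf = sorted(sorted(c.positions) for c in cluster_polya_sites(records_for(shuffled)))
        assert base == shuf
        moved = sorted(
            sorted(c.positions)
            for c in cluster_polya_sites(records_for([p + delta for p in positions]))
        )
        assert moved == [[p + delta for p in grp] for grp in base]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 400), min_size=1, max_size=15))
    def test_every_pass_read_in_exactly_one_cluster(self, positions):
        records = records_for(positions)
        clusters = cluster_polya_sites(records)
        member_ids = [rid for c in clusters for rid in c.read_ids]
        assert sorted(member_ids) == sorted(r.read_id for r in records)

    def test_non_pass_reads_excluded(self):
        records = records_for([100, 105]) + [
            ReadEndRecord("bad", "g1", "chr1", 102, "+", 40.0, "ADAPTER")
        ]
        clusters = cluster_polya_sites(records)
        assert all("bad" not in c.read_ids for c in clusters)

    def test_representative_is_mode_with_3prime_tiebreak(self):
        fwd = cluster_polya_sites(records_for([100, 100, 110, 110, 105]))[0]
        assert fwd.representative == 110  # tie 100/110 -> most 3' on +
        rev = cluster_polya_sites(records_for([100, 100, 110, 110], strand="-"))[0]
        assert rev.representative == 100  # most 3' on - is the smallest coordinate


def make_cluster(gene, strand, positions, lengths=(), role=None, tag=""):
    return PolyACluster(
        gene_id=gene,
        chrom="chr1",
        strand=strand,
        positions=list(positions),
        read_ids=[f"{gene}{tag}_{i}" for i in range(len(positions))],
        polya_lengths=list(lengths),
        role=role,
    )


class TestRoles:
    def test_forward_strand_ordering(self):
        clusters = [
            make_cluster("g", "+", [1000] * 12),
            make_cluster("g", "+", [1500] * 12),
        ]
        assign_proximal_distal(clusters, "+", stop_codon_genomic=800)
        assert clusters[0].role == "proximal" and clusters[1].role == "distal"

    def test_reverse_strand_flips(self):
        clusters = [
            make_cluster("g", "-", [1000] * 12),
            make_cluster("g", "-", [1500] * 12),
        ]
        assign_proximal_distal(clusters, "-", stop_codon_genomic=1700)
        assert clusters[0].role == "distal" and clusters[1].role == "proximal"

    def test_middle_cluster_labeled_other(self):
        clusters = [
            make_cluster("g", "+", [1000] * 12),
            make_cluster("g", "+", [1200] * 12),
            make_cluster("g", "+", [1500] * 12),
        ]
        assign_proximal_distal(clusters, "+", 800)
        assert [c.role for c in clusters] == ["proximal", "other", "distal"]

    def test_insufficient_support_means_non_apa(self):
        clusters = [
            make_cluster("g", "+", [1000] * 12),
            make_cluster("g", "+", [1500] * 5),  # below min_cluster_reads
        ]
        assign_proximal_distal(clusters, "+", 800)
        assert all(c.role is None for c in clusters)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            assign_proximal_distal([], ".", 100)


class TestLengthScreen:
    @pytest.mark.parametrize(
        "mean_p, mean_d, flagged",
        [
            (40.0, 90.0, True),  # 2.25-fold
            (80.0, 100.0, False),  # 1.25-fold
            (50.0, 100.0, True),  # exactly two-fold, inclusive
        ],
    )
    def test_two_fold_boundary(self, mean_p, mean_d, flagged):
        clusters = [
            make_cluster("g", "+", [1000] * 12, [mean_p] * 12, role="proximal"),
            make_cluster("g", "+", [1500] * 12, [mean_d] * 12, role="distal"),
        ]
        screen = apa_polya_length_screen(clusters)
        assert bool(screen.iloc[0].flagged) == flagged

    def test_zero_mean_undefined(self):
        clusters = [
            make_cluster("g", "+", [1000] * 12, [0.0] * 12, role="proximal"),
            make_cluster("g", "+", [1500] * 12, [90.0] * 12, role="distal"),
        ]
        screen = apa_polya_length_screen(clusters)
        assert math.isnan(screen.iloc[0].fold) and not bool(screen.iloc[0].flagged)


class TestFoldChange:
    def test_equal_ratios_give_zero(self):
        assert apa_methylation_fold_change(0.2, 0.2) == 0.0

    def test_epsilon_arithmetic(self):
        assert apa_methylation_fold_change(0.19, 0.39) == pytest.approx(-1.0)

    def test_cluster_ratios_from_read_calls(self):
        """Per-cluster ratio counts the cluster's own reads at passing sites."""
        prox = make_cluster("g", "+", [1000] * 12, role="proximal", tag="P")
        dist = make_cluster("g", "+", [1500] * 12, role="distal", tag="D")
        calls = []
        for i in range(12):
            # proximal reads: 8/12 modified; distal reads: 4/12 modified
            calls.append(ReadSiteCall(prox.read_ids[i], "t", 50, "GGACT", 0.9,
                                      "modified" if i < 8 else "unmodified"))
            calls.append(ReadSiteCall(dist.read_ids[i], "t", 50, "GGACT", 0.9,
                                      "modified" if i < 4 else "unmodified"))
            # a call at a non-passing site must be ignored
            calls.append(ReadSiteCall(prox.read_ids[i], "t", 99, "GGACT", 0.9, "modified"))
        attach_cluster_m6a([prox, dist], calls, passing_sites={("t", 50)})
        assert prox.m6a_ratio == pytest.approx(8 / 12)
        assert dist.m6a_ratio == pytest.approx(4 / 12)
        table = apa_fold_change_table([prox, dist])
        expected = math.log2((4 / 12 + 0.01) / (8 / 12 + 0.01))
        assert table.iloc[0].log2_fc == pytest.approx(expected)

    def test_isoform_without_calls_absent(self):
        prox = make_cluster("g", "+", [1000] * 12, role="proximal", tag="P")
        dist = make_cluster("g", "+", [1500] * 12, role="distal", tag="D")
        calls = [ReadSiteCall(prox.read_ids[i], "t", 50, "GGACT", 0.9, "modified")
                 for i in range(12)]
        attach_cluster_m6a([prox, dist], calls, passing_sites={("t", 50)})
        assert apa_fold_change_table([prox, dist]).empty


class TestPolyaTsv:
    def test_column_map_and_qc_filter(self, tmp_path):
        df = pd.DataFrame(
            {
                "readname": ["a", "b", "c"],
                "gene": ["g1", "g1", "g2"],
                "contig": ["chr1"] * 3,
                "position": [100, 120, 300],
                "orient": ["+", "+", "-"],
                "polya_length": [80.5, 90.0, 45.0],
                "qc_tag": ["PASS", "SUFFCLIP", "PASS"],
            }
        )
        path = tmp_path / "polya.tsv"
        df.to_csv(path, sep="\t", index=False)
        records = read_polya_tsv(
            path,
            column_map={"readname": "read_id", "gene": "gene_id",
                        "contig": "chrom", "position": "end_pos", "orient": "strand"},
        )
        assert [r.read_id for r in records] == ["a", "c"]
        assert records[0].polya_length == pytest.approx(80.5)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"read_id": ["a"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_polya_tsv(path)
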