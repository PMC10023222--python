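"""Global identity, greedy clustering, purity splitting, representatives."""

import pytest

from enzymespace.cluster import (
    ClusteringParams,
    align_global,
    global_identity,
    greedy_cluster,
    select_representative,
    split_all,
    split_by_subsubclass,
    write_clusters_tsv,
)
from enzymespace.ec import EnzymeRecord, parse_ec
from enzymespace.synth import make_sequence_family

from oracles import biopython_global_score, biopython_identity, greedy_oracle


def _rec(acc, seq, ecs=("1.1.1.1",)):
    return EnzymeRecord(accession=acc, sequence=seq, ec_numbers=tuple(parse_ec(e) for e in ecs))


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0

    def test_single_mismatch(self):
        # one substitution over five aligned columns
        assert global_identity("ACDEF", "ACDEG") == pytest.approx(0.8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("ACD", "")

    def test_symmetry(self):
        pairs = [("ACDEFGHIKL", "ACDEGHIKL"), ("MKTAYIAKQR", "AYIAKQ"), ("AAAA", "AAAC")]
        for a, b in pairs:
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_terminal_gaps_stripped_from_denominator(self):
        # 3-residue N-terminal overhang must not dilute the identity
        assert global_identity("MKTACDEFGH", "ACDEFGH") == pytest.approx(1.0)

    def test_alignment_score_matches_biopython(self):
        import numpy as np

        rng = np.random.default_rng(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(aas), size=rng.integers(5, 40)))
            score, _, _ = align_global(a, b)
            assert score == pytest.approx(biopython_global_score(a, b))


class TestGreedyCluster:
    def test_singleton(self):
        (c,) = greedy_cluster([_rec("A", "ACDEFGHIKL")])
        assert c.representative == "A" and c.members == {"A": 1.0}

    def test_identical_set_collapses_to_one_cluster(self):
        records = [_rec(f"S{i}", "ACDEFGHIKLMNPQ") for i in range(5)]
        (c,) = greedy_cluster(records)
        assert len(c) == 5
        assert c.representative == "S0"  # accession tie-break at equal length

    def test_related_pair_separates_from_unrelated(self):
        fam = make_sequence_family(seed=3, n=2, target_identity=0.95, ec_labels="1.1.1.1", length=60)
        other = make_sequence_family(
            seed=99, n=1, target_identity=1.0, ec_labels="2.1.1.1", length=55, accession_prefix="OTH"
        )
        clusters = greedy_cluster(fam + other)
        assert {frozenset({"SYN000", "SYN001"}), frozenset({"OTH000"})} == set(
            frozenset(c.members) for c in clusters
        )

    def test_members_meet_cutoff_on_synthetic_families(self):
        records = []
        for k, ec in enumerate(["1.1.1.1", "2.3.1.12", "3.6.5.2"]):
            records += make_sequence_family(
                seed=10 + k, n=6, target_identity=0.85, ec_labels=ec,
                length=80 + 7 * k, accession_prefix=f"F{k}_",
            )
        params = ClusteringParams()
        clusters = greedy_cluster(records, params)
        by_acc = {r.accession: r for r in records}
        for c in clusters:
            for m, ident in c.members.items():
                assert ident >= params.identity_cutoff
                assert global_identity(
                    by_acc[m].sequence, by_acc[c.representative].sequence
                ) == pytest.approx(ident)

    def test_matches_brute_force_greedy_oracle(self):
        records = []
        for k, ec in enumerate(["1.1.1.1", "2.3.1.12"]):
            records += make_sequence_family(
                seed=20 + k, n=6, target_identity=0.85, ec_labels=ec,
                length=60 + 11 * k, accession_prefix=f"G{k}_",
            )
        assert len(records) <= 15
        matrix = {}
        for i, a in enumerate(records):
            for b in records[i + 1 :]:
                matrix[frozenset((a.accession, b.accession))] = biopython_identity(
                    a.sequence, b.sequence
                )
        oracle = greedy_oracle(records, matrix)
        ours = greedy_cluster(records)
        assert sorted(map(sorted, (m for _, m in oracle))) == sorted(
            sorted(c.members) for c in ours
        )


class TestRepresentativeSelection:
    def test_singleton_is_its_own_representative(self):
        recs = {"A": _rec("A", "ACDEF")}
        assert select_representative(["A"], recs) == "A"

    def test_centroid_by_mean_identity(self):
        # B is identical to A; C is closer to A than to B? make A the centroid:
        recs = {
            "A": _rec("A", "ACDEFGHIKLMNPQRSTVWY"),
            "B": _rec("B", "ACDEFGHIKLMNPQRSTVWY"),
            "C": _rec("C", "ACDEFGHIKLAAAAAAAAAA"),
        }
        # A and B tie on mean identity and length; lexicographic tie-break -> A
        assert select_representative(["A", "B", "C"], recs) == "A"

    def test_equal_identity_triangle_lexicographic(self):
        recs = {k: _rec(k, s) for k, s in [("Z", "AAAAC"), ("Y", "AAAAD"), ("X", "AAAAE")]}
        assert select_representative(["Z", "Y", "X"], recs) == "X"


class TestSubsubSplit:
    def test_mixed_cluster_partitions_by_subsub_key(self):
        recs = {
            "A": _rec("A", "ACDEFGHIKL", ["3.6.5.2"]),
            "B": _rec("B", "ACDEFGHIKM", ["3.6.5.3"]),
            "C": _rec("C", "ACDEFGHIKN", ["3.6.1.1"]),
        }
        cluster = greedy_cluster(list(recs.values()))[0]
        parts = split_by_subsubclass(cluster, recs)
        by_key = {p.subsub_class: sorted(p.members) for p in parts}
        assert by_key == {"3.6.5": ["A", "B"], "3.6.1": ["C"]}

    def test_pure_cluster_unchanged(self):
        recs = {
            "A": _rec("A", "ACDEFGHIKL", ["3.6.5.2"]),
            "B": _rec("B", "ACDEFGHIKM", ["3.6.5.2"]),
        }
        (cluster,) = greedy_cluster(list(recs.values()))
        (out,) = split_by_subsubclass(cluster, recs)
        assert out is cluster and out.subsub_class == "3.6.5"

    def test_multi_ec_member_lands_in_both_partitions(self):
        recs = {
            "A": _rec("A", "ACDEFGHIKL", ["3.6.5.2", "3.6.1.1"]),
            "B": _rec("B", "ACDEFGHIKM", ["3.6.5.3"]),
        }
        (cluster,) = greedy_cluster(list(recs.values()))
        parts = split_by_subsubclass(cluster, recs)
        keys = {p.subsub_class: sorted(p.members) for p in parts}
        assert keys["3.6.1"] == ["A"]
        assert keys["3.6.5"] == ["A", "B"]

    def test_wildcard_only_member_routed_to_unclassified(self):
        recs = {
            "A": _rec("A", "ACDEFGHIKL", ["3.6.5.2"]),
            "B": _rec("B", "ACDEFGHIKM", ["3.6"]),
        }
        (cluster,) = greedy_cluster(list(recs.values()))
        parts = split_by_subsubclass(cluster, recs)
        assert {p.subsub_class for p in parts} == {"3.6.5", "unclassified"}

    def test_post_split_purity_on_random_families(self, study):
        records = {r.accession: r for r in study["records"]}
        clusters = split_all(greedy_cluster(list(records.values())), records)
        for c in clusters:
            keys = set()
            for m in c.members:
                keys.update(records[m].subsub_keys())
            if c.subsub_class != "unclassified":
                assert c.subsub_class in keys
                # every member carries the cluster's key
                for m in c.members:
                    assert c.subsub_class in records[m].subsub_keys()


class TestClusterTSV:
    def test_byte_deterministic_output(self, tmp_path, study):
        records = {r.accession: r for r in study["records"]}
        clusters = split_all(greedy_cluster(list(records.values())), records)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_clusters_tsv(clusters, p1, tmp_path / "a.json")
        write_clusters_tsv(clusters, p2, tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        # representative<TAB>member dialect
        for line in p1.read_text().splitlines():
            assert len(line.split("\t")) == 2
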