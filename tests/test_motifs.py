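import numpy as np
import pytest
from scipy import stats as sps

import dendropy

from tcrep.errors import ValidationError
from tcrep.motifs import (
    MotifHit,
    build_specificity_clusters,
    cluster_pattern,
    cluster_prognosis_association,
    clustering_input,
    enriched_motifs,
    global_similarity_pairs,
    interior_kmers,
    neighbor_joining_tree,
)
from tcrep.repertoire import Clonotype, Repertoire


class TestClusteringInput:
    def test_read_threshold(self):
        rep = Repertoire("p1", [
            Clonotype("CASSAAAAF", templates=1),
            Clonotype("CASSCCCCF", templates=2)])
        members = clustering_input([rep])
        assert members == [("p1", "CASSCCCCF")]

    def test_empty_result_errors(self):
        rep = Repertoire("p1", [Clonotype("CASSAAAAF", templates=1)])
        with pytest.raises(ValidationError, match="threshold"):
            clustering_input([rep])

    def test_matches_generator_bookkeeping(self, small_cohort):
        members = set(clustering_input(small_cohort.repertoires))
        planted = set()
        for info in small_cohort.truth.clusters.values():
            planted |= set(info["members"])
        assert planted <= members  # planted clones always exceed 1 read


class TestInteriorKmers:
    def test_interior_only(self):
        # CASSLVNTEAFF interior is SLVNTE (first/last 3 excluded)
        kmers = interior_kmers("CASSLVNTEAFF", 4)
        assert kmers == {"SLVN", "LVNT", "VNTE"}

    def test_short_sequence_fallback(self):
        assert interior_kmers("CASSF", 3) == {"CAS", "ASS", "SSF"}
        assert interior_kmers("CASSF", 3, whole_string_fallback=False) == set()


class TestEnrichedMotifs:
    def test_planted_motif_found(self):
        rng = np.random.default_rng(4)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        ref = ["C" + "".join(rng.choice(alphabet, 10)) + "F"
               for _ in range(300)]
        sample = ["C" + "".join(rng.choice(alphabet, 10)) + "F"
                  for _ in range(28)]
        sample += ["CAS" + "WQPD" + "".join(rng.choice(alphabet, 3)) + "AFF"
                   for _ in range(12)]  # motif in ~30% of the sample
        hits = enriched_motifs(sample, ref, n_resamples=200, p_max=0.005,
                               seed=1)
        motifs = {h.motif for h in hits}
        assert "WQPD" in motifs
        hit = next(h for h in hits if h.motif == "WQPD")
        assert hit.p_value <= 1 / 201 + 1e-12
        assert hit.fold == np.inf or hit.fold >= 10

    def test_sample_from_reference_is_null(self):
        rng = np.random.default_rng(7)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        ref = ["C" + "".join(rng.choice(alphabet, rng.integers(8, 15))) + "F"
               for _ in range(1500)]
        clean = 0
        for seed in range(20):
            srng = np.random.default_rng(seed)
            sample = [ref[i] for i in srng.choice(len(ref), 120,
                                                  replace=False)]
            hits = enriched_motifs(sample, ref, n_resamples=300, seed=seed)
            clean += int(len(hits) == 0)
        assert clean >= 18

    def test_short_sequences_without_fallback(self):
        with pytest.warns(UserWarning):
            hits = enriched_motifs(["CASSF", "CATSF", "CASSF"],
                                   ["CAAAF"] * 10, k_set=(4,),
                                   whole_string_fallback=False,
                                   n_resamples=50, seed=0)
        assert hits == []


class TestGlobalPairs:
    def test_hamming_one_paired(self):
        pairs = global_similarity_pairs(["CASSLVNTEAFF", "CASSLANTEAFF"])
        assert pairs == [("CASSLANTEAFF", "CASSLVNTEAFF")]

    def test_different_lengths_never_paired(self):
        assert global_similarity_pairs(["CASSF", "CASSFF"]) == []

    def test_hamming_two_not_paired(self):
        assert global_similarity_pairs(["CASSAA", "CATTAA"]) == []


class TestBuildClusters:
    def test_shared_motif_forces_one_cluster(self):
        members = [("p1", "CASSWQPDAAAFF"), ("p2", "CASTWQPDCCCFF"),
                   ("p3", "CADKWQPDEEEFF")]
        hits = [MotifHit("WQPD", 3, np.inf, 0.001)]
        clusters = build_specificity_clusters(members, hits, pairs=[])
        assert len(clusters) == 1
        assert clusters[0].subjects == 3

    def test_disjoint_motifs_two_clusters(self):
        members = [("p1", "CASSWQPDAAAFF"), ("p2", "CASTWQPDCCCFF"),
                   ("p3", "CAAAMKYHEEEFF"), ("p4", "CADDMKYHGGGFF")]
        hits = [MotifHit("WQPD", 2, np.inf, 0.001),
                MotifHit("MKYH", 2, np.inf, 0.001)]
        clusters = build_specificity_clusters(members, hits, pairs=[])
        assert len(clusters) == 2

    def test_planted_41_peptide_cluster_single_component(self):
        # variants of one base connected through the unmutated anchor
        base = "CASSLVNTEAFF"
        rng = np.random.default_rng(13)
        members = [("p0", base)]
        alphabet = [c for c in "ACDEFGHIKLMNPQRSTVWY"]
        while len({pep for _, pep in members}) < 41:
            pos = int(rng.choice([2, 5, 8]))
            sub = str(rng.choice([c for c in alphabet if c != base[pos]]))
            pep = base[:pos] + sub + base[pos + 1:]
            members.append((f"p{len(members)}", pep))
        clusters = build_specificity_clusters(sorted(set(members)), [])
        assert len(clusters) == 1
        assert len(clusters[0].peptides) == 41

    def test_input_order_invariance(self):
        members = [("p1", "CASSWQPDAAAFF"), ("p2", "CASTWQPDCCCFF"),
                   ("p3", "CASSWQPDAAAFF")]
        hits = [MotifHit("WQPD", 2, np.inf, 0.001)]
        c1 = build_specificity_clusters(members, hits)
        c2 = build_specificity_clusters(members[::-1], hits)
        assert [c.cluster_id for c in c1] == [c.cluster_id for c in c2]
        assert [c.members for c in c1] == [c.members for c in c2]


class TestClusterPattern:
    def test_published_style_pattern(self):
        pattern, pfm = cluster_pattern(
            ["CASSLVNTEAFF", "CASSLANTEAFF", "CAISLTNTEAFF"])
        assert pattern.pattern == "CA%SL%NTEAFF"
        assert pfm[2] == {"S": 2, "I": 1}

    def test_singleton(self):
        pattern, _ = cluster_pattern(["CASSF"])
        assert pattern.pattern == "CASSF"

    def test_identical_members(self):
        pattern, _ = cluster_pattern(["CASSF", "CASSF"])
        assert "%" not in pattern.pattern

    def test_member_matches_own_pattern(self):
        seqs = ["CASSLVNTEAFF", "CASSLANTEAFF", "CASSLVNTEGFF"]
        pattern, _ = cluster_pattern(seqs)
        for s in seqs:
            assert all(p == "%" or p == c for p, c in zip(pattern.pattern, s))


def make_cluster(members):
    clusters = build_specificity_clusters(
        members, [MotifHit("XXXX", 0, np.inf, 0.001)],
        pairs=[(a, b) for _, a in members for _, b in members if a < b])
    assert len(clusters) == 1
    return clusters[0]


class TestClusterAssociation:
    def setup_method(self):
        self.labels = {}
        self.dataset = []
        for i in range(50):
            self.labels[f"e{i}"] = "excellent"
            self.dataset.append((f"e{i}", f"CAAAAA{i:03d}F"))
            self.labels[f"p{i}"] = "poor"
            self.dataset.append((f"p{i}", f"CDDDDD{i:03d}F"))

    def test_excellent_cluster_matches_contingency_oracle(self):
        members = [(f"e{i}", f"CAAAAA{i:03d}F") for i in range(5)]
        cluster = make_cluster(members)
        res = cluster_prognosis_association(
            cluster, self.labels, {"excellent"}, self.dataset)
        oracle = sps.chi2_contingency([[5, 0], [45, 50]], correction=False)
        assert res["statistic"] == pytest.approx(oracle.statistic, abs=1e-10)
        assert res["p_value"] == pytest.approx(oracle.pvalue, abs=1e-10)
        assert res["p_value"] < 0.05
        assert res["associated"]
        assert res["direction"] == "group1"

    def test_three_subjects_not_evaluated(self):
        members = [(f"e{i}", f"CAAAAA{i:03d}F") for i in range(3)]
        cluster = make_cluster(members)
        res = cluster_prognosis_association(
            cluster, self.labels, {"excellent"}, self.dataset)
        assert not res["evaluated"]
        assert not res["associated"]

    def test_dataset_proportions_give_p_one(self):
        members = ([(f"e{i}", f"CAAAAA{i:03d}F") for i in range(5)]
                   + [(f"p{i}", f"CDDDDD{i:03d}F") for i in range(5)])
        cluster = make_cluster(members)
        res = cluster_prognosis_association(
            cluster, self.labels, {"excellent"}, self.dataset)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-9)
        assert not res["associated"]

    def test_degenerate_margin(self):
        labels = {f"e{i}": "excellent" for i in range(6)}
        dataset = [(f"e{i}", f"CAAAAA{i}F") for i in range(6)]
        cluster = make_cluster(dataset[:4])
        res = cluster_prognosis_association(cluster, labels, {"excellent"},
                                            dataset)
        assert res["degenerate"]
        assert res["p_value"] == 1.0

    def test_strict_exclusivity(self):
        members = ([(f"e{i}", f"CAAAAA{i:03d}F") for i in range(8)]
                   + [("p0", "CDDDDD000F")])
        cluster = make_cluster(members)
        res = cluster_prognosis_association(
            cluster, self.labels, {"excellent"}, self.dataset,
            strict_exclusive=True, opposing_groups={"poor", "worst"})
        assert res["p_value"] < 0.05
        assert not res["associated"]
        assert res.get("exclusivity_violated")


def patristic_matrix(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestNeighborJoining:
    def test_two_identical_sequences(self):
        newick = neighbor_joining_tree(["CASSF", "CATSF"])
        d = patristic_matrix(newick, ["CASSF", "CATSF"])
        assert d[0, 1] == pytest.approx(1 / 5)
        newick_same = neighbor_joining_tree({"a": "CASSF", "b": "CASSF"})
        d2 = patristic_matrix(newick_same, ["a", "b"])
        assert d2[0, 1] == pytest.approx(0.0)

    def test_three_taxa_closed_form(self):
        dm = np.array([[0.0, 2, 3], [2, 0, 4], [3, 4, 0]])
        newick = neighbor_joining_tree({"A": "", "B": "", "C": ""},
                                       distance_matrix=dm)
        d = patristic_matrix(newick, ["A", "B", "C"])
        np.testing.assert_allclose(d, dm, atol=1e-9)

    def test_four_taxon_additive_recovery(self):
        # tree: ((A:2,B:3):1,(C:4,D:5)) -> additive distance matrix
        dm = np.array([
            [0.0, 5, 7, 8],
            [5, 0.0, 8, 9],
            [7, 8, 0.0, 9],
            [8, 9, 9, 0.0]])
        newick = neighbor_joining_tree({"A": "", "B": "", "C": "", "D": ""},
                                       distance_matrix=dm)
        d = patristic_matrix(newick, ["A", "B", "C", "D"])
        np.testing.assert_allclose(d, dm, atol=1e-9)
        # topology check: A and B are siblings
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        pairs = {frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter())
                 for e in tree.edges() if e.head_node.is_internal()}
        assert frozenset({"A", "B"}) in pairs or frozenset({"C", "D"}) in pairs

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            neighbor_joining_tree(["CASSF", "CASSF"])
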