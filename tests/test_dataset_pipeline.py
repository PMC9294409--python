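"""Filters, sequence comparisons, redundancy clustering and typing."""
import numpy as np
import pytest

from ppiface.dataset_pipeline import (PipelineEntry,
                                      RedundancyItem, apply_filters,
                                      classify_interface_type,
                                      cluster_redundancy, interface_similarity,
                                      quality_score, sequence_identity)
from ppiface.interface_analysis import Interface, detect_interface
from ppiface.structure_model import Atom, ComplexPair, Residue
from ppiface.synthetic_complexes import build_peptide


def quartet(chain, seq, center, resname="GLY"):
    c = np.asarray(center, float)
    return Residue(chain, seq, "", resname, [
        Atom("N", "N", c + [0.4, 0.4, 0.4]),
        Atom("CA", "C", c + [-0.4, -0.4, 0.4]),
        Atom("C", "C", c + [0.4, -0.4, -0.4]),
        Atom("O", "O", c + [-0.4, 0.4, -0.4]),
    ])


def facing_pair(pid, n_a, n_b, resname_a="GLY", resname_b="GLY", gap=4.0):
    a = [quartet("A", i + 1, [i * 3.5, 0, 0], resname_a) for i in range(n_a)]
    b = [quartet("B", i + 1, [i * 3.5, gap, 0], resname_b) for i in range(n_b)]
    return ComplexPair(pid, a, b)


def entry(pid, n_a, n_b, bsa, source=None, missing_backbone=False):
    pair = facing_pair(pid, n_a, n_b)
    if missing_backbone:
        r = pair.chain_a[0]
        pair.chain_a[0] = Residue(r.chain_id, r.seq_num, r.icode, r.name, r.atoms[:2])
    iface = detect_interface(pair)
    return PipelineEntry(id=pid, pair=pair, interface=iface, bsa=bsa,
                         source=source or pid)


class TestFilters:
    def test_each_interface_counted_once_under_first_failing_rule(self):
        entries = [
            entry("ok1", 6, 6, 300.0),
            entry("missing", 6, 6, 300.0, missing_backbone=True),
            entry("small", 4, 5, 300.0),        # 20 < 25
            entry("lowbsa", 6, 6, 99.9),
            entry("small_and_low", 4, 4, 50.0),  # fails c before d
        ]
        rep = apply_filters(entries)
        assert rep.removed_missing_interface_atoms == ["missing"]
        assert rep.removed_small_product == ["small", "small_and_low"]
        assert rep.removed_low_bsa == ["lowbsa"]
        assert rep.surviving == ["ok1"]

    def test_boundary_product_of_25_survives(self):
        rep = apply_filters([entry("edge", 5, 5, 150.0)])
        assert rep.surviving == ["edge"]

    def test_overlapping_interfaces_share_a_chain_instance_residue(self):
        e1 = entry("p1", 6, 6, 300.0, source="structX")
        e2 = entry("p2", 6, 6, 300.0, source="structX")   # same chain instances
        e3 = entry("p3", 6, 6, 300.0, source="structY")
        rep = apply_filters([e1, e2, e3])
        assert set(rep.removed_overlapping) == {"p1", "p2"}
        assert rep.surviving == ["p3"]

    def test_counts_always_sum_to_input_count(self):
        rng = np.random.default_rng(0)
        entries = []
        for i in range(20):
            na, nb = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            entries.append(entry(f"e{i}", na, nb, float(rng.uniform(50, 400))))
        rep = apply_filters(entries)
        c = rep.counts()
        assert (c["missing_interface_atoms"] + c["overlapping"] + c["small_product"]
                + c["low_bsa"] + c["surviving"]) == c["input"]


class TestSequenceIdentity:
    def test_identical_sequences_are_100pct(self):
        assert sequence_identity("MKTAYIAK", "MKTAYIAK") == pytest.approx(100.0)

    def test_single_mismatch_in_four(self):
        assert sequence_identity("AAAA", "AAAT") == pytest.approx(75.0)

    def test_two_substitutions_in_fifty(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        s = "".join(rng.choice(aas) for _ in range(50))
        t = list(s)
        t[10] = "W" if s[10] != "W" else "Y"
        t[30] = "C" if s[30] != "C" else "M"
        assert sequence_identity(s, "".join(t)) == pytest.approx(96.0)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            sequence_identity("", "AAAA")


class TestInterfaceSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ABCD", "ABCD", 1.0),
        ("ABCD", "ABXD", 0.75),   # blocks "AB","D": M=3, 2*3/8
        ("A", "B", 0.0),
        ("", "", 1.0),
    ])
    def test_ratcliff_obershelp_ratio(self, a, b, expected):
        assert interface_similarity(a, b) == pytest.approx(expected)


def make_item(iid, seq_a, seq_b, iface_a, iface_b, quality=(1, -2.0, 1.0)):
    return RedundancyItem(id=iid, seq_a=seq_a, seq_b=seq_b,
                          iface_seq_a=iface_a, iface_seq_b=iface_b,
                          quality=quality)


def _random_seq(rng, n=40):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")) for _ in range(n))


class TestRedundancyClustering:
    def test_duplicates_collapse_to_one_representative(self):
        a = make_item("x1", "MKTAYIAKQR" * 4, "GSHMLEDPVR" * 4, "KTAYI", "SHMLE",
                      quality=(1, -1.5, 1.0))
        b = make_item("x2", a.seq_a, a.seq_b, a.iface_seq_a, a.iface_seq_b,
                      quality=(1, -2.5, 1.0))
        clusters = cluster_redundancy([a, b])
        assert len(clusters) == 1
        assert clusters[0].representative == "x1"   # better resolution wins

    def test_identical_chains_with_disjoint_interfaces_split(self):
        a = make_item("x1", "MKTAYIAKQR" * 4, "MKTAYIAKQR" * 4, "MKTAY", "MKTAY")
        b = make_item("x2", a.seq_a, a.seq_b, "QRQRQ", "QRQRQ")
        assert len(cluster_redundancy([a, b])) == 2

    def _ten_complex_fixture(self):
        rng = np.random.default_rng(42)
        items = []
        # three duplicate groups of two
        for g in range(3):
            sa, sb = _random_seq(rng), _random_seq(rng)
            ia, ib = sa[5:12], sb[5:12]
            for k in range(2):
                items.append(make_item(f"dup{g}_{k}", sa, sb, ia, ib,
                                       quality=(1, -1.0 - 0.1 * k, 1.0)))
        # four unique complexes
        for u in range(4):
            sa, sb = _random_seq(rng), _random_seq(rng)
            items.append(make_item(f"uniq{u}", sa, sb, sa[3:9], sb[3:9]))
        return items

    def test_ten_complexes_with_three_duplicate_groups_give_seven_clusters(self):
        clusters = cluster_redundancy(self._ten_complex_fixture())
        assert len(clusters) == 7

    def test_clustering_is_invariant_to_input_order(self):
        items = self._ten_complex_fixture()
        baseline = cluster_redundancy(items)
        base = sorted((frozenset(c.members), c.representative) for c in baseline)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(items)
            rng.shuffle(perm)
            got = cluster_redundancy(perm)
            assert sorted((frozenset(c.members), c.representative)
                          for c in got) == base

    def test_swapped_chain_pairing_still_matches(self):
        a = make_item("x1", "MKTAYIAKQR" * 4, "GSHMLEDPVR" * 4, "KTAYI", "SHMLE")
        b = make_item("x2", a.seq_b, a.seq_a, a.iface_seq_b, a.iface_seq_a)
        assert len(cluster_redundancy([a, b])) == 1


class TestQualityScore:
    def test_xray_preferred_then_resolution_then_completeness(self):
        hi = facing_pair("hi", 5, 5)
        hi.method, hi.resolution = "X-RAY DIFFRACTION", 1.5
        lo = facing_pair("lo", 5, 5)
        lo.method, lo.resolution = "X-RAY DIFFRACTION", 2.5
        nmr = facing_pair("n", 5, 5)
        nmr.method, nmr.resolution = "SOLUTION NMR", None
        assert quality_score(hi) > quality_score(lo) > quality_score(nmr)


class TestInterfaceTyping:
    def test_peptide_with_enzyme_partner(self):
        helix = build_peptide(12, chain_id="P")
        enzyme = [quartet("E", i + 1, [i * 3.5, 8, 0]) for i in range(200)]
        pair = ComplexPair("t", helix, enzyme)
        iface = Interface(pair=pair, cutoff=5.0, residues_a=[], residues_b=[])
        label = classify_interface_type(pair, iface, enzyme_flags={"E": True})
        assert label.label == "enzyme_peptide"

    def test_peptide_without_annotation_warns_protein_peptide(self):
        helix = build_peptide(12, chain_id="P")
        other = [quartet("Q", i + 1, [i * 3.5, 8, 0]) for i in range(120)]
        pair = ComplexPair("t", helix, other)
        iface = Interface(pair=pair, cutoff=5.0, residues_a=[], residues_b=[])
        with pytest.warns(UserWarning):
            label = classify_interface_type(pair, iface, enzyme_flags={})
        assert label.label == "protein_peptide"

    def _identical_pair(self, n=40):
        a = [quartet("A", i + 1, [i * 3.5, 0, 0]) for i in range(n)]
        b = [quartet("B", i + 1, [i * 3.5, 4.0, 0]) for i in range(n)]
        return ComplexPair("t", a, b)

    def test_identical_chains_same_interface_positions_are_symmetric(self):
        pair = self._identical_pair()
        iface = Interface(pair=pair, cutoff=5.0,
                          residues_a=pair.chain_a[:10], residues_b=pair.chain_b[:10])
        label = classify_interface_type(pair, iface)
        assert label.label == "identical_symmetric"
        assert label.symmetric_overlap == pytest.approx(1.0)

    def test_identical_chains_disjoint_interfaces_are_nonsymmetric(self):
        pair = self._identical_pair()
        iface = Interface(pair=pair, cutoff=5.0,
                          residues_a=pair.chain_a[:10], residues_b=pair.chain_b[-10:])
        label = classify_interface_type(pair, iface)
        assert label.label == "identical_nonsymmetric"
        assert label.symmetric_overlap == pytest.approx(0.0)

    def test_unrelated_long_chains_are_heteropair(self):
        rng = np.random.default_rng(9)
        names = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE"}
        def chain(cid, y):
            return [quartet(cid, i + 1, [i * 3.5, y, 0],
                            rng.choice(list(names.values())))
                    for i in range(40)]
        pair = ComplexPair("t", chain("A", 0.0), chain("B", 4.0))
        iface = Interface(pair=pair, cutoff=5.0,
                          residues_a=pair.chain_a[:10], residues_b=pair.chain_b[:10])
        label = classify_interface_type(pair, iface)
        assert label.label == "heteropair"

    def test_every_interface_gets_exactly_one_of_five_labels(self, homodimer_pair,
                                                             groove_pair):
        labels = set()
        for pair in (homodimer_pair, groove_pair):
            iface = detect_interface(pair)
            labels.add(classify_interface_type(pair, iface).label)
        valid = {"identical_symmetric", "identical_nonsymmetric", "heteropair",
                 "protein_peptide", "enzyme_peptide"}
        assert labels <= valid and len(labels) == 2
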