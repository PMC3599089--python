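import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import metrics_oracle
from voxpocket.evaluation import (
    ConfusionCounts,
    compute_metrics,
    match_member_centers,
    read_truth,
    truth_from_ligand,
    write_truth,
)
from voxpocket.structure_io import Atom, Structure


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.mcc) == (1, 1, 1, 1, 1)
        assert m.degenerate == ()

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=5, tn=85, fn=5))
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(85 / 90)
        assert m.accuracy == pytest.approx(0.9)
        assert m.ppv == pytest.approx(0.5)
        assert m.mcc == pytest.approx(4 / 9)

    def test_degenerate_denominators_flagged(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert m.sensitivity == 0.0 and m.ppv == 0.0
        assert m.specificity == 1.0
        assert "sensitivity" in m.degenerate and "ppv" in m.degenerate

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_textbook_oracle_1000_random_tuples(self):
        rng = np.random.default_rng(42)
        for tp, fp, tn, fn in rng.integers(0, 30, size=(1000, 4)):
            if tp + fp + tn + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            ref = metrics_oracle(int(tp), int(fp), int(tn), int(fn))
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "mcc"):
                assert getattr(m, name) == pytest.approx(ref[name], abs=1e-9), name

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), tn=st.integers(0, 50), fn=st.integers(0, 50)
    )
    @settings(max_examples=100)
    def test_mcc_symmetry(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m1 = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        m2 = compute_metrics(ConfusionCounts(tn, fn, tp, fp))  # tp<->tn, fp<->fn
        assert m1.mcc == pytest.approx(m2.mcc, abs=1e-12)


def line_structure(n=10, het=()):
    """n residues spaced 10 A apart along x, one atom each."""
    atoms = tuple(
        Atom("C", np.array([10.0 * i, 0.0, 0.0]), 1.7, "UNK", i + 1, "A", i + 1, name="C")
        for i in range(n)
    )
    hets = tuple(
        Atom("C", np.asarray(p, float), 1.7, "LIG", 900 + i, "A", 900 + i, name="C")
        for i, p in enumerate(het)
    )
    return Structure(atoms=atoms, source_id="line", het_atoms=hets)


class TestMatchMemberCenters:
    def test_top1_match_success(self):
        s = line_structure()
        centers = [np.array([[1.0, 1.0, 0.0]])]  # near residue 1
        ok, counts = match_member_centers(centers, {("A", 1)}, s, k=1, match_distance=4.5)
        assert ok
        assert counts.tp == 1 and counts.fp == 0 and counts.fn == 0 and counts.tn == 9

    def test_no_match(self):
        s = line_structure()
        centers = [np.array([[0.0, 50.0, 0.0]])]
        ok, counts = match_member_centers(centers, {("A", 1)}, s, k=1)
        assert not ok
        assert counts.tp == 0 and counts.fn == 1

    def test_false_positive_residues_counted(self):
        s = line_structure()
        # members stretch over residues 1 and 2; truth is residue 1 only
        centers = [np.array([[0.0, 1.0, 0.0], [10.0, 1.0, 0.0]])]
        ok, counts = match_member_centers(centers, {("A", 1)}, s, k=1)
        assert ok
        assert counts.tp == 1 and counts.fp == 1

    def test_success_monotone_in_k(self):
        s = line_structure()
        centers = [np.array([[0.0, 50.0, 0.0]]), np.array([[0.0, 1.0, 0.0]])]
        flags = [match_member_centers(centers, {("A", 1)}, s, k=k)[0] for k in (1, 2, 3)]
        assert flags == sorted(flags)  # False <= True ordering

    def test_only_matching_regions_contribute_positives(self):
        s = line_structure()
        centers = [
            np.array([[0.0, 1.0, 0.0]]),  # matches truth residue 1
            np.array([[50.0, 1.0, 0.0]]),  # near residue 6 but matches nothing in truth
        ]
        ok, counts = match_member_centers(centers, {("A", 1)}, s, k=2)
        assert ok
        assert counts.fp == 0  # region 2 matched nothing, so residue 6 is not predicted

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError):
            match_member_centers([np.zeros((1, 3))], set(), line_structure())

    def test_unknown_truth_residue_errors(self):
        with pytest.raises(ValueError):
            match_member_centers([np.zeros((1, 3))], {("Z", 99)}, line_structure())


class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth({("A", 3), ("B", 7)}, path)
        assert read_truth(path) == {("A", 3), ("B", 7)}

    def test_comments_and_blank_lines(self, tmp_path):
        path = tmp_path / "truth.tsv"
        path.write_text("# comment\n\nA 3\nB\t7  # trailing\n")
        assert read_truth(path) == {("A", 3), ("B", 7)}

    def test_malformed_errors(self, tmp_path):
        path = tmp_path / "truth.tsv"
        path.write_text("A\n")
        with pytest.raises(ValueError):
            read_truth(path)


class TestLigandTruth:
    def test_residues_near_ligand(self):
        s = line_structure(het=[(0.0, 3.0, 0.0)])
        assert truth_from_ligand(s, cutoff=4.5) == {("A", 1)}

    def test_water_excluded(self):
        s = line_structure()
        water = Atom("O", np.array([0.0, 3.0, 0.0]), 1.52, "HOH", 901, "A", 901, name="O")
        s = Structure(atoms=s.atoms, source_id="w", het_atoms=(water,))
        with pytest.raises(ValueError):
            truth_from_ligand(s)
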