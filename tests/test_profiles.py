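import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import perturbsig as ps
from perturbsig.profiles import (AlignmentError, ParseError, META_COLUMNS,
                                 modz_aggregate)


def _make_matrix(values, meta_rows, gene_ids=None):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    return ps.ExpressionMatrix(gene_ids=genes, values=values, samples=meta)


def _meta(sid, plate="P1", cell="A", pert="c1", ptype="compound",
          dose=10.0, time=24.0):
    return (sid, plate, cell, pert, ptype, dose, time)


# ---------------------------------------------------------------- I/O

class TestExpressionTSV:
    def test_toy_parse(self, tmp_path):
        (tmp_path / "x.tsv").write_text(
            "gene_id\ts1\ts2\nga\t1.5\t2\ngb\t0\t-1\ngc\t3\t4\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplate_id\tcell_line\tperturbagen_id\tpert_type"
            "\tdose_um\ttime_h\ns1\tP1\tA\tc1\tcompound\t10\t24\n"
            "s2\tP1\tA\t\tdmso_control\t\t24\n")
        m = ps.read_expression_tsv(tmp_path / "x.tsv", tmp_path / "m.tsv",
                                   allow_any_gene_count=True)
        assert m.values.shape == (2, 3)
        assert m.values.tolist() == [[1.5, 0.0, 3.0], [2.0, -1.0, 4.0]]
        assert np.isnan(m.samples.loc[1, "dose_um"])

    def test_round_trip(self, tmp_path, tiny_dataset):
        matrix, _, _ = tiny_dataset
        ps.write_expression_tsv(matrix, tmp_path / "x.tsv", tmp_path / "m.tsv")
        back = ps.read_expression_tsv(tmp_path / "x.tsv", tmp_path / "m.tsv",
                                      allow_any_gene_count=True)
        assert np.allclose(back.values, matrix.values, atol=1e-6)
        assert back.gene_ids == matrix.gene_ids
        assert back.samples["sample_id"].tolist() == \
            matrix.samples["sample_id"].tolist()
        assert back.samples["pert_type"].tolist() == \
            matrix.samples["pert_type"].tolist()

    def test_extra_metadata_sample_is_alignment_error(self, tmp_path):
        (tmp_path / "x.tsv").write_text("gene_id\ts1\nga\t1\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplate_id\tcell_line\tperturbagen_id\tpert_type"
            "\tdose_um\ttime_h\ns1\tP1\tA\tc1\tcompound\t10\t24\n"
            "s_extra\tP1\tA\tc2\tcompound\t10\t24\n")
        with pytest.raises(AlignmentError, match="s_extra"):
            ps.read_expression_tsv(tmp_path / "x.tsv", tmp_path / "m.tsv",
                                   allow_any_gene_count=True)

    def test_non_numeric_cell_locates_error(self, tmp_path):
        (tmp_path / "x.tsv").write_text(
            "gene_id\ts1\ts2\nga\t1\t2\ngb\toops\t3\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplate_id\tcell_line\tperturbagen_id\tpert_type"
            "\tdose_um\ttime_h\ns1\tP1\tA\tc1\tcompound\t10\t24\n"
            "s2\tP1\tA\tc2\tcompound\t10\t24\n")
        with pytest.raises(ParseError, match="gb.*s1"):
            ps.read_expression_tsv(tmp_path / "x.tsv", tmp_path / "m.tsv",
                                   allow_any_gene_count=True)

    def test_landmark_count_enforced(self, tmp_path):
        (tmp_path / "x.tsv").write_text("gene_id\ts1\nga\t1\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tplate_id\tcell_line\tperturbagen_id\tpert_type"
            "\tdose_um\ttime_h\ns1\tP1\tA\tc1\tcompound\t10\t24\n")
        with pytest.raises(ValueError, match="978"):
            ps.read_expression_tsv(tmp_path / "x.tsv", tmp_path / "m.tsv")


# ---------------------------------------------------------------- filtering

class TestFilterConditions:
    def _five_plus_control(self):
        rows = [_meta("s1", pert="c1", dose=10, time=24),
                _meta("s2", pert="c2", dose=10, time=24),
                _meta("s3", pert="c3", dose=10, time=6),
                _meta("s4", pert="c4", dose=1, time=24),
                _meta("s5", pert="c5", dose=1, time=24),
                _meta("s6", pert="DMSO", ptype="dmso_control",
                      dose=np.nan, time=24)]
        return _make_matrix(np.arange(18).reshape(6, 3), rows)

    def test_canonical_condition_filter(self):
        out = ps.filter_conditions(self._five_plus_control(), 24, 10)
        kept = out.samples["sample_id"].tolist()
        assert kept == ["s1", "s2", "s6"]

    def test_no_match_keeps_controls(self):
        out = ps.filter_conditions(self._five_plus_control(), 48, 10)
        assert out.samples["sample_id"].tolist() == ["s6"]

    def test_all_matching_is_identity(self):
        m = _make_matrix(np.eye(3), [
            _meta("s1"), _meta("s2", pert="c2"),
            _meta("s3", pert="DMSO", ptype="dmso_control", dose=np.nan)])
        out = ps.filter_conditions(m, 24, 10)
        assert np.array_equal(out.values, m.values)


# ---------------------------------------------------------------- pairing

class TestPairWithControls:
    def test_single_control_shared_verbatim(self):
        m = _make_matrix(
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
            [_meta("d1", ptype="dmso_control", pert="DMSO", dose=np.nan),
             _meta("c1", pert="cpdA"), _meta("c2", pert="cpdB")])
        pairs = ps.pair_with_controls(m)
        assert len(pairs) == 2
        assert np.array_equal(pairs[0].x1, [1, 2, 3])
        assert np.array_equal(pairs[1].x1, [1, 2, 3])
        assert np.array_equal(pairs[0].x2, [4, 5, 6])

    def test_identical_replicate_controls(self):
        m = _make_matrix(
            [[1, 2, 3], [1, 2, 3], [9, 9, 9]],
            [_meta("d1", ptype="dmso_control", pert="DMSO", dose=np.nan),
             _meta("d2", ptype="dmso_control", pert="DMSO", dose=np.nan),
             _meta("c1", pert="cpdA")])
        pairs = ps.pair_with_controls(m)
        assert len(pairs) == 1
        assert np.allclose(pairs[0].x1, [1, 2, 3])

    def test_plate_without_control_dropped_with_warning(self, caplog):
        m = _make_matrix([[1, 2, 3]], [_meta("c1", pert="cpdA")])
        with caplog.at_level("WARNING", logger="perturbsig"):
            pairs = ps.pair_with_controls(m)
        assert pairs == []
        assert any("no control" in r.message for r in caplog.records)

    def test_never_pairs_across_plates(self):
        m = _make_matrix(
            [[0, 0, 0], [9, 9, 9], [1, 1, 1], [2, 2, 2]],
            [_meta("d1", plate="P1", ptype="dmso_control", pert="DMSO",
                   dose=np.nan),
             _meta("d2", plate="P2", ptype="dmso_control", pert="DMSO",
                   dose=np.nan),
             _meta("c1", plate="P1", pert="cpdA"),
             _meta("c2", plate="P2", pert="cpdB")])
        pairs = {p.plate_id: p for p in ps.pair_with_controls(m)}
        assert np.array_equal(pairs["P1"].x1, [0, 0, 0])
        assert np.array_equal(pairs["P2"].x1, [9, 9, 9])


# ---------------------------------------------------------------- MODZ

class TestModz:
    def test_identity_on_single_vector(self):
        assert np.array_equal(modz_aggregate([[1, 2, 3]]), [1, 2, 3])

    def test_two_replicates_mean(self):
        assert np.allclose(modz_aggregate([[0, 0, 4], [2, 2, 0]]), [1, 1, 2])

    def test_three_identical_vectors(self):
        v = np.array([3.0, 1.0, 2.0, 5.0])
        assert np.allclose(modz_aggregate([v, v, v]), v)

    def test_hand_computed_weights_k3(self):
        # Spearman(r1,r2) = 0.8; Spearman(r1,r3) = -1 -> floor 0.01;
        # Spearman(r2,r3) = -0.8 -> floor 0.01
        r1 = np.array([1.0, 2.0, 3.0, 4.0])
        r2 = np.array([1.0, 2.0, 4.0, 3.0])
        r3 = np.array([4.0, 3.0, 2.0, 1.0])
        w = np.array([0.81, 0.81, 0.02])
        w = w / w.sum()
        expected = w[0] * r1 + w[1] * r2 + w[2] * r3
        assert np.allclose(modz_aggregate([r1, r2, r3]), expected)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            modz_aggregate([[1, 2], [1, 2, 3]])
        with pytest.raises(ValueError):
            modz_aggregate([])

    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(5)
        reps = [rng.standard_normal(12) for _ in range(4)]
        base = modz_aggregate(reps)
        assert np.allclose(modz_aggregate([reps[i] for i in perm]), base)


# ---------------------------------------------------------------- collapse

class TestCollapseRepeats:
    def _pair(self, cmpd, cell, x1, x2):
        return ps.PairedSample(x1=x1, x2=x2, compound_id=cmpd,
                               cell_line=cell, plate_id="P1")

    def test_one_pair_per_compound_cell(self):
        rng = np.random.default_rng(0)
        pairs = [self._pair("a", "A", rng.random(5), rng.random(5))
                 for _ in range(3)]
        out = ps.collapse_repeats(pairs)
        assert len(out) == 1
        assert out[0].plate_id == "aggregated"

    def test_shared_x2_is_preserved(self):
        x2 = np.array([1.0, 2.0, 3.0])
        pairs = [self._pair("a", "A", np.array([0.0, 0.0, 1.0]), x2),
                 self._pair("a", "A", np.array([1.0, 0.5, 0.0]), x2)]
        out = ps.collapse_repeats(pairs)
        assert np.allclose(out[0].x2, x2)

    def test_order_stable_by_compound(self):
        rng = np.random.default_rng(1)
        pairs = []
        for cmpd in ("b", "a"):
            pairs += [self._pair(cmpd, "A", rng.random(4), rng.random(4))
                      for _ in range(2)]
        out = ps.collapse_repeats(pairs)
        assert [p.compound_id for p in out] == ["a", "b"]


# ---------------------------------------------------------------- splits

class TestSplitDataset:
    def _pairs(self, n_compounds, n_cells=2):
        rng = np.random.default_rng(2)
        return [ps.PairedSample(x1=rng.random(4), x2=rng.random(4),
                                compound_id=f"c{i:04d}", cell_line=f"L{j}")
                for i in range(n_compounds) for j in range(n_cells)]

    def test_seeded_determinism(self):
        pairs = self._pairs(10)
        s1 = ps.split_dataset(pairs, "chemical_blind", (0.8, 0.0, 0.2), 7)
        s2 = ps.split_dataset(pairs, "chemical_blind", (0.8, 0.0, 0.2), 7)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids

    def test_chemical_blind_disjoint_and_covering(self):
        pairs = self._pairs(25)
        s = ps.split_dataset(pairs, "chemical_blind", (0.6, 0.2, 0.2), 3)
        all_ids = {p.compound_id for p in pairs}
        assert s.train_ids | s.val_ids | s.test_ids == all_ids
        assert not (s.train_ids & s.test_ids)
        train, val, test = ps.apply_split(pairs, s)
        assert {p.compound_id for p in train}.isdisjoint(
            {p.compound_id for p in test})

    def test_partition_sizes_floor_rule(self):
        pairs = self._pairs(1000, n_cells=1)
        s = ps.split_dataset(pairs, "chemical_blind", (0.8, 0.1, 0.1), 0)
        assert len(s.test_ids) == 100
        assert len(s.val_ids) == 100
        assert len(s.train_ids) == 800

    def test_cell_blind_partitions_cells(self):
        pairs = self._pairs(10, n_cells=4)
        s = ps.split_dataset(pairs, "cell_blind", (0.5, 0.25, 0.25), 1)
        assert len(s.train_ids | s.val_ids | s.test_ids) == 4

    def test_too_few_ids_raises(self):
        pairs = self._pairs(2, n_cells=1)
        with pytest.raises(ValueError):
            ps.split_dataset(pairs, "chemical_blind", (0.4, 0.3, 0.3), 0)
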