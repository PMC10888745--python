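"""Fold changes, DEG selection and the cross-cell Venn partition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigconn.differential import DEGSet, contrast, overlap_degs, select_degs
from sigconn.errors import ParameterError, ValidationError
from sigconn.io import CONTROL, TREATED
from sigconn.synthetic import SyntheticSpec, gen_expression

from conftest import make_expression


def _noisy(base_ctrl, base_trt, rng=None, sd=1e-6, reps=3):
    """Rows of replicates with symmetric jitter, so each group's mean is
    exactly the requested value but its variance is nonzero."""
    assert reps == 3
    c = np.atleast_1d(base_ctrl).astype(float)[:, None]
    t = np.atleast_1d(base_trt).astype(float)[:, None]
    offsets = np.array([-sd, 0.0, sd])
    return np.hstack([c * (1 + offsets), t * (1 + offsets)])


class TestContrast:
    def test_fold_change_arithmetic(self):
        rng = np.random.default_rng(0)
        mat = make_expression(_noisy([10.0], [30.0], rng))
        row = contrast(mat).table.iloc[0]
        assert row["fc"] == pytest.approx(3.0, rel=1e-4)
        assert row["signed_fc"] == pytest.approx(3.0, rel=1e-4)
        assert row["log2fc"] == pytest.approx(np.log2(3.0), rel=1e-4)

    def test_sign_convention_for_downregulation(self):
        rng = np.random.default_rng(1)
        mat = make_expression(_noisy([10.0], [5.0], rng))
        row = contrast(mat).table.iloc[0]
        assert row["signed_fc"] == pytest.approx(-2.0, rel=1e-4)
        assert row["log2fc"] < 0

    def test_identical_groups_give_zero_lfc_and_p_one(self):
        mat = make_expression(np.full((2, 6), 7.0))
        tab = contrast(mat).table
        assert (tab["log2fc"] == 0).all()
        assert (tab["p_value"] == 1.0).all()

    def test_signed_fc_magnitude_at_least_one(self):
        rng = np.random.default_rng(2)
        mat = make_expression(rng.lognormal(3, 1, size=(50, 6)))
        tab = contrast(mat).usable
        assert (tab["signed_fc"].abs() >= 1.0).all()
        assert (np.sign(tab["signed_fc"]) == np.where(tab["log2fc"] >= 0, 1, -1)).all()

    def test_single_replicate_rejected(self):
        mat = make_expression(np.ones((2, 3)), n_ctrl=1)
        with pytest.raises(ValidationError, match="2 replicates"):
            contrast(mat)

    def test_nonpositive_gene_flagged_and_excluded(self):
        rng = np.random.default_rng(3)
        vals = _noisy([10.0, 10.0], [20.0, 20.0], rng)
        vals[1, 0] = 0.0
        mat = make_expression(vals)
        ct = contrast(mat)
        assert not ct.table.iloc[1]["ok"]
        assert ct.table.iloc[1]["flag"] == "nonpositive_intensity"
        assert len(ct.usable) == 1

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(3, 1, size=(30, 6))
        mat = make_expression(vals)
        swapped = make_expression(np.hstack([vals[:, 3:], vals[:, :3]]))
        a = contrast(mat).table
        b = contrast(swapped).table
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], rtol=1e-10)
        np.testing.assert_allclose(
            a["signed_fc"], -np.sign(b["signed_fc"]) * np.abs(b["signed_fc"]), rtol=1e-10
        )
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-8)

    def test_student_flag_changes_test(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 1, size=(20, 8))
        mat = make_expression(vals, n_ctrl=4)
        welch = contrast(mat, equal_var=False).table["p_value"]
        student = contrast(mat, equal_var=True).table["p_value"]
        assert not np.allclose(welch, student)


class TestSelectDegs:
    @pytest.fixture
    def ct(self):
        rng = np.random.default_rng(6)
        # gene 0: strong up; gene 1: strong down; gene 2: null
        return contrast(make_expression(_noisy([10, 20, 15], [16, 10, 15], rng)))

    def test_cutoff_definition(self, ct):
        degs = select_degs(ct)
        assert degs.up == ["G001"] and degs.down == ["G002"]

    def test_inclusive_fc_cutoff(self, ct):
        degs = select_degs(ct, fc_cutoff=1.6)
        assert "G001" in degs.up  # signed_fc == 1.6 passes FC >= cutoff

    def test_p_cutoff_is_strict(self, ct):
        assert select_degs(ct, p_cutoff=1e-300).up == []

    def test_fc_cutoff_below_one_rejected(self, ct):
        with pytest.raises(ParameterError, match=">= 1"):
            select_degs(ct, fc_cutoff=0.5)

    def test_planted_recovery_near_noiseless(self):
        spec = SyntheticSpec(seed=7, noise_sd=0.0)
        mat, up, down = gen_expression(spec, "A549")
        degs = select_degs(contrast(mat))
        assert sorted(degs.up) == up
        assert sorted(degs.down) == down

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(8)
        ct = contrast(make_expression(rng.lognormal(3, 0.5, size=(200, 6))))
        loose = select_degs(ct, fc_cutoff=1.1, p_cutoff=0.2)
        tight = select_degs(ct, fc_cutoff=1.5, p_cutoff=0.05)
        assert set(tight.up) <= set(loose.up)
        assert set(tight.down) <= set(loose.down)

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValidationError):
            DEGSet("A549", up=["G1"], down=["G1"])


class TestOverlap:
    def test_pairwise_shared_genes(self):
        # two genes shared by exactly two cell lines, none by all three
        sets = [
            DEGSet("A549", up=[], down=["POGZ", "TRAT1", "X"]),
            DEGSet("MCF7", up=[], down=["POGZ", "TRAT1", "Y"]),
            DEGSet("PC3", up=[], down=["Z"]),
        ]
        regions = overlap_degs(sets, "down")
        assert regions["A549&MCF7"] == ["POGZ", "TRAT1"]
        assert regions["A549&MCF7&PC3"] == []

    def test_identical_sets_all_in_full_region(self):
        sets = [DEGSet(c, up=["G1", "G2"], down=[]) for c in ("A", "B", "C")]
        regions = overlap_degs(sets, "up")
        assert regions["A&B&C"] == ["G1", "G2"]
        assert all(not v for k, v in regions.items() if k != "A&B&C")

    def test_disjoint_sets_only_singletons(self):
        sets = [DEGSet("A", up=["G1"], down=[]), DEGSet("B", up=["G2"], down=[])]
        regions = overlap_degs(sets, "up")
        assert regions == {"A": ["G1"], "B": ["G2"], "A&B": []}

    def test_duplicate_labels_rejected(self):
        sets = [DEGSet("A", up=["G1"], down=[]), DEGSet("A", up=["G2"], down=[])]
        with pytest.raises(ValidationError, match="duplicate"):
            overlap_degs(sets, "up")

    @given(
        st.lists(
            st.sets(st.integers(min_value=0, max_value=30), max_size=15),
            min_size=2,
            max_size=5,
        )
    )
    def test_partition_disjoint_and_covering(self, memberships):
        sets = [
            DEGSet(f"C{i}", up=[f"G{g}" for g in sorted(s)], down=[])
            for i, s in enumerate(memberships)
        ]
        regions = overlap_degs(sets, "up")
        all_assigned = [g for genes in regions.values() for g in genes]
        assert len(all_assigned) == len(set(all_assigned))  # disjoint
        assert set(all_assigned) == set().union(*(s.up for s in sets))  # covering
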