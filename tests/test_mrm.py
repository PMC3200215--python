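import numpy as np
import pandas as pd
import pytest
from pyteomics import mass as pmass

from lfqpipe import mrm as M
from lfqpipe.errors import DataValidationError
from lfqpipe.synthetic import load_table_fixtures

PROTON = 1.00728


class TestPrecursorMz:
    def test_glycine_singly_protonated_monoisotopic(self):
        # 57.02146 (G residue) + 18.01056 (water) + 1.00728 (proton)
        assert M.peptide_precursor_mz("G", 1) == pytest.approx(76.0393, abs=1e-3)

    def test_printed_average_mass_precursor(self):
        mz = M.peptide_precursor_mz("ELLQLSKPELPQDGTSTLR", 2, "average")
        assert mz == pytest.approx(1063.7, abs=0.5)

    def test_charge_reduction_identity(self):
        mz1 = M.peptide_precursor_mz("IESQTQEEVR", 1)
        mz2 = M.peptide_precursor_mz("IESQTQEEVR", 2)
        assert mz2 == pytest.approx((mz1 + PROTON) / 2, abs=1e-3)

    def test_unknown_residue_names_position(self):
        with pytest.raises(DataValidationError, match="position 3"):
            M.peptide_precursor_mz("GGXGG", 2)


class TestFragmentMz:
    def test_y8_of_secretogranin_peptide(self):
        assert M.fragment_mz("IESQTQEEVR", "y", 8, 1) == pytest.approx(976.5,
                                                                       abs=0.1)

    def test_y6_of_proenkephalin_peptide(self):
        assert M.fragment_mz("ELLQLSKPELPQDGTSTLR", "y", 6, 1) == pytest.approx(
            634.4, abs=0.1
        )

    def test_complementarity_identity(self):
        seq = "VLEYLNQEK"
        y = M.fragment_mz(seq, "y", len(seq) - 1, 1)
        b = M.fragment_mz(seq, "b", 1, 1)
        neutral = pmass.calculate_mass(sequence=seq)
        assert y + b == pytest.approx(neutral + 2 * PROTON, abs=1e-3)

    def test_index_out_of_range(self):
        with pytest.raises(DataValidationError):
            M.fragment_mz("PEPTIDE", "y", 7, 1)

    def test_unsupported_series(self):
        with pytest.raises(Exception):
            M.fragment_mz("PEPTIDE", "x", 2, 1)


class TestCollisionEnergy:
    def test_doubly_charged_formula(self):
        assert M.collision_energy(610.1, 2) == pytest.approx(38.505)

    def test_triply_charged_formula(self):
        assert M.collision_energy(790.9, 3) == pytest.approx(42.80, abs=5e-3)

    def test_unsupported_charge(self):
        with pytest.raises(DataValidationError):
            M.collision_energy(500.0, 1)

    def test_strictly_increasing_in_mz(self):
        grid = np.linspace(300, 1500, 40)
        for z in (2, 3):
            ce = [M.collision_energy(x, z) for x in grid]
            assert (np.diff(ce) > 0).all()


@pytest.fixture(scope="module")
def transitions():
    return load_table_fixtures().transitions


class TestAgainstPrintedAssay:
    """Every printed transition must be reproducible from first principles."""

    def test_product_mz_within_tolerance(self, transitions):
        rows = transitions.dropna(subset=["product_mz"])
        assert len(rows) == 16
        for row in rows.itertuples():
            mz = M.fragment_mz(
                row.peptide,
                row.product_series,
                int(row.product_index),
                int(row.product_charge),
                "monoisotopic",
                bool(row.cys_ethanolyl),
            )
            assert mz == pytest.approx(row.product_mz, abs=0.2), row.peptide

    def test_precursor_mz_average_mode(self, transitions):
        rows = transitions.dropna(subset=["precursor_mz"])
        for row in rows.itertuples():
            mz = M.peptide_precursor_mz(
                row.peptide, int(row.precursor_charge), "average",
                bool(row.cys_ethanolyl),
            )
            assert mz == pytest.approx(row.precursor_mz, abs=0.7), row.peptide

    def test_ce_follows_charge_specific_formula(self, transitions):
        rows = transitions.dropna(subset=["precursor_mz"])
        for row in rows.itertuples():
            z = int(row.precursor_charge)
            slope = 0.05 if z == 2 else 0.044
            expected = slope * row.precursor_mz + 8.0
            assert M.collision_energy(row.precursor_mz, z) == pytest.approx(expected)


class TestBuildTransitionList:
    def test_proenkephalin_three_products(self):
        targets = [
            {
                "protein": "P01210",
                "peptide": "ELLQLSKPELPQDGTSTLR",
                "charge": 2,
                "products": [("y", 6, 1), ("y", 9, 1), ("y", 12, 1)],
            }
        ]
        transitions = M.build_transition_list(targets)
        assert len(transitions) == 3
        assert all(t.declustering_potential == 100.0 for t in transitions)
        assert all(20.0 <= t.dwell_ms <= 30.0 for t in transitions)

    def test_empty_products_warns(self):
        with pytest.warns(UserWarning):
            out = M.build_transition_list(
                [{"protein": "P", "peptide": "PEPTIDEK", "charge": 2,
                  "products": []}]
            )
        assert out == []

    def test_fixture_targets_expand_to_printed_count(self):
        fx = load_table_fixtures()
        targets = M.targets_from_fixture(fx.transitions)
        # the failed peptide is excluded; four proteins remain
        assert len({t["protein"] for t in targets}) == 4
        transitions = M.build_transition_list(targets)
        assert len(transitions) == 16

    def test_parse_product_label(self):
        assert M.parse_product_label("y6") == ("y", 6, 1)
        assert M.parse_product_label("y8^2+") == ("y", 8, 2)
        with pytest.raises(DataValidationError):
            M.parse_product_label("z4")


def chromatogram_frame(aucs):
    """aucs: list of (protein, peptide, transition, sample, group, auc)."""
    return pd.DataFrame(
        aucs, columns=["protein", "peptide", "transition", "sample", "group",
                       "auc"]
    )


class TestQuantifyMrm:
    def test_single_transition_twofold_change(self):
        rows = []
        for s, g, a in (("a1", "AT", 8.0), ("a2", "AT", 8.0),
                        ("c1", "control", 4.0), ("c2", "control", 4.0)):
            rows.append(("P", "PEP", "y6", s, g, a))
        out = M.quantify_mrm(chromatogram_frame(rows))
        assert out.loc["P", "fold_change"] == pytest.approx(2.0)

    def test_peptide_fold_changes_averaged_on_signed_scale(self):
        rows = []
        # peptide 1: ratio 1.5; peptide 2: ratio 1.58
        for pep, ratio in (("pepA", 1.5), ("pepB", 1.58)):
            for s, g in (("a1", "AT"), ("a2", "AT")):
                rows.append(("P", pep, "y1", s, g, 100.0 * ratio))
            for s, g in (("c1", "control"), ("c2", "control")):
                rows.append(("P", pep, "y1", s, g, 100.0))
        out = M.quantify_mrm(chromatogram_frame(rows))
        assert out.loc["P", "fold_change"] == pytest.approx(1.54, abs=1e-9)

    def test_all_equal_aucs_give_unity_and_p_one(self):
        rows = [("P", "PEP", "y6", s, g, 10.0)
                for s, g in (("a1", "AT"), ("a2", "AT"),
                             ("c1", "control"), ("c2", "control"))]
        out = M.quantify_mrm(chromatogram_frame(rows))
        assert out.loc["P", "fold_change"] == pytest.approx(1.0)
        assert out.loc["P", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_undetected_protein_reported_not_raised(self):
        rows = [("GOOD", "PEP", "y6", "a1", "AT", 10.0),
                ("GOOD", "PEP", "y6", "c1", "control", 5.0),
                ("ALCAM_LIKE", "PEP2", "y6", "a1", "AT", np.nan)]
        out = M.quantify_mrm(chromatogram_frame(rows))
        assert not out.loc["ALCAM_LIKE", "detected"]
        assert out.loc["GOOD", "detected"]

    def test_known_ratio_recovered_unbiasedly(self):
        rng = np.random.default_rng(6)
        true_log2 = 1.2
        ests = []
        for trial in range(30):
            rows = []
            for s in range(4):
                noise = rng.normal(0, 0.05)
                rows.append(("P", "PEP", "y1", f"a{s}", "AT",
                             2.0 ** (10 + true_log2 + noise)))
            for s in range(4):
                noise = rng.normal(0, 0.05)
                rows.append(("P", "PEP", "y1", f"c{s}", "control",
                             2.0 ** (10 + noise)))
            out = M.quantify_mrm(chromatogram_frame(rows))
            ests.append(np.log2(out.loc["P", "fold_change"]))
        err = np.mean(ests) - true_log2
        assert abs(err) < 3 * np.std(ests) / np.sqrt(len(ests)) + 1e-3
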