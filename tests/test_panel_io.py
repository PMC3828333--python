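"""Panel I/O: censor parsing, resolution, unit conversion, round-trips."""

import numpy as np
import pandas as pd
import pytest

from cytostrat.panel_io import (
    FLAG_BELOW,
    FLAG_NONE,
    FLAG_ZERO,
    AnalyteCatalog,
    AssayMatrix,
    ClinicalTable,
    PanelDataError,
    from_molar,
    global_nonzero_min,
    load_cohort,
    log10_view,
    read_assay_tsv,
    resolve_censored,
    to_molar,
    write_assay_tsv,
)


def make_matrix(values, flags=None, analytes=("A1", "A2"), timepoint="baseline"):
    values = np.atleast_2d(np.asarray(values, float))
    patients = [f"P{i}" for i in range(values.shape[0])]
    if flags is None:
        flags = np.where(values == 0, FLAG_ZERO, FLAG_NONE)
    return AssayMatrix(
        pd.DataFrame(values, index=patients, columns=list(analytes)),
        pd.DataFrame(np.atleast_2d(flags), index=patients, columns=list(analytes)),
        timepoint,
    )


def catalog_of(mw_by_id):
    return AnalyteCatalog(
        pd.DataFrame(
            {
                "current_name": list(mw_by_id),
                "historical_name": list(mw_by_id),
                "mw_daltons": list(mw_by_id.values()),
                "class_label": "interleukin",
            },
            index=pd.Index(list(mw_by_id), name="analyte_id"),
        )
    )


class TestReadWrite:
    def test_long_tsv_round_trip_with_censor_flags(self, tmp_path):
        rows = [
            ("P1", "A1", "baseline", "1.5"),
            ("P1", "A2", "baseline", "<2.55"),
            ("P2", "A1", "baseline", ">100"),
            ("P2", "A2", "baseline", "0"),
            ("P3", "A1", "baseline", "3.3"),
            ("P3", "A2", "baseline", "7"),
        ]
        path = tmp_path / "assay.tsv"
        pd.DataFrame(rows, columns=["patient_id", "analyte_id", "timepoint", "value"]).to_csv(
            path, sep="\t", index=False
        )
        m = read_assay_tsv(path)["baseline"]
        assert m.shape == (3, 2)
        # a "<2.55" cell keeps the limit as its working value
        assert m.values.at["P1", "A2"] == 2.55
        assert m.flags.at["P1", "A2"] == FLAG_BELOW
        assert m.flags.at["P2", "A2"] == FLAG_ZERO

        out = tmp_path / "roundtrip.tsv"
        write_assay_tsv(m, out)
        m2 = read_assay_tsv(out)["baseline"]
        pd.testing.assert_frame_equal(m.values, m2.values)
        pd.testing.assert_frame_equal(m.flags, m2.flags)

    def test_duplicate_patient_analyte_is_hard_error(self, tmp_path):
        rows = [
            ("P1", "A1", "baseline", "1"),
            ("P1", "A1", "baseline", "2"),
        ]
        path = tmp_path / "assay.tsv"
        pd.DataFrame(rows, columns=["patient_id", "analyte_id", "timepoint", "value"]).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(PanelDataError, match="duplicate"):
            read_assay_tsv(path)

    def test_non_numeric_value_names_coordinates(self, tmp_path):
        path = tmp_path / "assay.tsv"
        pd.DataFrame(
            [("P1", "A1", "baseline", "oops")],
            columns=["patient_id", "analyte_id", "timepoint", "value"],
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(PanelDataError, match="P1.*A1"):
            read_assay_tsv(path)

    def test_load_cohort_drops_patients_missing_clinical(self, tmp_path, caplog):
        rows = [
            (p, a, "baseline", "1.0")
            for p in ("P1", "P2", "P3")
            for a in ("IL2", "IL6")
        ]
        assay = tmp_path / "assay.tsv"
        pd.DataFrame(rows, columns=["patient_id", "analyte_id", "timepoint", "value"]).to_csv(
            assay, sep="\t", index=False
        )
        clin = tmp_path / "clinical.tsv"
        pd.DataFrame(
            {
                "patient_id": ["P1", "P2"],
                "apache2": [20, 25],
                "survival_time": [90, 10],
                "event": [0, 1],
                "death_day28": [0, 1],
                "death_day90": [0, 1],
            }
        ).to_csv(clin, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            matrices, clinical, catalog = load_cohort(assay, clin)
        assert matrices["baseline"].patient_ids == ["P1", "P2"]
        assert "P3" in caplog.text

    def test_unknown_analyte_is_hard_error(self, tmp_path):
        assay = tmp_path / "assay.tsv"
        pd.DataFrame(
            [("P1", "NOT_AN_ANALYTE", "baseline", "1")],
            columns=["patient_id", "analyte_id", "timepoint", "value"],
        ).to_csv(assay, sep="\t", index=False)
        clin = tmp_path / "clinical.tsv"
        pd.DataFrame(
            {
                "patient_id": ["P1"],
                "apache2": [20],
                "survival_time": [90],
                "event": [0],
                "death_day28": [0],
                "death_day90": [0],
            }
        ).to_csv(clin, sep="\t", index=False)
        with pytest.raises(PanelDataError, match="NOT_AN_ANALYTE"):
            load_cohort(assay, clin)


class TestCensorResolution:
    def test_zero_replaced_by_half_global_minimum(self):
        m = make_matrix([[0.10, 5.0], [0.0, 2.0]])
        r = resolve_censored(m)
        # global nonzero minimum is 0.10 anywhere in the matrix -> fill 0.05
        assert r.values.at["P1", "A1"] == pytest.approx(0.05)
        assert r.flags.at["P1", "A1"] == FLAG_ZERO  # provenance kept

    def test_below_limit_cell_keeps_limit_and_uncensored_unchanged(self):
        m = make_matrix(
            [[2.55, 3.3]], flags=[[FLAG_BELOW, FLAG_NONE]]
        )
        r = resolve_censored(m)
        assert r.values.at["P0", "A1"] == 2.55
        assert r.values.at["P0", "A2"] == 3.3

    def test_idempotent(self):
        m = make_matrix([[0.10, 5.0], [0.0, 2.0]])
        r1 = resolve_censored(m)
        r2 = resolve_censored(r1)
        pd.testing.assert_frame_equal(r1.values, r2.values)

    def test_half_minimum_is_global_over_all_analytes(self):
        # minimum sits in a different analyte column than the zero
        m = make_matrix([[0.0, 50.0], [8.0, 0.4]])
        r = resolve_censored(m)
        assert r.values.at["P0", "A1"] == pytest.approx(0.2)
        # the fill is half the smallest nonzero value over ALL analytes jointly
        detected = m.values.to_numpy()
        assert r.values.at["P0", "A1"] == pytest.approx(
            detected[detected > 0].min() / 2
        )

    def test_all_zero_matrix_raises(self):
        m = make_matrix([[0.0, 0.0]])
        with pytest.raises(PanelDataError, match="minimum"):
            resolve_censored(m)

    def test_joint_minimum_across_timepoints(self):
        base = make_matrix([[0.0, 5.0]])
        late = make_matrix([[0.2, 9.0]], timepoint="24h")
        fill = global_nonzero_min(base, late) / 2.0
        r = resolve_censored(base, zero_fill=fill)
        assert r.values.at["P0", "A1"] == pytest.approx(0.1)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "pgml,mw,expected_pM",
        [(10.0, 10_000.0, 1.0), (1.0, 1_000.0, 1.0), (1.0, 2_000.0, 0.5)],
    )
    def test_pgml_to_pM(self, pgml, mw, expected_pM):
        cat = catalog_of({"A1": mw, "A2": mw})
        m = make_matrix([[pgml, pgml]])
        molar = to_molar(m, cat)
        assert molar.values.at["P0", "A1"] == pytest.approx(expected_pM)

    def test_round_trip_recovers_pgml(self, rng):
        cat = catalog_of({"A1": 15_420.0, "A2": 8_360.0})
        m = make_matrix(rng.uniform(0.01, 100, size=(5, 2)))
        back = from_molar(to_molar(m, cat), cat)
        assert np.allclose(back.to_numpy(), m.values.to_numpy(), rtol=1e-9)

    def test_missing_mw_names_analyte(self):
        cat = catalog_of({"A1": 10_000.0})
        m = make_matrix([[1.0, 1.0]])
        with pytest.raises(PanelDataError, match="A2"):
            to_molar(m, cat)

    def test_unresolved_zero_rejected(self):
        cat = catalog_of({"A1": 10_000.0, "A2": 10_000.0})
        m = make_matrix([[0.0, 1.0]])
        with pytest.raises(PanelDataError, match="resolve_censored"):
            to_molar(m, cat)


class TestLog10View:
    def test_known_values_and_round_trip(self):
        cat = catalog_of({"A1": 1_000.0, "A2": 1_000.0})
        m = make_matrix([[1.0, 100.0]])
        lg = log10_view(to_molar(m, cat))
        assert lg.at["P0", "A1"] == pytest.approx(0.0)
        assert lg.at["P0", "A2"] == pytest.approx(2.0)
        assert np.allclose(10 ** lg.to_numpy(), [[1.0, 100.0]], rtol=1e-12)


class TestDomainInvariants:
    def test_default_catalog_has_39_analytes_with_positive_mw(self):
        cat = AnalyteCatalog.default()
        assert len(cat.analyte_ids) == 39
        assert (cat.table["mw_daltons"] > 0).all()
        assert "IL2" in cat.analyte_ids and "CSF2" in cat.analyte_ids

    def test_clinical_death_flag_consistency_enforced(self):
        df = pd.DataFrame(
            {
                "apache2": [20],
                "survival_time": [50.0],
                "event": [1],
                "death_day28": [1],
                "death_day90": [0],
            },
            index=["P1"],
        )
        with pytest.raises(PanelDataError, match="death_day28"):
            ClinicalTable(df)
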