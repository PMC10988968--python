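import math

import numpy as np
import pytest

from llps_pscreen import (
    ExperimentRecord,
    bin_condition,
    condition_vector,
    encode_label,
    filter_for_behavior_model,
    fit_quantile_bins,
    ionic_strength,
    log_concentration,
    normalize_temperature,
    table1_schemes,
    to_micromolar,
)
from llps_pscreen.preprocess import BinningScheme, UnsupportedSaltError


class TestToMicromolar:
    @pytest.mark.parametrize(
        "value,unit,mw,expected",
        [
            (1, "mM", None, 1000.0),
            (250, "nM", None, 0.25),
            (2, "M", None, 2e6),
            (5, "uM", None, 5.0),
            (1, "mg/mL", 50000.0, 20.0),
        ],
    )
    def test_conversions(self, value, unit, mw, expected):
        assert to_micromolar(value, unit, mw) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            to_micromolar(1, "stone")
        with pytest.raises(ValueError, match="molecular weight"):
            to_micromolar(1, "mg/mL")


@pytest.mark.parametrize("c,expected", [(100, 2.0), (1, 0.0), (0.001, -3.0)])
def test_log_concentration(c, expected):
    assert log_concentration(c) == pytest.approx(expected)


def test_log_concentration_rejects_nonpositive():
    with pytest.raises(ValueError):
        log_concentration(0)


class TestIonicStrength:
    @pytest.mark.parametrize(
        "salts,expected",
        [
            ([("NaCl", 0.15)], 0.15),           # 1/2 (0.15*1 + 0.15*1)
            ([("MgCl2", 0.01)], 0.03),          # 1/2 (0.01*4 + 0.02*1)
            ([("Na2SO4", 0.1)], 0.3),           # 1/2 (0.2*1 + 0.1*4)
            ([], 0.0),
        ],
    )
    def test_hand_values(self, salts, expected):
        assert ionic_strength(salts) == pytest.approx(expected)

    def test_additive_over_disjoint_salt_lists(self, rng):
        salts = [("NaCl", 0.1), ("KCl", 0.05), ("MgCl2", 0.02), ("CaCl2", 0.01)]
        for split in range(1, len(salts)):
            a, b = salts[:split], salts[split:]
            assert ionic_strength(a) + ionic_strength(b) == pytest.approx(
                ionic_strength(salts)
            )

    def test_unsupported_species(self):
        with pytest.raises(UnsupportedSaltError, match="LiBr"):
            ionic_strength([("LiBr", 0.1)])


class TestNormalizeTemperature:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("room temperature", 25.0),
            ("Room Temperature", 25.0),
            ("310.15 K", 37.0),
            ("4", 4.0),
            (4.0, 4.0),
            ("37 C", 37.0),
        ],
    )
    def test_values(self, raw, expected):
        assert normalize_temperature(raw) == pytest.approx(expected)

    def test_kelvin_flagged_by_unit(self):
        assert normalize_temperature(310.15, unit="K") == pytest.approx(37.0)

    def test_unrecognized_token(self):
        with pytest.raises(ValueError, match="unrecognized"):
            normalize_temperature("lukewarm")


def test_encode_label():
    assert encode_label("solute") == 0
    assert encode_label("liquid") == 1
    with pytest.raises(ValueError):
        encode_label("gel")


class TestTable1Binning:
    def test_class_counts(self):
        schemes = table1_schemes()
        assert schemes["pH"].n_classes == 3
        assert schemes["temperature"].n_classes == 3
        assert schemes["ionic_strength"].n_classes == 5
        assert schemes["protein_conc"].n_classes == 5
        assert schemes["rna_conc"].n_classes == 5

    @pytest.mark.parametrize(
        "name,value,expected",
        [
            ("pH", 6.5, 1),
            ("pH", 7.4, 2),
            ("pH", 9.0, 3),
            ("temperature", 25.0, 1),   # shared boundary -> lower class
            ("temperature", 37.0, 3),
            ("ionic_strength", 0.15, 4),
            ("rna_conc", -3.0, 2),
            ("protein_conc", 1.0, 4),
        ],
    )
    def test_worked_assignments(self, name, value, expected):
        assert bin_condition(value, table1_schemes()[name]) == expected

    def test_exhaustive_boundaries(self):
        """Every edge of every scheme obeys the right-closed convention."""
        eps = 1e-9
        for scheme in table1_schemes().values():
            edges = scheme.edges
            assert bin_condition(edges[0], scheme) == 1
            assert bin_condition(edges[-1], scheme) == scheme.n_classes
            for k, boundary in enumerate(edges[1:-1], start=1):
                assert bin_condition(boundary, scheme) == k
                assert bin_condition(boundary - eps, scheme) == k
                assert bin_condition(boundary + eps, scheme) == k + 1

    def test_out_of_range_clamps_to_terminal_classes(self):
        scheme = table1_schemes()["pH"]
        assert bin_condition(-1.0, scheme) == 1
        assert bin_condition(15.0, scheme) == 3

    def test_nan_is_an_error(self):
        with pytest.raises(ValueError, match="NaN"):
            bin_condition(float("nan"), table1_schemes()["pH"])

    def test_monotone_in_value(self, rng):
        for scheme in table1_schemes().values():
            values = np.sort(rng.uniform(scheme.edges[0], scheme.edges[-1], 200))
            classes = [bin_condition(v, scheme) for v in values]
            assert all(a <= b for a, b in zip(classes, classes[1:]))


class TestQuantileBins:
    def test_uniform_ranks(self):
        scheme = fit_quantile_bins(np.arange(1, 101), 5)
        np.testing.assert_allclose(scheme.edges[1:], [20, 40, 60, 80, 100])

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            fit_quantile_bins(np.full(50, 3.0), 5)

    def test_class_occupancy_near_equal_shares(self, rng):
        values = rng.uniform(0, 1, 1000)
        scheme = fit_quantile_bins(values, 5)
        classes = np.array([bin_condition(v, scheme) for v in values])
        counts = np.bincount(classes, minlength=6)[1:]
        assert counts.max() - counts.min() <= 1


def _record(**overrides):
    base = dict(
        record_id="r",
        protein_sequence="MKVQRMKVQR",
        rna_sequence="ACGUACGUAC",
        morphology="liquid",
        protein_conc_value=10.0,
        protein_conc_unit="uM",
        rna_conc_value=1.0,
        rna_conc_unit="uM",
        salts=[("NaCl", 0.15, "M")],
        ph=7.0,
        temperature_raw="room temperature",
    )
    base.update(overrides)
    return ExperimentRecord(**base)


class TestBehaviorFilter:
    def test_reasons(self):
        records = [
            _record(),
            _record(morphology="gel"),
            _record(rna_sequence="ACGUACGU"),
            _record(has_crowder_or_small_molecule=True),
            _record(salts=[("LiBr", 0.1, "M")]),
            _record(protein_conc_value=None, protein_conc_unit=None),
        ]
        kept, excluded = filter_for_behavior_model(records)
        assert [r.record_id for r in kept] == ["r"]
        reasons = [reason for _, reason in excluded]
        assert reasons[0] == "morphology"
        assert "length < 10" in reasons[1]
        assert "crowding" in reasons[2]
        assert "LiBr" in reasons[3]
        assert "protein concentration" in reasons[4]

    def test_idempotent(self, behavior_dataset):
        kept, _ = filter_for_behavior_model(behavior_dataset["records"])
        kept2, excluded2 = filter_for_behavior_model(kept)
        assert kept2 == kept and not excluded2


def test_condition_vector_worked_example():
    cv = condition_vector(_record())
    assert cv.log_protein_conc == pytest.approx(1.0)
    assert cv.log_rna_conc == pytest.approx(0.0)
    assert cv.ionic_strength == pytest.approx(0.15)
    assert cv.ph == 7.0
    assert cv.temperature == 25.0


def test_condition_vector_mg_ml_uses_sequence_weight():
    rec = _record(protein_conc_value=1.0, protein_conc_unit="mg/mL")
    cv = condition_vector(rec)
    # 10-mer MKVQRMKVQR has molar mass ~1245 g/mol -> ~803 uM
    assert 2.5 < cv.log_protein_conc < 3.5


def test_binning_scheme_rejects_unsorted_edges():
    with pytest.raises(ValueError):
        BinningScheme(name="x", edges=[0.0, 2.0, 1.0])
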