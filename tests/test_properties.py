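"""Property calculators: AP binning, logP, charge/pI, descriptors, ingest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from udpep.errors import ConfigError, DomainError, FormatError
from udpep.peptide_space import AMINO_ACIDS, index_to_peptide
from udpep.properties import (
    DESCRIPTOR_KEYS,
    PeptideDescriptorizer,
    ap_from_sasa,
    aromatic_count,
    classify_ap,
    classify_ap_array,
    descriptor_frame,
    descriptor_vector,
    full_space_logp,
    interval_proportions,
    isoelectric_point,
    load_hydrophilicity_scale,
    load_property_table,
    logp,
    net_charge,
)

peptides4 = st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=4)


class TestAp:
    def test_ratio_and_nonaggregating_floor(self):
        assert ap_from_sasa(100.0, 100.0) == 1.0
        assert ap_from_sasa(300.0, 150.0) == 2.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(DomainError):
            ap_from_sasa(100.0, 0.0)

    @pytest.mark.parametrize(
        "ap,cls", [(1.0, 0), (1.49, 0), (1.5, 1), (1.99, 1), (2.0, 2), (2.5, 2)]
    )
    def test_half_open_bins_as_printed(self, ap, cls):
        assert classify_ap(ap) == cls

    def test_below_floor_rejected(self):
        with pytest.raises(DomainError):
            classify_ap(0.9)

    def test_overflow_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert classify_ap(2.8) == 2

    def test_array_path_agrees_with_scalar(self, rng):
        ap = 1.0 + 1.5 * rng.random(200)
        assert np.array_equal(classify_ap_array(ap), [classify_ap(a) for a in ap])


class TestLogp:
    def test_additivity_over_concatenation(self):
        assert logp("GG") + logp("GG") == pytest.approx(logp("GGGG"))

    def test_composition_permutation_invariance(self):
        assert logp("ADGK") == pytest.approx(logp("KGDA"))

    def test_dddd_is_four_times_scale_entry(self):
        scale = load_hydrophilicity_scale()
        assert logp("DDDD") == pytest.approx(4 * scale["D"])
        assert logp("DDDD") == pytest.approx(-14.56)

    def test_full_space_mean_matches_closed_form(self):
        vals = full_space_logp(4)
        scale = load_hydrophilicity_scale()
        closed = 4 * np.mean(list(scale.values()))
        assert vals.size == 160_000
        assert vals.mean() == pytest.approx(closed, abs=1e-9)

    def test_full_space_order_matches_enumeration(self):
        vals = full_space_logp(2)
        assert vals[0] == pytest.approx(logp("AA"))
        assert vals[-1] == pytest.approx(logp("YY"))


class TestChargeAndPi:
    def test_gggg_charge_near_zero_at_ph7(self):
        # termini only: +1/(1+10^(7-8.6)) - 1/(1+10^(3.6-7))
        assert net_charge("GGGG", 7.0) == pytest.approx(-0.024, abs=0.005)

    def test_charge_ordering(self):
        assert net_charge("KKKK", 7.0) > net_charge("GGGG", 7.0) > net_charge("DDDD", 7.0)

    def test_full_protonation_limit(self):
        # pH -> 0: + (basic side chains + N-terminus)
        assert net_charge("KKKK", 0.0) == pytest.approx(5.0, abs=0.02)

    def test_charge_monotone_nonincreasing_in_ph(self, rng):
        for _ in range(20):
            seq = index_to_peptide(int(rng.integers(160000)), 4)
            grid = np.arange(0.0, 14.01, 0.1)
            charges = np.array([net_charge(seq, p) for p in grid])
            assert np.all(np.diff(charges) <= 1e-12)

    def test_gggg_pi_is_terminal_midpoint(self):
        # symmetric two-group case: (3.6 + 8.6) / 2
        assert isoelectric_point("GGGG") == pytest.approx(6.1, abs=0.05)

    def test_pi_root_property(self, rng):
        for _ in range(50):
            seq = index_to_peptide(int(rng.integers(160000)), 4)
            pi = isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 1e-3

    def test_pi_ordering_basic_vs_acidic(self):
        assert isoelectric_point("KKKK") > isoelectric_point("DDDD")

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            net_charge("GGGG", 15.0)


class TestDescriptors:
    def test_aromatic_set_as_printed(self):
        assert aromatic_count("FHWY") == 4
        assert aromatic_count("GGGG") == 0
        assert aromatic_count("WGWG") == 2

    def test_schema_stable_across_peptides(self):
        a = descriptor_vector("GGGG")
        b = descriptor_vector("WKDE")
        assert tuple(a) == tuple(b) == DESCRIPTOR_KEYS

    def test_gggg_values(self):
        d = descriptor_vector("GGGG")
        assert d["aromatic_count"] == 0
        assert d["frac_charged"] == 0.0

    def test_logp_key_single_source_of_truth(self):
        assert descriptor_vector("WKDE")["logp"] == logp("WKDE")

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            descriptor_vector("GGGG", keys=["bogus"])

    @given(peptides4)
    @settings(max_examples=50, deadline=None)
    def test_frame_matches_scalar_path(self, seq):
        row = descriptor_frame([seq]).iloc[0]
        scalar = descriptor_vector(seq)
        for key in DESCRIPTOR_KEYS:
            assert row[key] == pytest.approx(scalar[key], abs=1e-6)

    def test_sklearn_transformer(self):
        tr = PeptideDescriptorizer(keys=["logp", "aromatic_count"])
        M = tr.fit_transform(["GGGG", "WWWW"])
        assert M.shape == (2, 2)
        assert list(tr.get_feature_names_out()) == ["logp", "aromatic_count"]


class TestDiagnosticsAndIngest:
    def test_interval_proportions_thirds(self):
        p = interval_proportions([1.2, 1.7, 2.1], [1.0, 1.5, 2.0, 2.5])
        assert p.fractions == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert p.total == pytest.approx(1.0, abs=1e-12)

    def test_overflow_and_underflow_reported_separately(self):
        p = interval_proportions([0.5, 1.2, 3.0], [1.0, 2.0])
        assert p.underflow == pytest.approx(1 / 3)
        assert p.overflow == pytest.approx(1 / 3)
        assert p.total == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            interval_proportions([], [0, 1])

    def test_property_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"sequence": ["ACDE", "WWWW", "GGGG"], "ap": [1.2, 2.1, 1.0]}
        )
        path = tmp_path / "props.csv"
        df.to_csv(path, index=False)
        table = load_property_table(path)
        assert len(table.records) == 3
        assert table.n_rejected == 0

    def test_invalid_sequence_rejected_and_counted(self, tmp_path):
        df = pd.DataFrame({"sequence": ["ACDE", "AXAA"], "ap": [1.2, 1.3]})
        path = tmp_path / "props.csv"
        df.to_csv(path, index=False)
        table = load_property_table(path)
        assert len(table.records) == 1
        assert table.n_rejected == 1 and table.rejected_rows == (1,)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("seq,ap\nACDE,1.2\n")
        with pytest.raises(FormatError):
            load_property_table(path)

    def test_nonnumeric_property_names_row(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text("sequence,ap\nACDE,oops\n")
        with pytest.raises(FormatError, match="row 0"):
            load_property_table(path)

    def test_duplicates_flagged(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("sequence,ap\nACDE,1.2\nACDE,1.3\n")
        assert load_property_table(path).n_duplicates == 1
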