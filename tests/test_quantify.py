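"""Unit conversions, dilution fluxes, and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import invivokinetics as ivk
from invivokinetics.quantify import (
    ConversionConstants,
    MeasurementRecord,
    SchemaError,
    amount_to_concentration,
    concentration_to_amount,
    concentration_to_protein,
    dilution_flux,
    protein_to_concentration,
    read_records,
    turnover_number,
    write_records,
)


class TestConversions:
    def test_amount_per_gdcw_to_micromolar(self):
        # 1 µmol/gDCW over 6.59e10 cells * 66 fL = 229.9 µM (hand unit analysis)
        assert amount_to_concentration(0.0) == 0.0
        assert amount_to_concentration(1.0) == pytest.approx(229.9, abs=0.05)
        assert amount_to_concentration(0.01) == pytest.approx(2.299, abs=5e-4)

    def test_protein_abundance_to_nanomolar(self):
        # 1 fmol/µg protein * 0.63e6 µg/gDCW over 4.3494e-3 L/gDCW = 144.8 nM
        assert protein_to_concentration(0.0) == 0.0
        assert protein_to_concentration(1.0) == pytest.approx(144.8, abs=0.05)
        assert protein_to_concentration(0.29) == pytest.approx(42.0, abs=0.05)

    @settings(max_examples=50, derandomize=True)
    @given(q=st.floats(1e-9, 1e6))
    def test_round_trips_are_exact(self, q):
        c = ConversionConstants()
        assert concentration_to_amount(amount_to_concentration(q, c), c) == pytest.approx(
            q, rel=1e-12
        )
        assert concentration_to_protein(protein_to_concentration(q, c), c) == pytest.approx(
            q, rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            amount_to_concentration(-1.0)
        with pytest.raises(ValueError):
            protein_to_concentration(-1.0)
        with pytest.raises(ValueError):
            ConversionConstants(cells_per_gdcw=0)


class TestFluxAndTurnover:
    def test_dilution_flux_is_concentration_times_growth(self):
        assert dilution_flux(100, 0.40) == pytest.approx(40.0)
        assert dilution_flux(0, 0.40) == 0.0
        assert dilution_flux(1641, 0.40) == pytest.approx(656.4)

    def test_dilution_flux_inverts_exactly(self):
        assert dilution_flux(123.456, 0.37) / 0.37 == 123.456

    def test_dilution_flux_requires_growth(self):
        with pytest.raises(ValueError):
            dilution_flux(1.0, 0.0)

    def test_turnover_number(self):
        # Vmax 849 µM/h at 42 nM enzyme -> ~5.6 1/s, i.e. 6 to one significant digit
        kcat = turnover_number(849, 0.042)
        assert kcat == pytest.approx(5.615, abs=1e-3)
        assert round(kcat) == 6
        # unit identity: Vmax = 3600*E gives exactly 1/s
        assert turnover_number(3600 * 0.7, 0.7) == pytest.approx(1.0)
        assert turnover_number(309, 0.042) == pytest.approx(2.04, abs=0.005)
        with pytest.raises(ValueError):
            turnover_number(1.0, 0.0)


def _record(strain="S1", rep=1, mu=0.4, s=5.0, p=100.0, s_unit="uM", p_unit="uM", **kw):
    return MeasurementRecord(
        strain_id=strain, replicate=rep, growth_rate=mu,
        substrate_conc=s, substrate_unit=s_unit,
        product_conc=p, product_unit=p_unit, **kw,
    )


class TestBuildDataset:
    def test_preserves_replicates_as_independent_pairs(self):
        records = [
            _record(strain=f"S{i}", rep=r, s=float(i), p=10.0 * i)
            for i in range(1, 9)
            for r in (1, 2, 3)
        ]
        data = ivk.build_dataset(records)
        assert len(data) == 24
        assert data.provenance["n_retained"] == 24

    def test_below_loq_records_dropped_and_logged(self):
        records = [_record(strain="S1"), _record(strain="S2", rep=2, product_below_loq=True)]
        data = ivk.build_dataset(records)
        assert len(data) == 1
        assert data.provenance["dropped_below_loq"] == ["S2/rep2"]

    def test_half_loq_substitution(self):
        records = [_record(), _record(strain="S2", product_below_loq=True), _record(strain="S3")]
        data = ivk.build_dataset(records, loq_policy="half_loq", loq_product=2.0)
        assert len(data) == 3
        assert data.rate[1] == pytest.approx(1.0 * 0.4)  # LOQ/2 * mu

    def test_per_gdcw_units_compose_conversion_and_dilution(self):
        c = ConversionConstants()
        rec = _record(s=0.01, p=0.05, s_unit="umol_per_gDCW", p_unit="umol_per_gDCW")
        data = ivk.build_dataset([rec, _record(s_unit="umol_per_gDCW", p_unit="umol_per_gDCW")], c)
        assert data.substrate[0] == pytest.approx(amount_to_concentration(0.01, c))
        assert data.rate[0] == pytest.approx(
            dilution_flux(amount_to_concentration(0.05, c), 0.4)
        )

    def test_mixed_units_raise_schema_error(self):
        records = [_record(), _record(strain="S2", s_unit="umol_per_gDCW")]
        with pytest.raises(SchemaError, match="mixed unit"):
            ivk.build_dataset(records)


class TestTableIO:
    def test_write_read_round_trip(self, tmp_path):
        records = [
            _record(strain="S1", enzyme_abundance=42.0, enzyme_unit="nM"),
            _record(strain="S2", rep=2, substrate_below_loq=True),
        ]
        path = tmp_path / "panel.csv"
        write_records(records, path)
        back = read_records(path)
        assert len(back) == 2
        assert back[0].enzyme_abundance == 42.0
        assert back[1].substrate_below_loq is True
        assert back[0].strain_id == "S1"

    def test_missing_columns_and_bad_rows_reported(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("strain_id,replicate\nS1,1\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_records(p)
        p2 = tmp_path / "badrow.csv"
        p2.write_text(
            "strain_id,replicate,growth_rate_per_h,substrate,substrate_unit,product,product_unit\n"
            "S1,1,-0.4,1.0,uM,2.0,uM\n"
        )
        with pytest.raises(SchemaError, match="row 2"):
            read_records(p2)
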