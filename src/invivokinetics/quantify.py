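"""Conversion of raw omics measurements to intracellular concentrations and fluxes.

Metabolomics and proteomics report amounts per gram of dry cell weight
(gDCW).  To compare with kinetic models these are converted to intracellular
molar concentrations using a cell count per gDCW and a single cell volume;
protein abundances additionally use the protein mass fraction of dry weight.
Production fluxes follow from the dilution balance at metabolic steady state
during exponential growth: a stable end product accumulating only through
synthesis and removed only by growth satisfies

    flux = [P] * mu

so multiplying a product concentration by the specific growth rate yields its
synthesis flux.  This assumes steady state and no degradation or secretion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConversionConstants",
    "MeasurementRecord",
    "SchemaError",
    "amount_to_concentration",
    "concentration_to_amount",
    "protein_to_concentration",
    "concentration_to_protein",
    "dilution_flux",
    "turnover_number",
    "build_dataset",
    "read_records",
    "write_records",
]

CONC_UNITS = {"uM", "umol_per_gDCW"}
ENZYME_UNITS = {"nM", "fmol_per_ug"}

RECORD_COLUMNS = [
    "strain_id",
    "promoter",
    "crt_e_copies",
    "replicate",
    "growth_rate_per_h",
    "substrate",
    "substrate_unit",
    "product",
    "product_unit",
    "enzyme",
    "enzyme_unit",
    "substrate_below_loq",
    "product_below_loq",
]


class SchemaError(ValueError):
    """Input table does not match the measurement schema."""


@dataclass(frozen=True)
class ConversionConstants:
    """Physical constants linking per-gDCW amounts to molar concentrations.

    Defaults: 6.59e10 cells per gDCW, 66 fL per cell, and a protein content
    of 0.63 g protein per gDCW (yeast grown on ammonium sulfate medium).
    """

    cells_per_gdcw: float = 6.59e10
    cell_volume_fl: float = 66.0
    protein_fraction: float = 0.63

    def __post_init__(self) -> None:
        for name in ("cells_per_gdcw", "cell_volume_fl", "protein_fraction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def litres_per_gdcw(self) -> float:
        """Total cell volume per gram dry weight (L/gDCW)."""
        return self.cells_per_gdcw * self.cell_volume_fl * 1e-15


@dataclass
class MeasurementRecord:
    """One strain x replicate row of raw measurements."""

    strain_id: str
    replicate: int
    growth_rate: float  # 1/h
    substrate_conc: float
    substrate_unit: str
    product_conc: float
    product_unit: str
    promoter: str = ""
    crt_e_copies: int = 0
    enzyme_abundance: Optional[float] = None
    enzyme_unit: Optional[str] = None
    substrate_below_loq: bool = False
    product_below_loq: bool = False

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValueError(f"growth_rate must be > 0, got {self.growth_rate}")
        if self.substrate_conc < 0 or self.product_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.substrate_unit not in CONC_UNITS:
            raise ValueError(f"unknown substrate unit {self.substrate_unit!r}")
        if self.product_unit not in CONC_UNITS:
            raise ValueError(f"unknown product unit {self.product_unit!r}")
        if self.enzyme_abundance is not None and self.enzyme_unit not in ENZYME_UNITS:
            raise ValueError(f"unknown enzyme unit {self.enzyme_unit!r}")


def amount_to_concentration(q: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Convert a metabolite amount in µmol/gDCW to an intracellular µM.

    q µmol/gDCW corresponds to q*1e-6 mol distributed over the total cell
    volume contained in one gDCW.
    """
    if q < 0:
        raise ValueError("amount must be non-negative")
    molar = q * 1e-6 / c.litres_per_gdcw
    return molar * 1e6  # M -> µM


def concentration_to_amount(um: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Inverse of :func:`amount_to_concentration` (µM -> µmol/gDCW)."""
    if um < 0:
        raise ValueError("concentration must be non-negative")
    return um * 1e-6 * c.litres_per_gdcw * 1e6


def protein_to_concentration(x: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Convert an enzyme abundance in fmol/µg protein to an intracellular nM.

    x fmol per µg protein, times 0.63e6 µg protein per gDCW, gives
    x*protein_fraction nmol/gDCW, distributed over the cell volume per gDCW.
    """
    if x < 0:
        raise ValueError("abundance must be non-negative")
    nmol_per_gdcw = x * c.protein_fraction * 1e6 * 1e-6  # fmol/ug * ug/gDCW -> nmol
    return nmol_per_gdcw * 1e-9 / c.litres_per_gdcw * 1e9  # -> nM


def concentration_to_protein(nm: float, c: ConversionConstants = ConversionConstants()) -> float:
    """Inverse of :func:`protein_to_concentration` (nM -> fmol/µg protein)."""
    if nm < 0:
        raise ValueError("concentration must be non-negative")
    nmol_per_gdcw = nm * 1e-9 * c.litres_per_gdcw * 1e9
    return nmol_per_gdcw / (c.protein_fraction * 1e6 * 1e-6)


def dilution_flux(conc: float, mu: float) -> float:
    """Production flux of a stable product from its growth-dilution balance.

    Valid only at metabolic steady state with no degradation or secretion of
    the product: synthesis flux = concentration x specific growth rate.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if mu <= 0:
        raise ValueError("growth rate must be strictly positive")
    return conc * mu


def turnover_number(vmax: float, enzyme_conc: float) -> float:
    """Catalytic constant kcat (1/s) from Vmax (µM/h) and enzyme conc (µM)."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be strictly positive")
    return vmax / enzyme_conc / 3600.0


def _to_uM(value: float, unit: str, c: ConversionConstants) -> float:
    if unit == "uM":
        return float(value)
    if unit == "umol_per_gDCW":
        return amount_to_concentration(float(value), c)
    raise SchemaError(f"unsupported concentration unit {unit!r}")


def _enzyme_to_nM(value: float, unit: str, c: ConversionConstants) -> float:
    if unit == "nM":
        return float(value)
    if unit == "fmol_per_ug":
        return protein_to_concentration(float(value), c)
    raise SchemaError(f"unsupported enzyme unit {unit!r}")


def build_dataset(
    records: Sequence[MeasurementRecord],
    c: ConversionConstants = ConversionConstants(),
    loq_policy: Literal["drop", "half_loq"] = "drop",
    loq_substrate: float = 0.0,
    loq_product: float = 0.0,
):
    """Convert records to a fit-ready set of (substrate µM, rate µM/h) pairs.

    All concentrations are converted to µM, the product synthesis flux is
    computed per replicate as product x growth rate, and records flagged
    below the limit of quantification are handled by ``loq_policy``:

    - ``"drop"`` (default): the record is excluded and reported in the
      provenance block.
    - ``"half_loq"``: the flagged quantity is replaced by LOQ/2 (requires the
      corresponding ``loq_substrate`` / ``loq_product`` in µM).

    Replicates stay independent points; nothing is averaged.
    Returns a :class:`~invivokinetics.fitting.KineticDataset`.
    """
    from .fitting import KineticDataset  # local import to avoid a cycle

    if not records:
        raise SchemaError("no records supplied")
    sub_units = {r.substrate_unit for r in records}
    prod_units = {r.product_unit for r in records}
    if len(sub_units) > 1 or len(prod_units) > 1:
        bad = [
            i for i, r in enumerate(records)
            if r.substrate_unit != records[0].substrate_unit
            or r.product_unit != records[0].product_unit
        ]
        raise SchemaError(f"mixed unit tags in rows {bad}")

    substrates, rates, labels = [], [], []
    dropped = []
    for r in records:
        s_um = _to_uM(r.substrate_conc, r.substrate_unit, c)
        p_um = _to_uM(r.product_conc, r.product_unit, c)
        if r.substrate_below_loq or r.product_below_loq:
            if loq_policy == "drop":
                dropped.append(f"{r.strain_id}/rep{r.replicate}")
                continue
            if r.substrate_below_loq:
                s_um = loq_substrate / 2.0
            if r.product_below_loq:
                p_um = loq_product / 2.0
        substrates.append(s_um)
        rates.append(dilution_flux(p_um, r.growth_rate))
        labels.append(f"{r.strain_id}/rep{r.replicate}")

    provenance = {
        "constants": asdict(c),
        "loq_policy": loq_policy,
        "n_input_records": len(records),
        "n_retained": len(substrates),
        "dropped_below_loq": dropped,
        "flux_assumption": "steady state, no degradation: flux = conc * mu",
    }
    return KineticDataset(
        substrate=np.asarray(substrates, dtype=float),
        rate=np.asarray(rates, dtype=float),
        labels=labels,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

def _records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "strain_id": r.strain_id,
                "promoter": r.promoter,
                "crt_e_copies": r.crt_e_copies,
                "replicate": r.replicate,
                "growth_rate_per_h": r.growth_rate,
                "substrate": r.substrate_conc,
                "substrate_unit": r.substrate_unit,
                "product": r.product_conc,
                "product_unit": r.product_unit,
                "enzyme": r.enzyme_abundance if r.enzyme_abundance is not None else "",
                "enzyme_unit": r.enzyme_unit if r.enzyme_unit is not None else "",
                "substrate_below_loq": r.substrate_below_loq,
                "product_below_loq": r.product_below_loq,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable[MeasurementRecord], path: str | Path, sep: str = ",") -> None:
    """Write records as a delimited table with the canonical header."""
    _records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_records(path: str | Path, sep: str | None = None) -> list[MeasurementRecord]:
    """Read a delimited measurement table (comma or tab; autodetected).

    The header must use the canonical column names; replicate indices are
    1-based.  Raises :class:`SchemaError` on missing columns or bad values,
    naming the offending rows.
    """
    path = Path(path)
    if sep is None:
        head = path.read_text().splitlines()[0] if path.exists() else ""
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype={"strain_id": str, "promoter": str})
    required = {
        "strain_id", "replicate", "growth_rate_per_h",
        "substrate", "substrate_unit", "product", "product_unit",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    records = []
    errors = []
    for i, row in df.iterrows():
        enzyme = row.get("enzyme", "")
        has_enzyme = pd.notna(enzyme) and str(enzyme).strip() != ""
        try:
            records.append(
                MeasurementRecord(
                    strain_id=str(row["strain_id"]),
                    promoter=str(row.get("promoter", "") or ""),
                    crt_e_copies=int(row.get("crt_e_copies", 0) or 0),
                    replicate=int(row["replicate"]),
                    growth_rate=float(row["growth_rate_per_h"]),
                    substrate_conc=float(row["substrate"]),
                    substrate_unit=str(row["substrate_unit"]),
                    product_conc=float(row["product"]),
                    product_unit=str(row["product_unit"]),
                    enzyme_abundance=float(enzyme) if has_enzyme else None,
                    enzyme_unit=str(row["enzyme_unit"]) if has_enzyme else None,
                    substrate_below_loq=_parse_bool(row.get("substrate_below_loq", False)),
                    product_below_loq=_parse_bool(row.get("product_below_loq", False)),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise SchemaError("; ".join(errors))
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if pd.isna(x):
        return False
    return str(x).strip().lower() in {"true", "1", "yes"}
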