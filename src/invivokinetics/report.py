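"""Pipeline orchestration and reproducible result serialisation.

``run_pipeline`` ties the stages together: read a measurement table,
convert to intracellular units and fluxes, fit the Michaelis-Menten
parameters, run the Monte-Carlo uncertainty analysis, assess
identifiability, and derive the catalytic constant when an enzyme
concentration is available.  Reports are deterministic given the input
files and seed, serialised with fixed key order and 6 significant digits so
that reruns are byte-identical and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .fitting import (
    DEFAULT_N_MC,
    DEFAULT_RSD_THRESHOLD,
    DEFAULT_SEED,
    FitResult,
    KineticDataset,
    assess_identifiability,
    fit_michaelis_menten,
    monte_carlo_uncertainty,
)
from .quantify import (
    ConversionConstants,
    MeasurementRecord,
    build_dataset,
    read_records,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "report_to_json", "EXIT_CODES"]

# distinct exit codes per failure class, used by the CLI
EXIT_CODES = {"schema": 2, "fit_failure": 3, "degenerate_noise": 4}


@dataclass
class PipelineConfig:
    """Knobs of a pipeline run; field names mirror the config file keys."""

    n_mc: int = DEFAULT_N_MC
    seed: int = DEFAULT_SEED
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD
    noise_floor: Optional[float] = None
    loq_policy: str = "drop"
    loq_substrate: float = 0.0
    loq_product: float = 0.0
    cells_per_gdcw: float = 6.59e10
    cell_volume_fl: float = 66.0
    protein_fraction: float = 0.63

    def constants(self) -> ConversionConstants:
        return ConversionConstants(
            cells_per_gdcw=self.cells_per_gdcw,
            cell_volume_fl=self.cell_volume_fl,
            protein_fraction=self.protein_fraction,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML/JSON key-value file; unknown keys are rejected."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineReport:
    input_file: str
    constants: dict
    n_strains: int
    n_pairs: int
    n_dropped: int
    substrate_min_uM: float
    substrate_max_uM: float
    fold_range: float
    fit: FitResult
    enzyme_conc_uM: Optional[float]
    kcat_per_s: Optional[float]
    seed: int
    software_version: str = __version__


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return _round_sig(v) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: PipelineReport) -> str:
    """Serialise a report with fixed key order and 6 significant digits."""
    fit = report.fit
    fit_block = {
        "vmax_hat_uM_per_h": fit.vmax_hat,
        "k_half_hat_uM": fit.k_half_hat,
        "residual_sd_uM_per_h": fit.residual_sd,
        "covariance": fit.covariance,
        "cov_condition": fit.cov_condition if np.isfinite(fit.cov_condition) else None,
        "n_points": fit.n_points,
        "mc": None,
        "n_mc": fit.n_mc,
        "n_mc_failed": fit.n_mc_failed,
        "identifiable": fit.identifiable,
        "lower_limits": fit.lower_limits,
    }
    if fit.mc_summary is not None:
        fit_block["mc"] = {
            name: {
                "mean": s.mean,
                "sd": s.sd,
                "rsd": s.rsd,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
            }
            for name, s in fit.mc_summary.items()
        }
    doc = {
        "software": "invivokinetics",
        "version": report.software_version,
        "input_file": report.input_file,
        "seed": report.seed,
        "constants": report.constants,
        "dataset": {
            "n_strains": report.n_strains,
            "n_pairs": report.n_pairs,
            "n_dropped_below_loq": report.n_dropped,
            "substrate_min_uM": report.substrate_min_uM,
            "substrate_max_uM": report.substrate_max_uM,
            "fold_range": report.fold_range,
        },
        "fit": fit_block,
        "enzyme_conc_uM": report.enzyme_conc_uM,
        "kcat_per_s": report.kcat_per_s,
    }
    return json.dumps(_jsonable(doc), indent=2, sort_keys=False)


def human_summary(report: PipelineReport) -> str:
    fit = report.fit
    lines = [
        f"invivokinetics {report.software_version} — in vivo Michaelis-Menten fit",
        f"input: {report.input_file}",
        f"dataset: {report.n_strains} strains, {report.n_pairs} pairs "
        f"({report.n_dropped} dropped below LOQ), substrate "
        f"{report.substrate_min_uM:.3g}-{report.substrate_max_uM:.3g} µM "
        f"({report.fold_range:.3g}-fold)",
        f"Vmax_cell = {fit.vmax_hat:.4g} µM/h, K1/2_cell = {fit.k_half_hat:.4g} µM "
        f"(residual sd {fit.residual_sd:.3g} µM/h)",
    ]
    if fit.mc_summary is not None:
        for name, s in fit.mc_summary.items():
            flag = ""
            if fit.identifiable is not None and not fit.identifiable[name]:
                lim = (fit.lower_limits or {}).get(name)
                flag = f"  [NON-IDENTIFIABLE; lower limit {lim:.4g}]" if lim else "  [NON-IDENTIFIABLE]"
            lines.append(
                f"  {name}: {s.mean:.4g} ± {s.sd:.3g} (rsd {100 * s.rsd:.1f}%), "
                f"95% CI [{s.ci95_low:.4g}, {s.ci95_high:.4g}]{flag}"
            )
    if report.kcat_per_s is not None:
        lines.append(
            f"kcat_cell = {report.kcat_per_s:.3g} 1/s "
            f"(enzyme {1e3 * report.enzyme_conc_uM:.3g} nM)"
        )
    return "\n".join(lines)


def run_pipeline(
    data_file: str | Path,
    config: PipelineConfig | str | Path | None = None,
) -> PipelineReport:
    """Execute quantify -> fit -> Monte-Carlo -> identifiability on one table.

    ``config`` may be a :class:`PipelineConfig`, a path to a YAML/JSON
    config file, or None for defaults.  The run is deterministic given the
    file contents and the seed.
    """
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, PipelineConfig):
        cfg = config
    else:
        cfg = PipelineConfig.from_file(config)

    records = read_records(data_file)
    constants = cfg.constants()
    data = build_dataset(
        records,
        constants,
        loq_policy=cfg.loq_policy,  # type: ignore[arg-type]
        loq_substrate=cfg.loq_substrate,
        loq_product=cfg.loq_product,
    )

    fit = fit_michaelis_menten(data)
    fit = monte_carlo_uncertainty(
        data, fit, n=cfg.n_mc, seed=cfg.seed, noise_floor=cfg.noise_floor
    )
    fit = assess_identifiability(fit, rsd_threshold=cfg.rsd_threshold)

    from .quantify import _enzyme_to_nM, turnover_number

    enzyme_vals = [
        _enzyme_to_nM(r.enzyme_abundance, r.enzyme_unit, constants)
        for r in records
        if r.enzyme_abundance is not None
    ]
    enzyme_um = float(np.mean(enzyme_vals)) * 1e-3 if enzyme_vals else None
    kcat = turnover_number(fit.vmax_hat, enzyme_um) if enzyme_um else None

    strains = {r.strain_id for r in records}
    return PipelineReport(
        input_file=str(data_file),
        constants=asdict(constants),
        n_strains=len(strains),
        n_pairs=len(data),
        n_dropped=len(data.provenance.get("dropped_below_loq", [])),
        substrate_min_uM=float(data.substrate.min()),
        substrate_max_uM=float(data.substrate.max()),
        fold_range=data.fold_range,
        fit=fit,
        enzyme_conc_uM=enzyme_um,
        kcat_per_s=kcat,
        seed=cfg.seed,
    )
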