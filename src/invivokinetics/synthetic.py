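"""Seeded synthetic strain panels with the structure of an engineered yeast collection.

A strain panel replaces the substrate titration of a classical in vitro
assay: each strain expresses the substrate-producing enzyme at a different
level (promoter strength x gene copy number), which sets a different influx
v_in, hence a different steady-state substrate concentration, while the
converting enzyme under study is expressed identically everywhere.  The
generator computes the noiseless steady state of each strain from the
pathway model, draws a growth rate per replicate, applies multiplicative
lognormal measurement noise to the concentrations, and emits measurement
records in the same schema the quantification stage reads — so the whole
pipeline is testable end-to-end without any experimental data.

True parameters are kept in a separate sidecar (never in the data file) so
that downstream fitting code cannot accidentally read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .model import PathwayModel, steady_state
from .quantify import MeasurementRecord

__all__ = [
    "PanelConfig",
    "DesignScanConfig",
    "PanelConfigError",
    "generate_strain_panel",
    "truth_sidecar",
    "reference_presets",
    "influx_for_substrate",
]

InfluxLevel = Union[float, tuple[str, int, float]]


class PanelConfigError(ValueError):
    """Panel configuration is inconsistent (e.g. infeasible influx)."""


@dataclass
class PanelConfig:
    """Configuration of one synthetic strain panel.

    ``influx_levels`` entries are either plain v_in values (µM/h) or
    ``(promoter_label, copy_number, per_copy_influx)`` triples mapped
    linearly to v_in = copy_number * per_copy_influx.  Growth rates are
    drawn per replicate from a truncated normal (default 0.40 +/- 0.03 1/h);
    concentration noise is multiplicative lognormal parameterised by a
    coefficient of variation (default 10%), mean-corrected so the expected
    noisy value equals the noiseless steady state.
    """

    influx_levels: Sequence[InfluxLevel]
    true_vmax: float
    true_k_half: float
    mu_mean: float = 0.40
    mu_sd: float = 0.03
    enzyme_conc_nm: float = 42.0
    n_replicates: int = 3
    noise_cv_conc: float = 0.10
    loq_substrate: float = 0.0
    loq_product: float = 0.0
    seed: int = 42
    allow_infeasible: bool = False
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.influx_levels:
            raise PanelConfigError("influx_levels must be non-empty")
        if self.n_replicates < 1:
            raise PanelConfigError("n_replicates must be >= 1")
        for v in (self.noise_cv_conc, self.loq_substrate, self.loq_product, self.mu_sd):
            if v < 0:
                raise PanelConfigError("noise and LOQ parameters must be >= 0")

    def resolved_influxes(self) -> list[tuple[str, int, float]]:
        """Normalise influx levels to (promoter, copies, v_in) per strain."""
        out = []
        for i, lvl in enumerate(self.influx_levels, start=1):
            if isinstance(lvl, (tuple, list)):
                promoter, copies, per_copy = lvl
                out.append((str(promoter), int(copies), float(copies) * float(per_copy)))
            else:
                out.append((f"prom{i}", 1, float(lvl)))
        return out


@dataclass
class DesignScanConfig:
    """Grid for a steady-state design scan over enzyme levels and influx."""

    vmax_levels: tuple[float, ...]
    k_half: float
    v_in_start: float
    v_in_stop: float
    n_steps: int = 40
    mu: float = 0.40

    def v_in_grid(self) -> np.ndarray:
        return np.linspace(self.v_in_start, self.v_in_stop, self.n_steps)


def influx_for_substrate(s_star: float, vmax: float, k_half: float) -> float:
    """Influx that puts the steady-state substrate at ``s_star``.

    Inverts S* = K*v_in/(Vmax - v_in): v_in = Vmax*S*/(K + S*).  This is how
    panel designs translate a target substrate span into promoter/copy
    choices.
    """
    return vmax * s_star / (k_half + s_star)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_strain_panel(cfg: PanelConfig) -> list[MeasurementRecord]:
    """Generate one seeded panel of strain x replicate measurement records.

    For each strain the noiseless steady state (substrate S*, product
    P* = v_in/mu, conversion flux v_in) is computed from the pathway model
    at that strain's influx; each replicate then gets its own growth rate
    draw and lognormal concentration noise.  Below-LOQ flags are set
    whenever the *noisy* value falls under the configured limit of
    quantification.  Influx levels at or above the enzyme capacity have no
    steady state and raise :class:`PanelConfigError` unless
    ``allow_infeasible`` is set, in which case they are skipped.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MeasurementRecord] = []
    for idx, (promoter, copies, v_in) in enumerate(cfg.resolved_influxes(), start=1):
        if v_in >= cfg.true_vmax:
            if cfg.allow_infeasible:
                continue
            raise PanelConfigError(
                f"influx {v_in} µM/h >= Vmax {cfg.true_vmax} µM/h for strain {idx}: "
                "no steady state (set allow_infeasible to skip such levels)"
            )
        for rep in range(1, cfg.n_replicates + 1):
            mu = rng.normal(cfg.mu_mean, cfg.mu_sd)
            while mu <= 0:  # truncate at zero; essentially never loops
                mu = rng.normal(cfg.mu_mean, cfg.mu_sd)
            ss = steady_state(
                PathwayModel(v_in=v_in, vmax=cfg.true_vmax, k_half=cfg.true_k_half, mu=mu)
            )
            s_noisy = ss.s_star * _lognormal_factor(rng, cfg.noise_cv_conc)
            p_noisy = ss.p_star * _lognormal_factor(rng, cfg.noise_cv_conc)
            records.append(
                MeasurementRecord(
                    strain_id=f"{cfg.name}_S{idx:02d}",
                    promoter=promoter,
                    crt_e_copies=copies,
                    replicate=rep,
                    growth_rate=float(mu),
                    substrate_conc=float(s_noisy),
                    substrate_unit="uM",
                    product_conc=float(p_noisy),
                    product_unit="uM",
                    enzyme_abundance=cfg.enzyme_conc_nm,
                    enzyme_unit="nM",
                    substrate_below_loq=bool(s_noisy < cfg.loq_substrate),
                    product_below_loq=bool(p_noisy < cfg.loq_product),
                )
            )
    return records


def truth_sidecar(cfg: PanelConfig) -> dict:
    """Ground-truth metadata for a panel, kept apart from the data table."""
    influxes = [v for _, _, v in cfg.resolved_influxes()]
    s_stars = [
        steady_state(
            PathwayModel(v_in=v, vmax=cfg.true_vmax, k_half=cfg.true_k_half, mu=cfg.mu_mean)
        ).s_star
        for v in influxes
        if v < cfg.true_vmax
    ]
    return {
        "name": cfg.name,
        "true_vmax": cfg.true_vmax,
        "true_k_half": cfg.true_k_half,
        "true_kcat_per_s": cfg.true_vmax / (cfg.enzyme_conc_nm * 1e-3) / 3600.0,
        "enzyme_conc_nm": cfg.enzyme_conc_nm,
        "influx_levels": influxes,
        "noiseless_s_star": s_stars,
        "mu_mean": cfg.mu_mean,
        "mu_sd": cfg.mu_sd,
        "noise_cv_conc": cfg.noise_cv_conc,
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
    }


def _panel_from_substrate_span(
    name: str,
    s_min: float,
    s_max: float,
    n_strains: int,
    vmax: float,
    k_half: float,
    enzyme_conc_nm: float,
    **kwargs,
) -> PanelConfig:
    targets = np.geomspace(s_min, s_max, n_strains)
    influxes = [influx_for_substrate(s, vmax, k_half) for s in targets]
    return PanelConfig(
        influx_levels=influxes,
        true_vmax=vmax,
        true_k_half=k_half,
        enzyme_conc_nm=enzyme_conc_nm,
        name=name,
        **kwargs,
    )


def reference_presets() -> dict[str, PanelConfig | DesignScanConfig]:
    """Named panel and scan presets mirroring the published study designs.

    - ``crtB_medium``: phytoene-synthase panel at medium enzyme expression;
      truth Vmax = 849 µM/h, K = 19 µM; 8 strains whose steady-state GGPP
      spans 0.12-20.78 µM (167-fold), partial saturation.
    - ``crtI_fungal``: fungal phytoene-desaturase panel; truth
      Vmax = 168 µM/h, K = 380 µM; phytoene span 4-1641 µM (430-fold),
      reaching saturation, enzyme ~1.56 µM (kcat ~0.03 1/s).
    - ``crtI_bacterial``: bacterial desaturase shaped on the reported lower
      limits Vmax = 13 µM/h, K = 560 µM, with the substrate span truncated
      far below saturation (4-100 µM, under a fifth of K) so that only the
      efficiency Vmax/K is constrained — the canonical non-identifiable case.
    - ``crtB_like_btcrtI``: desaturase panel at Vmax = 309 µM/h, K = 41 µM
      over the same 4-1641 µM span (well saturating).
    - ``ggpp_panel``: base strain collection whose steady-state substrate
      spans a factor of 38, for fold-range bookkeeping.
    - ``design_scan_three_level``: design scan grid, Vmax in {0.02, 0.4, 0.7}
      µM/h, K = 1 µM, influx from 0.01 to 0.4 µM/h.
    """
    presets: dict[str, PanelConfig | DesignScanConfig] = {
        "crtB_medium": _panel_from_substrate_span(
            "crtB_medium", 0.12, 20.78, 8, vmax=849.0, k_half=19.0, enzyme_conc_nm=42.0
        ),
        "crtI_fungal": _panel_from_substrate_span(
            "crtI_fungal", 4.0, 1641.0, 8, vmax=168.0, k_half=380.0, enzyme_conc_nm=1556.0
        ),
        "crtI_bacterial": _panel_from_substrate_span(
            "crtI_bacterial", 4.0, 100.0, 8, vmax=13.0, k_half=560.0, enzyme_conc_nm=1000.0
        ),
        "crtB_like_btcrtI": _panel_from_substrate_span(
            "crtB_like_btcrtI", 4.0, 1641.0, 8, vmax=309.0, k_half=41.0, enzyme_conc_nm=42.0
        ),
        "ggpp_panel": _panel_from_substrate_span(
            "ggpp_panel", 0.55, 20.9, 8, vmax=849.0, k_half=19.0, enzyme_conc_nm=42.0
        ),
        "design_scan_three_level": DesignScanConfig(
            vmax_levels=(0.02, 0.4, 0.7),
            k_half=1.0,
            v_in_start=0.01,
            v_in_stop=0.4,
        ),
    }
    return presets
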