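"""Pipeline driver: in-air FOMs -> in-phantom UTCP -> out-of-beam safety
-> beam selection, from a single YAML configuration.

Each candidate beam is generated (or loaded), scored on the five in-air
figures of merit, evaluated in the cylindrical mucosa phantom for the
UTCP-maximising irradiation time, and finally ranked by the out-of-field
organ dose accumulated over that time.  All stages are deterministic given
the configured seed, and every emitted report carries the seed and a hash
of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dosimetry import (
    AbsorbedDose,
    TissueComposition,
    WeightingScheme,
    component_percentages,
    default_tissues,
    read_tissue_table,
)
from .fom import FOMReport, IAEAThresholds, compute_foms
from .outofbeam import (
    DEFAULT_IN_FIELD,
    BeamSafetyComparison,
    assemble_organ_table,
    organ_table_frame,
    out_of_field_summary,
    select_safest_beam,
)
from .radiobiology import NTCPParams, OutcomeResult, TCPParams, optimize_time
from .spectrum import BeamSpectrum, read_spectrum
from .synthetic import (
    BeamModelParams,
    CylinderPhantomSpec,
    DoseComponentField,
    DoseKernelParams,
    OrganSpec,
    default_grid,
    default_organ_specs,
    deposit_dose_cylinder,
    generate_beam_spectrum,
    generate_organ_doses,
)

logger = logging.getLogger("bnctbeam")

_STRING_FIELDS = {"name", "mode"}


def _numeric(mapping: dict) -> dict:
    """Coerce YAML scalars to float (YAML 1.1 reads ``2.6e9`` as a string)."""
    return {k: (v if k in _STRING_FIELDS else float(v)) for k, v in mapping.items()}


@dataclass
class PipelineConfig:
    """Typed view of the YAML pipeline configuration."""

    beams: list[BeamModelParams]
    spectrum_files: list[str] = field(default_factory=list)
    phantom: CylinderPhantomSpec = field(default_factory=CylinderPhantomSpec)
    kernels: DoseKernelParams = field(default_factory=DoseKernelParams)
    tcp_params: TCPParams = field(default_factory=TCPParams)
    ntcp_params: NTCPParams = field(default_factory=NTCPParams)
    thresholds: IAEAThresholds = field(default_factory=IAEAThresholds)
    weighting: WeightingScheme = field(default_factory=WeightingScheme)
    organs: list[OrganSpec] = field(default_factory=default_organ_specs)
    in_field: frozenset[str] = DEFAULT_IN_FIELD
    tissues: dict[str, TissueComposition] = field(default_factory=default_tissues)
    summary_statistic: str = "sum"
    t_max_min: float = 120.0
    t_step_min: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        beams = [BeamModelParams(**_numeric(b)) for b in raw.get("beams", [])]
        organs = raw.get("organs", "default")
        organ_specs = (
            default_organ_specs()
            if organs == "default"
            else [OrganSpec(**_numeric(o)) for o in organs]
        )
        tissues = default_tissues()
        if raw.get("tissue_table"):
            tissues.update(read_tissue_table(raw["tissue_table"]))
        return cls(
            beams=beams,
            spectrum_files=list(raw.get("spectrum_files", [])),
            phantom=CylinderPhantomSpec(**_numeric(raw.get("phantom", {}))),
            kernels=DoseKernelParams(**_numeric(raw.get("kernels", {}))),
            tcp_params=TCPParams(**_numeric(raw.get("tcp", {}))),
            ntcp_params=NTCPParams(**_numeric(raw.get("ntcp", {}))),
            thresholds=IAEAThresholds(**_numeric(raw.get("thresholds", {}))),
            weighting=WeightingScheme(**_numeric(raw.get("weighting", {}))),
            organs=organ_specs,
            in_field=frozenset(raw.get("in_field", DEFAULT_IN_FIELD)),
            tissues=tissues,
            summary_statistic=raw.get("summary_statistic", "sum"),
            t_max_min=float(raw.get("t_max_min", 120.0)),
            t_step_min=float(raw.get("t_step_min", 0.5)),
            noise_sigma=float(raw.get("noise_sigma", 0.0)),
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.from_dict(raw)
        cfg._raw_text = Path(path).read_text()  # for the provenance hash
        return cfg

    def config_hash(self) -> str:
        text = getattr(self, "_raw_text", None)
        if text is None:
            text = json.dumps(
                {
                    "beams": [asdict(b) for b in self.beams],
                    "phantom": asdict(self.phantom),
                    "kernels": asdict(self.kernels),
                    "seed": self.seed,
                },
                sort_keys=True,
            )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def weighted_rate_field(fld: DoseComponentField, tissue: TissueComposition) -> np.ndarray:
    """Per-voxel fixed-RBE weighted dose rate (Gy-Eq/min) for one tissue."""
    return (
        fld.gamma * tissue.rbe_gamma
        + (fld.thermal_n + fld.fast_n) * tissue.rbe_neutron
        + fld.boron_per_ppm * tissue.boron_ppm * tissue.cbe_boron
    )


def evaluate_phantom(
    spectrum: BeamSpectrum, config: PipelineConfig
) -> tuple[OutcomeResult, DoseComponentField]:
    """Tier 2: UTCP maximisation in the cylinder phantom for one beam.

    The healthy-tissue limiting point is the mucosa voxel with the highest
    weighted dose rate; the component percentages reported with the outcome
    are evaluated at that voxel.
    """
    fld = deposit_dose_cylinder(spectrum, config.phantom, config.kernels)
    tumor_tissue = config.tissues["tumor"]
    mucosa_tissue = config.tissues["mucosa"]

    tumor_rates = weighted_rate_field(fld, tumor_tissue)[fld.tumor_mask()]
    mucosa_rates = weighted_rate_field(fld, mucosa_tissue)
    mucosa_mask = fld.mucosa_mask()
    flat_index = int(np.argmax(np.where(mucosa_mask, mucosa_rates, -np.inf)))
    limit_idx = np.unravel_index(flat_index, mucosa_rates.shape)
    limit_rate = float(mucosa_rates[limit_idx])

    outcome = optimize_time(
        tumor_rates,
        limit_rate,
        config.tcp_params,
        config.ntcp_params,
        fld.voxel_volume_cm3,
        t_max_min=config.t_max_min,
        t_step_min=config.t_step_min,
    )
    absorbed_at_limit = AbsorbedDose(
        boron=float(fld.boron_per_ppm[limit_idx]) * mucosa_tissue.boron_ppm,
        thermal_n=float(fld.thermal_n[limit_idx]),
        fast_n=float(fld.fast_n[limit_idx]),
        gamma=float(fld.gamma[limit_idx]),
    )
    outcome.component_percentages = component_percentages(absorbed_at_limit)
    outcome.beam = spectrum.name
    return outcome, fld


def run_evaluation(config: PipelineConfig) -> dict:
    """Run the full three-tier evaluation and return the ranked report."""
    spectra: list[BeamSpectrum] = []
    grid = default_grid()
    for params in config.beams:
        spectra.append(
            generate_beam_spectrum(grid, params, seed=config.seed, noise_sigma=config.noise_sigma)
        )
    for path in config.spectrum_files:
        spectra.append(read_spectrum(path))
    if not spectra:
        raise ValueError("no beams configured")

    beams_report: dict[str, dict] = {}
    statistics: dict[str, float] = {}
    utcps: dict[str, float] = {}
    tables = {}
    for spectrum in spectra:
        name = spectrum.name
        t0 = time.perf_counter()
        try:
            fom_report = compute_foms(spectrum, config.thresholds)
        except Exception as exc:  # pragma: no cover - stage naming
            raise RuntimeError(f"in-air FOM stage failed for beam {name!r}: {exc}") from exc
        try:
            outcome, _ = evaluate_phantom(spectrum, config)
        except Exception as exc:
            raise RuntimeError(f"phantom evaluation stage failed for beam {name!r}: {exc}") from exc
        try:
            raw = generate_organ_doses(
                spectrum, config.organs, config.kernels, seed=config.seed,
                noise_sigma=config.noise_sigma,
            )
            table = assemble_organ_table(
                raw, config.tissues, config.weighting, t_irr_min=outcome.t_irr_min
            )
            stat = out_of_field_summary(table, config.in_field, config.summary_statistic)
        except Exception as exc:
            raise RuntimeError(f"organ dosimetry stage failed for beam {name!r}: {exc}") from exc
        logger.info("beam %s evaluated in %.2f s", name, time.perf_counter() - t0)

        statistics[name] = stat
        utcps[name] = outcome.utcp
        tables[name] = table
        beams_report[name] = {
            "fom": {**fom_report.values(), "compliance": fom_report.compliance},
            "outcome": {
                "t_irr_min": outcome.t_irr_min,
                "tcp": outcome.tcp,
                "ntcp": outcome.ntcp,
                "utcp": outcome.utcp,
                "d_max_healthy_gy_eq": outcome.d_max_healthy_gy_eq,
                "component_percentages": list(outcome.component_percentages or ()),
                "flat_tcp_warning": outcome.flat_tcp_warning,
            },
            "out_of_field_d_eq_cgy": stat,
        }

    selected = select_safest_beam(statistics, utcps)
    report = {
        "beams": beams_report,
        "selection": {
            "selected_beam": selected,
            "statistic": config.summary_statistic,
            "out_of_field_statistics": statistics,
        },
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": __version__,
        },
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        render_tables(report, tables, outdir)
    return report


def _sig3(x: float) -> float:
    return float(f"{x:.3g}")


def render_tables(report: dict, tables: dict, outdir) -> None:
    """Write CSV tables mirroring the conventional report layouts.

    Figures of merit are rendered at three significant figures and
    probabilities at two decimals.
    """
    import pandas as pd

    outdir = Path(outdir)
    fom_rows = []
    outcome_rows = []
    for name, entry in report["beams"].items():
        fom = entry["fom"]
        fom_rows.append(
            {
                "Beam": name,
                "phi_epi(1e9 cm-2 s-1)": _sig3(fom["phi_epi"] / 1e9),
                "phi_th/phi_epi": _sig3(fom["ratio_th_epi"]),
                "Dfast/phi_epi(1e-13 cm2 Gy)": _sig3(fom["fast_dose_per_epi"] / 1e-13),
                "Dgamma/phi_epi(1e-13 cm2 Gy)": _sig3(fom["gamma_dose_per_epi"] / 1e-13),
                "J/phi_epi": _sig3(fom["J_over_phi_epi"]),
            }
        )
        oc = entry["outcome"]
        pct = oc["component_percentages"] or [float("nan")] * 4
        outcome_rows.append(
            {
                "Beam": name,
                "Tirr(min)": oc["t_irr_min"],
                "UTCP": round(oc["utcp"], 2),
                "TCP": round(oc["tcp"], 2),
                "NTCP": round(oc["ntcp"], 2),
                "D(Gy)": _sig3(oc["d_max_healthy_gy_eq"]),
                "%(n,alpha)": round(pct[0]),
                "%(n,p)": round(pct[1]),
                "%(n,n')": round(pct[2]),
                "%gamma": round(pct[3]),
            }
        )
    pd.DataFrame(fom_rows).to_csv(outdir / "table_fom.csv", index=False)
    pd.DataFrame(outcome_rows).to_csv(outdir / "table_outcome.csv", index=False)
    for name, table in tables.items():
        organ_table_frame(table).to_csv(outdir / f"table_organs_{name}.csv", index=False)
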