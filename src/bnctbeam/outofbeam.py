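"""Out-of-beam organ dosimetry and safety ranking of candidate beams.

At the irradiation time chosen to maximise UTCP, each organ of a
simplified whole-body phantom accumulates the four dose components.  The
table reports, per organ, the absorbed components in cGy (DN fast recoil,
DB boron, DH thermal capture, Dgamma), the ICRP-weighted equivalent dose DW
in cSv, and the fixed-RBE biologically weighted dose DEq in cGy-Eq.  Beams
are ranked by an out-of-field summary of DEq — the safety criterion — with
lower meaning safer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dosimetry import (
    DEFAULT_ORGAN_TISSUE,
    AbsorbedDose,
    DoseComponents,
    TissueComposition,
    WeightingScheme,
    absorbed_dose,
    equivalent_dose_icrp,
    weighted_dose_fixed_rbe,
)
from .synthetic import OrganRawDose

#: organs inside the irradiation field for a head-and-neck position
DEFAULT_IN_FIELD = frozenset({"brain", "head", "pharynx", "thyroid"})

SUMMARY_STATISTICS = ("sum", "max", "mean")


@dataclass
class OrganDoseRecord:
    """Dose table row for one organ.

    Absorbed components in cGy (``d_fast`` = DN, ``d_boron`` = DB,
    ``d_thermal`` = DH, ``d_gamma``), equivalent dose ``d_w`` in cSv and
    fixed-RBE weighted dose ``d_eq`` in cGy-Eq.  The mapping of the DH
    column to the thermal-capture component is a convention of this
    package (see the methods note).
    """

    organ: str
    d_fast: float
    d_boron: float
    d_thermal: float
    d_gamma: float
    d_w: float
    d_eq: float
    d_eq_sigma: float | None = None

    def __post_init__(self) -> None:
        if min(self.d_fast, self.d_boron, self.d_thermal, self.d_gamma, self.d_w, self.d_eq) < 0.0:
            raise ValueError("doses must be nonnegative")


def assemble_organ_table(
    raw_doses: list[OrganRawDose],
    tissues: dict[str, TissueComposition],
    scheme: WeightingScheme | None = None,
    t_irr_min: float = 1.0,
    allow_default_tissue: bool = True,
    relative_errors: dict[str, float] | None = None,
) -> list[OrganDoseRecord]:
    """Per-organ dose records after ``t_irr_min`` minutes of irradiation.

    Organs without a tissue entry fall back to generic factors
    (RBE_gamma=1, RBE_n=3.2, CBE=1.3, 15 ppm) unless
    ``allow_default_tissue`` is disabled.  When per-organ relative errors
    are supplied they propagate to DEq in quadrature over the components.
    """
    scheme = scheme or WeightingScheme()
    records = []
    for raw in raw_doses:
        tissue = tissues.get(raw.name)
        if tissue is None:
            if not allow_default_tissue:
                raise KeyError(f"no tissue factors for organ {raw.name!r}")
            tissue = TissueComposition(
                raw.name,
                DEFAULT_ORGAN_TISSUE.boron_ppm,
                DEFAULT_ORGAN_TISSUE.rbe_gamma,
                DEFAULT_ORGAN_TISSUE.rbe_neutron,
                DEFAULT_ORGAN_TISSUE.cbe_boron,
            )
        components = DoseComponents(
            boron_per_ppm=raw.boron_per_ppm,
            thermal_n=raw.thermal_n,
            fast_n=raw.fast_n,
            gamma=raw.gamma,
        )
        absorbed = absorbed_dose(components, tissue, t_irr_min)
        d_eq_gy = weighted_dose_fixed_rbe(absorbed, tissue)
        d_w_sv = equivalent_dose_icrp(absorbed, fast_energy_ev=raw.mean_neutron_energy_ev)
        sigma = None
        if relative_errors is not None and raw.name in relative_errors:
            rel = relative_errors[raw.name]
            # same relative error on each component, combined in quadrature
            contributions = (
                absorbed.gamma * tissue.rbe_gamma,
                absorbed.thermal_n * tissue.rbe_neutron,
                absorbed.fast_n * tissue.rbe_neutron,
                absorbed.boron * tissue.cbe_boron,
            )
            sigma = 100.0 * rel * math.sqrt(sum(c * c for c in contributions))
        records.append(
            OrganDoseRecord(
                organ=raw.name,
                d_fast=100.0 * absorbed.fast_n,
                d_boron=100.0 * absorbed.boron,
                d_thermal=100.0 * absorbed.thermal_n,
                d_gamma=100.0 * absorbed.gamma,
                d_w=100.0 * d_w_sv,
                d_eq=100.0 * d_eq_gy,
                d_eq_sigma=sigma,
            )
        )
    return records


def out_of_field_summary(
    table: list[OrganDoseRecord],
    in_field: frozenset[str] | set[str] = DEFAULT_IN_FIELD,
    statistic: str = "sum",
) -> float:
    """Scalar out-of-field dose statistic over DEq (cGy-Eq).

    ``statistic`` is one of ``sum`` (default), ``max`` or ``mean``; all are
    monotone in every organ dose, so organ-wise dominance between beams is
    preserved by any choice.
    """
    if statistic not in SUMMARY_STATISTICS:
        raise ValueError(f"statistic must be one of {SUMMARY_STATISTICS}")
    doses = [rec.d_eq for rec in table if rec.organ not in in_field]
    if not doses:
        raise ValueError("no out-of-field organs in the table")
    if statistic == "sum":
        return float(sum(doses))
    if statistic == "max":
        return float(max(doses))
    return float(sum(doses) / len(doses))


@dataclass
class BeamSafetyComparison:
    """Per-beam organ tables and out-of-field statistics, plus the selection."""

    tables: dict[str, list[OrganDoseRecord]]
    statistics: dict[str, float]
    utcps: dict[str, float]
    selected: str


def select_safest_beam(
    statistics: dict[str, float], utcps: dict[str, float] | None = None
) -> str:
    """Beam with the minimum out-of-field statistic.

    Ties are broken by higher UTCP (when provided), then lexicographically
    by beam id.
    """
    if not statistics:
        raise ValueError("no beams to compare")
    utcps = utcps or {}
    return min(
        statistics,
        key=lambda b: (statistics[b], -utcps.get(b, 0.0), b),
    )


def organ_table_frame(table: list[OrganDoseRecord]) -> pd.DataFrame:
    """Organ dose table with the conventional column order."""
    return pd.DataFrame(
        [
            {
                "Organ": rec.organ,
                "DN(cGy)": rec.d_fast,
                "DB(cGy)": rec.d_boron,
                "DH(cGy)": rec.d_thermal,
                "Dgamma(cGy)": rec.d_gamma,
                "DW(cSv)": rec.d_w,
                "DEq(cGy_Eq)": rec.d_eq,
            }
            for rec in table
        ]
    )
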