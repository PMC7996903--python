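"""In-air physical figures of merit for epithermal BNCT beams.

The five quantities evaluated at the beam port are the epithermal flux
phi_epi, the thermal-to-epithermal flux ratio, the fast-neutron and gamma
dose rates per unit epithermal flux, and the collimation ratio J/phi_epi
(total neutron current over epithermal flux).  Compliance is judged against
the IAEA-recommended values, all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .spectrum import BeamSpectrum, band_integrals, band_masks, BAND_FAST

#: order in which the five criteria are reported everywhere
CRITERIA = ("phi_epi", "ratio_th_epi", "fast_dose_per_epi", "gamma_dose_per_epi", "J_over_phi_epi")


@dataclass(frozen=True)
class IAEAThresholds:
    """Recommended in-air figure-of-merit limits.

    Units: ``min_phi_epi`` cm^-2 s^-1; ``max_fast``/``max_gamma`` cm^2 Gy
    (dose rate per unit epithermal flux); ratios dimensionless.
    """

    min_phi_epi: float = 1.0e9
    max_ratio_th_epi: float = 0.05
    max_fast: float = 2.0e-13
    max_gamma: float = 2.0e-13
    min_collimation: float = 0.7

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all thresholds must be positive")


@dataclass
class FOMReport:
    """The five in-air figures of merit plus compliance flags."""

    phi_epi: float
    ratio_th_epi: float
    fast_dose_per_epi: float
    gamma_dose_per_epi: float
    J_over_phi_epi: float
    compliance: dict[str, bool] | None = None
    beam: str = "beam"

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CRITERIA}


def compute_foms(spectrum: BeamSpectrum, thresholds: IAEAThresholds | None = None) -> FOMReport:
    """Form the five figure-of-merit ratios from beam-port tallies.

    The gamma and fast dose tallies are taken from the spectrum as scalars;
    J is the total directed neutron current over the port.  Raises if the
    epithermal flux vanishes (the ratios are undefined).
    """
    phi_th, phi_epi, phi_fast, j_total = band_integrals(spectrum)
    if phi_epi <= 0.0:
        raise ZeroDivisionError("epithermal flux is zero; FOM ratios undefined")
    report = FOMReport(
        phi_epi=phi_epi,
        ratio_th_epi=phi_th / phi_epi,
        fast_dose_per_epi=spectrum.fast_dose_rate / phi_epi,
        gamma_dose_per_epi=spectrum.gamma_dose_rate / phi_epi,
        J_over_phi_epi=j_total / phi_epi,
        beam=spectrum.name,
    )
    report.compliance, _ = check_compliance(report, thresholds or IAEAThresholds())
    return report


def check_compliance(
    report: FOMReport, thresholds: IAEAThresholds | None = None
) -> tuple[dict[str, bool], int]:
    """Strict-inequality compliance flags for the five criteria plus pass count."""
    t = thresholds or IAEAThresholds()
    flags = {
        "phi_epi": report.phi_epi > t.min_phi_epi,
        "ratio_th_epi": report.ratio_th_epi < t.max_ratio_th_epi,
        "fast_dose_per_epi": report.fast_dose_per_epi < t.max_fast,
        "gamma_dose_per_epi": report.gamma_dose_per_epi < t.max_gamma,
        "J_over_phi_epi": report.J_over_phi_epi > t.min_collimation,
    }
    return flags, sum(flags.values())


def apply_kerma(spectrum: BeamSpectrum, kerma_per_bin: np.ndarray, band: str | None = None) -> float:
    """Fold per-bin kerma coefficients (Gy cm^2) with the flux, in Gy/s.

    Hook for recomputing the scalar dose-rate tallies from an energy-resolved
    kerma table; restrict to one band (e.g. ``"fast"``) via ``band``.
    """
    kerma = np.asarray(kerma_per_bin, dtype=float)
    if kerma.shape != spectrum.flux_per_bin.shape:
        raise ValueError("kerma table must have one coefficient per bin")
    flux = spectrum.flux_per_bin
    if band is not None:
        mask = band_masks(spectrum.grid)[band]
        flux = np.where(mask, flux, 0.0)
    return float(np.dot(flux, kerma))
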