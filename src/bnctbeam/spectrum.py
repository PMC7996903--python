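"""Energy grids, beam-port spectra, and energy-band bookkeeping.

The neutron energy axis is divided into the three bands conventional in
BNCT beam design: thermal (E < 0.5 eV), epithermal (0.5 eV <= E <= 10 keV)
and fast (E > 10 keV).  Band boundaries belong to the epithermal band.
Spectra are stored as per-bin tallies on a fixed energy grid together with
the scalar gamma and fast-neutron dose-rate tallies measured at the beam
port.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: thermal/epithermal boundary (eV); energies strictly below are thermal
THERMAL_MAX_EV = 0.5
#: epithermal/fast boundary (eV); energies strictly above are fast
FAST_MIN_EV = 1.0e4

BAND_THERMAL = "thermal"
BAND_EPITHERMAL = "epithermal"
BAND_FAST = "fast"


@dataclass(frozen=True)
class EnergyGrid:
    """Monotonically increasing energy bin edges in eV."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 4:
            raise ValueError("energy grid needs at least 3 bins (4 edges)")
        if edges[0] <= 0.0:
            raise ValueError("energies must be positive")
        if not np.all(np.diff(edges) > 0.0):
            raise ValueError("energy edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def lower(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def upper(self) -> np.ndarray:
        return self.edges[1:]

    @property
    def centers(self) -> np.ndarray:
        """Geometric-mean bin centers, the natural choice on a log grid."""
        return np.sqrt(self.lower * self.upper)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def bin_index(self, energy_ev: float) -> int:
        """Index of the bin containing ``energy_ev`` (edges go to the upper bin)."""
        if not (self.edges[0] <= energy_ev <= self.edges[-1]):
            raise ValueError(f"{energy_ev} eV outside grid range")
        idx = int(np.searchsorted(self.edges, energy_ev, side="right") - 1)
        return min(idx, self.n_bins - 1)


def make_energy_grid(emin_ev: float, emax_ev: float, n_bins: int = 100) -> EnergyGrid:
    """Log-spaced energy grid from ``emin_ev`` to ``emax_ev``.

    Defaults elsewhere use 1e-3 eV .. 1e7 eV so that the grid spans the
    thermal through fast range.
    """
    if emin_ev <= 0.0 or emax_ev <= emin_ev:
        raise ValueError("need 0 < emin < emax")
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    edges = np.logspace(np.log10(emin_ev), np.log10(emax_ev), n_bins + 1)
    return EnergyGrid(edges)


def classify_energy(energy_ev: float) -> str:
    """Band label of a neutron energy.

    Thermal iff E < 0.5 eV, fast iff E > 10 keV, otherwise epithermal;
    both boundary energies are assigned to the epithermal band.
    """
    if energy_ev <= 0.0:
        raise ValueError("energy must be positive")
    if energy_ev < THERMAL_MAX_EV:
        return BAND_THERMAL
    if energy_ev > FAST_MIN_EV:
        return BAND_FAST
    return BAND_EPITHERMAL


def band_masks(grid: EnergyGrid) -> dict[str, np.ndarray]:
    """Boolean per-bin masks by band, classifying bins by their centers."""
    c = grid.centers
    thermal = c < THERMAL_MAX_EV
    fast = c > FAST_MIN_EV
    return {
        BAND_THERMAL: thermal,
        BAND_EPITHERMAL: ~(thermal | fast),
        BAND_FAST: fast,
    }


@dataclass
class BeamSpectrum:
    """Energy-binned tallies at the beam port.

    ``flux_per_bin`` and ``current_per_bin`` are in cm^-2 s^-1; the current
    is the directed component of the flux, so it cannot exceed the flux in
    any bin.  ``gamma_dose_rate`` and ``fast_dose_rate`` are the scalar
    in-air dose-rate tallies in Gy s^-1.
    """

    grid: EnergyGrid
    flux_per_bin: np.ndarray
    current_per_bin: np.ndarray
    gamma_dose_rate: float
    fast_dose_rate: float
    port_radius_cm: float = 6.0
    name: str = field(default="beam")

    def __post_init__(self) -> None:
        self.flux_per_bin = np.asarray(self.flux_per_bin, dtype=float)
        self.current_per_bin = np.asarray(self.current_per_bin, dtype=float)
        n = self.grid.n_bins
        if self.flux_per_bin.shape != (n,) or self.current_per_bin.shape != (n,):
            raise ValueError("tally arrays must have one entry per energy bin")
        if np.any(self.flux_per_bin < 0.0) or np.any(self.current_per_bin < 0.0):
            raise ValueError("tallies must be nonnegative")
        if self.gamma_dose_rate < 0.0 or self.fast_dose_rate < 0.0:
            raise ValueError("dose-rate tallies must be nonnegative")
        # small tolerance: currents produced by scaling flux may differ in ulps
        if np.any(self.current_per_bin > self.flux_per_bin * (1.0 + 1e-12) + 1e-300):
            raise ValueError("current cannot exceed flux in any bin")
        if self.port_radius_cm <= 0.0:
            raise ValueError("port radius must be positive")

    @property
    def total_flux(self) -> float:
        return float(self.flux_per_bin.sum())

    @property
    def total_current(self) -> float:
        return float(self.current_per_bin.sum())

    def mean_energy_ev(self) -> float:
        """Flux-weighted mean neutron energy."""
        phi = self.total_flux
        if phi <= 0.0:
            return 0.0
        return float(np.dot(self.flux_per_bin, self.grid.centers) / phi)

    def scaled(self, factor: float) -> "BeamSpectrum":
        """Spectrum of the same beam operated at ``factor`` times the intensity.

        All tallies (neutron and photon alike) scale with the source
        strength, so a factor of zero represents the beam switched off.
        """
        if factor < 0.0:
            raise ValueError("scale factor must be nonnegative")
        return BeamSpectrum(
            grid=self.grid,
            flux_per_bin=self.flux_per_bin * factor,
            current_per_bin=self.current_per_bin * factor,
            gamma_dose_rate=self.gamma_dose_rate * factor,
            fast_dose_rate=self.fast_dose_rate * factor,
            port_radius_cm=self.port_radius_cm,
            name=self.name,
        )


def band_integrals(spectrum: BeamSpectrum) -> tuple[float, float, float, float]:
    """Band-integrated fluxes and total current.

    Returns ``(phi_thermal, phi_epithermal, phi_fast, J_total)``.  Bins are
    assigned wholly to the band of their (geometric) center; the current is
    summed over all bins regardless of band.
    """
    if spectrum.grid.n_bins == 0:
        raise ValueError("empty spectrum")
    masks = band_masks(spectrum.grid)
    phi = spectrum.flux_per_bin
    return (
        float(phi[masks[BAND_THERMAL]].sum()),
        float(phi[masks[BAND_EPITHERMAL]].sum()),
        float(phi[masks[BAND_FAST]].sum()),
        spectrum.total_current,
    )


# ---------------------------------------------------------------------------
# tabular spectrum file I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("gamma_dose_rate", "fast_dose_rate", "port_radius_cm")


def write_spectrum(spectrum: BeamSpectrum, path) -> None:
    """Write a spectrum as CSV with ``# key = value`` header lines."""
    df = pd.DataFrame(
        {
            "energy_low_eV": spectrum.grid.lower,
            "energy_high_eV": spectrum.grid.upper,
            "flux": spectrum.flux_per_bin,
            "current": spectrum.current_per_bin,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# name = {spectrum.name}\n")
        fh.write(f"# gamma_dose_rate = {spectrum.gamma_dose_rate!r}\n")
        fh.write(f"# fast_dose_rate = {spectrum.fast_dose_rate!r}\n")
        fh.write(f"# port_radius_cm = {spectrum.port_radius_cm!r}\n")
        df.to_csv(fh, index=False)


def read_spectrum(path) -> BeamSpectrum:
    """Read a spectrum written by :func:`write_spectrum`."""
    header: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"spectrum file missing header key {key!r}")
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    edges = np.concatenate(
        [df["energy_low_eV"].to_numpy(), df["energy_high_eV"].to_numpy()[-1:]]
    )
    return BeamSpectrum(
        grid=EnergyGrid(edges),
        flux_per_bin=df["flux"].to_numpy(),
        current_per_bin=df["current"].to_numpy(),
        gamma_dose_rate=float(header["gamma_dose_rate"]),
        fast_dose_rate=float(header["fast_dose_rate"]),
        port_radius_cm=float(header["port_radius_cm"]),
        name=header.get("name", "beam"),
    )
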