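"""Photon interaction physics: cross sections, Compton sampling, spectra.

The data layer behind the transport engine.  Total attenuation is modelled
as incoherent (Compton) scattering on free electrons via the Klein-Nishina
cross section plus a power-law photoelectric term calibrated to water;
coherent scattering and pair production are neglected, which is adequate
for megavoltage beams where Compton dominates.  Valid energy range:
0.01-10 MeV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Material, effective_z, electrons_per_gram

__all__ = [
    "ELECTRON_REST_MEV",
    "Attenuation",
    "klein_nishina_total_cm2",
    "klein_nishina_differential",
    "attenuation_coefficient",
    "klein_nishina_sample",
    "compton_scattered_energy",
    "Spectrum",
    "monoenergetic_spectrum",
    "bremsstrahlung_spectrum",
    "DEFAULT_SPECTRA",
]

ELECTRON_REST_MEV = 0.51099895
_RE_CM = 2.8179403262e-13  # classical electron radius
ENERGY_RANGE_MEV = (0.01, 10.0)

# Photoelectric mass coefficient tau/rho = _PE_C * Zeff^3.8 * E^-3.2 (cm^2/g),
# calibrated so water at 30 keV gives ~0.14 cm^2/g.
_PE_ZEFF_EXP = 3.8
_PE_E_EXP = 3.2
_PE_C = 0.14 * 7.42 ** (-_PE_ZEFF_EXP) * 0.03**_PE_E_EXP


def _check_energy(energy) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    if np.any(e < ENERGY_RANGE_MEV[0]) or np.any(e > ENERGY_RANGE_MEV[1]):
        raise ValueError(
            f"photon energy outside tabulated range {ENERGY_RANGE_MEV} MeV"
        )
    return e


def klein_nishina_total_cm2(energy_mev) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    eps = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    t = 1.0 + 2.0 * eps
    log_t = np.log(t)
    sigma = (
        (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / t - log_t / eps)
        + log_t / (2.0 * eps)
        - (1.0 + 3.0 * eps) / t**2
    )
    return 2.0 * np.pi * _RE_CM**2 * sigma


def klein_nishina_differential(energy_mev: float, cos_theta) -> np.ndarray:
    """Klein-Nishina d(sigma)/d(Omega) per electron (cm^2/sr)."""
    eps = float(energy_mev) / ELECTRON_REST_MEV
    mu = np.asarray(cos_theta, dtype=float)
    r = 1.0 / (1.0 + eps * (1.0 - mu))  # E'/E
    return 0.5 * _RE_CM**2 * r**2 * (r + 1.0 / r - (1.0 - mu**2))


@dataclass(frozen=True)
class Attenuation:
    """Linear attenuation split (cm^-1)."""

    total: float
    compton: float
    photoelectric: float


def attenuation_coefficient(material: Material, energy_mev: float) -> Attenuation:
    """Linear attenuation coefficient of a material at one energy.

    mu = rho * (sigma_KN * electrons/g + photoelectric term); scales
    linearly with density at fixed composition.
    """
    e = float(_check_energy(energy_mev))
    mu_c = material.density * electrons_per_gram(material) * float(
        klein_nishina_total_cm2(e)
    )
    zeff = effective_z(material)
    mu_pe = material.density * _PE_C * zeff**_PE_ZEFF_EXP * e ** (-_PE_E_EXP)
    return Attenuation(total=mu_c + mu_pe, compton=mu_c, photoelectric=mu_pe)


def compton_scattered_energy(energy_mev, cos_theta) -> np.ndarray:
    """Compton relation: scattered photon energy for a given angle."""
    eps = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    return np.asarray(energy_mev) / (1.0 + eps * (1.0 - np.asarray(cos_theta)))


def klein_nishina_sample(
    energy_mev, rng: np.random.Generator, size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample Compton scattering angles from the Klein-Nishina distribution.

    Rejection sampling with a constant envelope in cos(theta): the
    angular kernel r^2 (r + 1/r - sin^2 theta) attains its maximum 2 at
    theta = 0 for every energy.  Returns ``(cos_theta, scattered_energy)``;
    scattered energy always obeys the Compton relation and never exceeds
    the incident energy.

    ``energy_mev`` may be a scalar (with ``size`` draws) or an array of
    per-photon energies.
    """
    if size is None:
        energies = np.asarray(energy_mev, dtype=float)
        scalar = energies.ndim == 0
        energies = np.atleast_1d(energies)
    else:
        energies = np.full(int(size), float(energy_mev))
        scalar = False

    eps = energies / ELECTRON_REST_MEV
    n = energies.size
    cos_out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        mu = rng.uniform(-1.0, 1.0, size=pending.size)
        r = 1.0 / (1.0 + eps[pending] * (1.0 - mu))
        f = r * r * (r + 1.0 / r - (1.0 - mu * mu))
        accept = rng.uniform(0.0, 2.0, size=pending.size) < f
        cos_out[pending[accept]] = mu[accept]
        pending = pending[~accept]
    e_out = compton_scattered_energy(energies, cos_out)
    if scalar:
        return float(cos_out[0]), float(e_out[0])
    return cos_out, e_out


# -- beam spectra ---------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon fluence spectrum: energies (MeV) and relative weights."""

    energies_mev: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("spectrum weights must be >= 0 and normalizable")
        if len(self.energies_mev) != len(self.weights):
            raise ValueError("energies and weights differ in length")

    @property
    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    @property
    def mean_energy_mev(self) -> float:
        return float(np.dot(self.probabilities, self.energies_mev))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.choice(len(self.energies_mev), size=size, p=self.probabilities)
        return np.asarray(self.energies_mev)[idx]


def monoenergetic_spectrum(energy_mev: float) -> Spectrum:
    return Spectrum((float(energy_mev),), (1.0,))


def bremsstrahlung_spectrum(
    e_max_mev: float, n_bins: int = 30, e_min_mev: float = 0.25
) -> Spectrum:
    """Parameterized thick-target bremsstrahlung-like spectrum.

    Weight ~ (E_max - E)/E softened by a low-energy filtration factor
    exp(-0.12/E); a plausible stand-in for clinical 4/6 MV fluence spectra,
    not a reproduction of any published linac spectrum.
    """
    if e_max_mev <= e_min_mev:
        raise ValueError("e_max must exceed e_min")
    e = np.linspace(e_min_mev, e_max_mev, n_bins + 1)[:-1] + 0.5 * (
        e_max_mev - e_min_mev
    ) / n_bins
    w = (e_max_mev - e) / e * np.exp(-0.12 / e)
    return Spectrum(tuple(e.tolist()), tuple(w.tolist()))


#: Default spectra by nominal accelerating-potential label.
DEFAULT_SPECTRA: dict[str, Spectrum] = {
    "4MV": bremsstrahlung_spectrum(4.0),
    "6MV": bremsstrahlung_spectrum(6.0),
}
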