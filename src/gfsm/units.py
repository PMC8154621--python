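"""Spectroscopic unit conversions and derived quantities.

Energies live in eV at the user-facing boundary and in Hartree atomic units
inside the computational core; these helpers are the only place the two meet.
Constants are CODATA: hc = 1239.84198 eV nm, 1 hartree = 27.211386245988 eV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HC_EV_NM",
    "HARTREE_EV",
    "BIOLOGICAL_WINDOW_NM",
    "ev_to_nm",
    "nm_to_ev",
    "ev_to_au",
    "au_to_ev",
    "two_photon_wavelength",
    "oscillator_strength",
    "in_biological_window",
    "TransitionSummary",
]

HC_EV_NM = 1239.84198
HARTREE_EV = 27.211386245988

#: First/second biological transparency window of tissue (inclusive bounds).
BIOLOGICAL_WINDOW_NM = (650.0, 1100.0)


def _require_positive(energy: float, what: str = "energy") -> None:
    if not energy > 0:
        raise ValueError(f"{what} must be positive, got {energy!r}")


def ev_to_nm(energy_ev: float) -> float:
    """Photon wavelength (nm) of a transition energy in eV."""
    _require_positive(energy_ev)
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    _require_positive(wavelength_nm, "wavelength")
    return HC_EV_NM / wavelength_nm


def ev_to_au(energy_ev: float) -> float:
    return energy_ev / HARTREE_EV


def au_to_ev(energy_au: float) -> float:
    return energy_au * HARTREE_EV


def two_photon_wavelength(delta_e_ev: float) -> int:
    """Degenerate two-photon excitation wavelength, nearest nm.

    Two photons of equal energy sum to the transition energy, so the
    excitation wavelength is twice the one-photon wavelength.
    """
    _require_positive(delta_e_ev)
    return int(round(2.0 * HC_EV_NM / delta_e_ev))


def oscillator_strength(delta_e_au: float, mu) -> float:
    """Dimensionless oscillator strength ``f = (2/3) dE |mu|^2`` (au inputs).

    ``mu`` may be a 3-vector or a scalar magnitude.
    """
    _require_positive(delta_e_au)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    return float(2.0 / 3.0 * delta_e_au * np.sum(mu**2))


def in_biological_window(wavelength_nm: float, window=BIOLOGICAL_WINDOW_NM) -> bool:
    """True when the wavelength falls in the tissue transparency window
    (650-1100 nm by default, bounds inclusive)."""
    _require_positive(wavelength_nm, "wavelength")
    lo, hi = window
    return lo <= wavelength_nm <= hi


@dataclass(frozen=True)
class TransitionSummary:
    """One-/two-photon wavelength bookkeeping for a single transition."""

    delta_e_ev: float
    lambda_1pa_nm: float
    lambda_2pa_nm: int
    f: float
    in_window: bool

    @classmethod
    def from_transition(cls, delta_e_ev: float, f: float) -> "TransitionSummary":
        lam2 = two_photon_wavelength(delta_e_ev)
        return cls(
            delta_e_ev=delta_e_ev,
            lambda_1pa_nm=ev_to_nm(delta_e_ev),
            lambda_2pa_nm=lam2,
            f=f,
            in_window=in_biological_window(lam2),
        )
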