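"""Synthetic few-state systems and the packaged BOPHY reference dataset.

The generator emulates the shape of coupled-cluster (CC2-like) excited-state
data for two chromophore architectures:

* **dipolar** (donor-acceptor, low symmetry): nonzero permanent and
  fluctuation dipoles on the excited states, transition dipoles between every
  state pair;
* **quadrupolar / centrosymmetric** (D-A-A-D): parity-labelled states with
  transition dipoles only between opposite-parity states and no permanent
  dipoles, which enforces the mutual exclusion of one- and two-photon
  activity for a given final state.

Energies are drawn in the 2.6-4.2 eV span typical of BF2-bridged
chromophores and transition-dipole magnitudes are sized so that the implied
oscillator strengths stay below ~2 — the regime of the packaged reference
compounds.  One integer seed fully determines a draw; no global RNG state is
touched.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import GERADE, UNGERADE, ElectronicStateSet
from .units import ev_to_au

__all__ = [
    "SyntheticSpec",
    "CompoundRecord",
    "make_system",
    "calibrate_transition_dipole",
    "random_rotation",
    "flip_state_sign",
    "bophy_reference_table",
    "bophy_reference_frame",
    "DIPOLAR_COMPOUNDS",
]

#: Reference compounds with dipolar (donor-acceptor) architecture; the
#: remaining eight of the thirteen are quadrupolar.
DIPOLAR_COMPOUNDS = frozenset({3, 4, 5, 10, 12})

DIPOLAR = "dipolar"
QUADRUPOLAR = "quadrupolar"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic few-state draw.

    Ranges are (low, high) pairs; energies in eV, dipoles in au.  The
    fluctuation-dipole range controls the permanent-dipole structure of
    dipolar systems and is ignored for quadrupolar ones (whose permanent
    dipoles are identically zero).
    """

    polarity_class: str
    seed: int
    n_excited: int = 3
    energy_range_ev: tuple[float, float] = (2.6, 4.2)
    transition_dipole_range_au: tuple[float, float] = (0.5, 3.5)
    fluctuation_dipole_range_au: tuple[float, float] = (0.5, 5.0)

    def __post_init__(self):
        if self.polarity_class not in (DIPOLAR, QUADRUPOLAR):
            raise ValueError(
                f"polarity_class must be {DIPOLAR!r} or {QUADRUPOLAR!r}"
            )
        if self.n_excited < 1:
            raise ValueError("need at least one excited state")
        for name in ("energy_range_ev", "transition_dipole_range_au",
                     "fluctuation_dipole_range_au"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be ordered and non-negative")
        if self.energy_range_ev[0] <= 0:
            raise ValueError("energies must be positive")


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _draw_vectors(rng, n, magnitude_range):
    mags = rng.uniform(*magnitude_range, size=n)
    return _unit_vectors(rng, n) * mags[:, None]


def make_system(spec: SyntheticSpec) -> ElectronicStateSet:
    """Draw one reproducible few-state system from a spec.

    Excitation energies are sorted ascending.  Quadrupolar draws label the
    ground state gerade and alternate u, g, u, ... over the excited states,
    so S1 is one-photon allowed and S2 two-photon allowed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_excited + 1
    energies_ev = np.sort(rng.uniform(*spec.energy_range_ev, size=spec.n_excited))
    energies = np.concatenate([[0.0], ev_to_au(energies_ev)])
    mu = np.zeros((n, n, 3))

    if spec.polarity_class == DIPOLAR:
        pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
        vecs = _draw_vectors(rng, len(pairs), spec.transition_dipole_range_au)
        for (p, q), vec in zip(pairs, vecs):
            mu[p, q] = vec
            mu[q, p] = vec
        # permanent dipoles: ground dipole plus a per-state fluctuation,
        # both sized by the fluctuation range so (0, 0) zeroes them all
        ground = _draw_vectors(rng, 1, spec.fluctuation_dipole_range_au)[0]
        fluct = _draw_vectors(rng, spec.n_excited, spec.fluctuation_dipole_range_au)
        mu[0, 0] = ground
        for k in range(1, n):
            mu[k, k] = ground + fluct[k - 1]
        return ElectronicStateSet(energies, mu)

    parity = (GERADE,) + tuple(
        UNGERADE if k % 2 == 1 else GERADE for k in range(1, n)
    )
    pairs = [
        (p, q)
        for p in range(n)
        for q in range(p + 1, n)
        if parity[p] != parity[q]
    ]
    vecs = _draw_vectors(rng, len(pairs), spec.transition_dipole_range_au)
    for (p, q), vec in zip(pairs, vecs):
        mu[p, q] = vec
        mu[q, p] = vec
    return ElectronicStateSet(energies, mu, parity=parity)


def calibrate_transition_dipole(delta_e_ev: float, f: float) -> float:
    """Transition-dipole magnitude (au) implied by an oscillator strength.

    Inverts ``f = (2/3) dE |mu|^2``: ``|mu| = sqrt(3 f / (2 dE_au))``.
    """
    if delta_e_ev <= 0:
        raise ValueError("excitation energy must be positive")
    if f < 0:
        raise ValueError("oscillator strength must be non-negative")
    return float(np.sqrt(3.0 * f / (2.0 * ev_to_au(delta_e_ev))))


def random_rotation(system: ElectronicStateSet, seed: int) -> ElectronicStateSet:
    """Apply one uniformly random proper rotation to every dipole vector.

    Energies, parities and all pairwise dipole angles are unchanged; any
    rotationally averaged quantity must be invariant under this map.
    """
    R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()

    def rot(mat):
        return np.einsum("ij,pqj->pqi", R, mat)

    return ElectronicStateSet(
        system.energies.copy(),
        rot(system.dipoles_right),
        dipoles_left=None if system.dipoles_left is None else rot(system.dipoles_left),
        parity=system.parity,
    )


def flip_state_sign(system: ElectronicStateSet, K: int) -> ElectronicStateSet:
    """Flip the arbitrary phase of state K: negate every transition dipole
    involving K (permanent dipoles are phase-invariant).  All two-photon
    strengths must be unchanged."""

    def flip(mat):
        out = mat.copy()
        out[K, :] = -out[K, :]
        out[:, K] = -out[:, K]  # [K, K] negated twice, i.e. phase-invariant
        return out

    return ElectronicStateSet(
        system.energies.copy(),
        flip(system.dipoles_right),
        dipoles_left=None if system.dipoles_left is None else flip(system.dipoles_left),
        parity=system.parity,
    )


@dataclass(frozen=True)
class CompoundRecord:
    """One compound of the packaged RI-CC2/cc-pVDZ reference dataset.

    Excitation energies in eV, oscillator strengths dimensionless, two-photon
    strengths in units of 1e4 au (the dataset's printed unit).  Few-state
    model columns are ``None`` where the dataset leaves them blank.
    """

    compound_id: int
    polarity_class: str
    de_s1_ev: float
    f_s1: float
    delta_s1: float
    delta_s1_2sm: float | None
    de_s2_ev: float
    f_s2: float
    delta_s2: float
    delta_s2_3sm: float | None

    def energy(self, transition: str) -> float:
        return self.de_s1_ev if transition == "S0->S1" else self.de_s2_ev

    def strength(self, transition: str) -> float:
        return self.delta_s1 if transition == "S0->S1" else self.delta_s2

    def oscillator(self, transition: str) -> float:
        return self.f_s1 if transition == "S0->S1" else self.f_s2


def bophy_reference_frame() -> pd.DataFrame:
    """The packaged 13-compound reference dataset as a DataFrame."""
    ref = importlib.resources.files("gfsm.data") / "bophy_cc2_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def bophy_reference_table() -> list[CompoundRecord]:
    """The packaged reference dataset: 13 BF2-bridged chromophores with
    RI-CC2 one-photon energies, oscillator strengths and two-photon
    strengths for the S0->S1 and S0->S2 transitions, plus two-state-model
    (S0->S1) and three-state-model (S0->S2) strengths where available."""
    df = bophy_reference_frame()

    def opt(x):
        return None if pd.isna(x) else float(x)

    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                compound_id=int(row.compound),
                polarity_class=str(row.polarity),
                de_s1_ev=float(row.dE_S0S1_eV),
                f_s1=float(row.f_S0S1),
                delta_s1=float(row.delta_S0S1_1e4au),
                delta_s1_2sm=opt(row.delta2SM_S0S1_1e4au),
                de_s2_ev=float(row.dE_S0S2_eV),
                f_s2=float(row.f_S0S2),
                delta_s2=float(row.delta_S0S2_1e4au),
                delta_s2_3sm=opt(row.delta3SM_S0S2_1e4au),
            )
        )
    return records
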