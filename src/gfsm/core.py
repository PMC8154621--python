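"""Sum-over-states two-photon transition moments and generalized few-state models.

This module evaluates degenerate two-photon absorption (2PA) transition
strengths for a finite electronic state space.  The central quantity is the
rotationally averaged two-photon transition strength

.. math::

    \\delta_{0J} = \\frac{1}{15} \\sum_{a,b} \\left[
        F\\, S^{L}_{aa} S^{R}_{bb} + G\\, S^{L}_{ab} S^{R}_{ab}
        + H\\, S^{L}_{ab} S^{R}_{ba} \\right]

with polarization weights ``F = G = H = 2`` for a single linearly polarized
monochromatic beam, and second-order transition moments

.. math::

    S_{ab} = \\sum_{K} \\frac{\\mu_a^{0K} \\mu_b^{KJ} + \\mu_b^{0K}
        \\mu_a^{KJ}}{E_K - E_J/2}

summed over every state of the set (ground state included).  When the sum is
truncated to a few states, inserting the truncated moments into the average
yields the generalized few-state model (GFSM): a closed-form decomposition of
:math:`\\delta` into terms :math:`\\delta_{0JKL}` built from four dipole
magnitudes, three interdipole-angle channels, and two energy denominators.
The full sum over the complete state set serves as the internal oracle for
every truncated model.

All quantities are in Hartree atomic units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectronicStateSet",
    "TwoPhotonTensor",
    "FsmTerm",
    "FsmResult",
    "ResonanceError",
    "second_order_moment",
    "rotational_average",
    "full_sos_delta",
    "gfsm_term",
    "fsm_delta",
    "channel_classification",
    "term_label",
    "RESONANCE_TOL",
    "ZERO_DIPOLE_TOL",
    "POLARIZATION_WEIGHTS",
    "TERM_CONSTANT",
]

#: Minimum allowed |E_K - E_J/2| before an intermediate state is considered
#: resonant with half the final-state energy (au).  No linewidth/damping is
#: modelled, so a near-zero denominator is an error, not a feature.
RESONANCE_TOL = 1e-8

#: Dipole magnitude below which a GFSM term is set to exactly zero; the
#: magnitude prefactor vanishes before the interdipole cosines become 0/0.
ZERO_DIPOLE_TOL = 1e-12

#: (F, G, H) polarization weights for one linearly polarized beam.
POLARIZATION_WEIGHTS = (2.0, 2.0, 2.0)

#: Constant multiplying every GFSM term delta_0JKL.  Expanding the
#: (1/15)[F Saa Sbb + G Sab Sab + H Sab Sba] contraction of the symmetrized
#: moments into dipole dot products gives (F + G + H) * 4/30 = 8/15 per
#: ordered intermediate pair; the all-states GFSM then reproduces the full
#: sum-over-states value identically (asserted in the test suite).
TERM_CONSTANT = (
    4.0 * (POLARIZATION_WEIGHTS[0] + POLARIZATION_WEIGHTS[1] + POLARIZATION_WEIGHTS[2]) / 45.0
)

GERADE = "gerade"
UNGERADE = "ungerade"


class ResonanceError(ValueError):
    """An intermediate state sits at (or numerically too close to) half the
    final-state excitation energy, making an energy denominator singular."""


def _as_parity(labels) -> tuple[str, ...]:
    out = []
    for lab in labels:
        lab = str(lab).lower()
        if lab in ("g", GERADE):
            out.append(GERADE)
        elif lab in ("u", UNGERADE):
            out.append(UNGERADE)
        else:
            raise ValueError(f"parity label must be gerade/ungerade, got {lab!r}")
    return tuple(out)


@dataclass(frozen=True)
class ElectronicStateSet:
    """A few-state electronic system: excitation energies and dipole moments.

    Parameters
    ----------
    energies : (n,) array
        Excitation energies in au relative to the ground state;
        ``energies[0] == 0`` and all excited energies positive.
    dipoles_right : (n, n, 3) array
        Dipole-moment matrix in au.  Off-diagonal entries are transition
        dipoles ``mu^{PQ}``; diagonal entries are permanent state dipoles.
    dipoles_left : (n, n, 3) array, optional
        Left moments of a non-Hermitian (e.g. coupled-cluster) theory.  When
        absent the set is Hermitian and ``dipoles_right`` must be symmetric
        under bra/ket exchange.
    parity : tuple of {"gerade", "ungerade"}, optional
        Per-state inversion-symmetry labels for centrosymmetric systems.
        When present, dipoles between same-parity states and all permanent
        dipoles must vanish.
    """

    energies: np.ndarray
    dipoles_right: np.ndarray
    dipoles_left: np.ndarray | None = None
    parity: tuple[str, ...] | None = None

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.dipoles_right, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "dipoles_right", mu)
        if self.dipoles_left is not None:
            object.__setattr__(
                self, "dipoles_left", np.asarray(self.dipoles_left, dtype=float)
            )
        if self.parity is not None:
            object.__setattr__(self, "parity", _as_parity(self.parity))
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        energies,
        dipoles: dict,
        dipoles_left: dict | None = None,
        parity=None,
        hermitianize: bool = True,
    ) -> "ElectronicStateSet":
        """Build a set from sparse ``{(P, Q): 3-vector}`` dipole maps.

        With ``hermitianize`` (and no left map) a pair given in one
        orientation only is mirrored to the other.
        """
        e = np.asarray(energies, dtype=float)
        n = e.shape[0]

        def dense(pairs):
            arr = np.zeros((n, n, 3))
            for (p, q), vec in pairs.items():
                arr[p, q] = np.asarray(vec, dtype=float)
            return arr

        mu = dense(dipoles)
        if dipoles_left is None and hermitianize:
            for (p, q) in dipoles:
                if p != q and (q, p) not in dipoles:
                    mu[q, p] = mu[p, q]
        left = dense(dipoles_left) if dipoles_left is not None else None
        return cls(e, mu, dipoles_left=left, parity=parity)

    # -- basic queries ----------------------------------------------------

    @property
    def n_states(self) -> int:
        return int(self.energies.shape[0])

    @property
    def is_hermitian(self) -> bool:
        return self.dipoles_left is None

    def moments(self, side: str = "right") -> np.ndarray:
        """Dipole matrix for the requested side; Hermitian sets serve the
        right matrix for both sides."""
        if side == "left":
            return self.dipoles_left if self.dipoles_left is not None else self.dipoles_right
        if side == "right":
            return self.dipoles_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    # -- validation -------------------------------------------------------

    def validate(self, atol: float = 1e-9) -> None:
        n = self.n_states
        if self.energies.ndim != 1:
            raise ValueError("energies must be a 1-D array")
        if abs(self.energies[0]) > atol:
            raise ValueError("ground-state energy must be zero")
        if n > 1 and np.any(self.energies[1:] <= 0):
            raise ValueError("excited-state energies must be positive")
        if self.dipoles_right.shape != (n, n, 3):
            raise ValueError(f"dipoles_right must have shape ({n}, {n}, 3)")
        if not np.all(np.isfinite(self.dipoles_right)) or not np.all(
            np.isfinite(self.energies)
        ):
            raise ValueError("non-finite energies or dipoles")
        if self.dipoles_left is not None:
            if self.dipoles_left.shape != (n, n, 3):
                raise ValueError(f"dipoles_left must have shape ({n}, {n}, 3)")
            if not np.all(np.isfinite(self.dipoles_left)):
                raise ValueError("non-finite left dipoles")
        elif not np.allclose(
            self.dipoles_right, self.dipoles_right.transpose(1, 0, 2), atol=atol
        ):
            raise ValueError(
                "Hermitian state set requires dipoles_right symmetric under "
                "bra/ket exchange (supply dipoles_left for a non-Hermitian set)"
            )
        if self.parity is not None:
            if len(self.parity) != n:
                raise ValueError("need one parity label per state")
            for p, q in itertools.product(range(n), repeat=2):
                if self.parity[p] == self.parity[q] and np.any(
                    np.abs(self.dipoles_right[p, q]) > atol
                ):
                    raise ValueError(
                        f"parity forbids a dipole between states {p} and {q} "
                        f"(both {self.parity[p]})"
                    )

    # -- convention helpers -----------------------------------------------

    def with_fluctuation_dipoles(self) -> "ElectronicStateSet":
        """Return a copy with diagonal dipoles shifted by the ground-state
        dipole, ``mu_bar^{KK} = mu^{KK} - mu^{00}`` (so ``mu_bar^{00} = 0``).

        At the degenerate photon energy ``omega = E_J/2`` this shift leaves
        the full sum-over-states value and every few-state-model total
        unchanged; only the per-term attribution moves (all diagonal weight
        collapses onto the ``delta_0JJJ``-type terms).
        """

        def shift(mat):
            out = mat.copy()
            idx = np.arange(self.n_states)
            out[idx, idx] -= mat[0, 0]
            return out

        return ElectronicStateSet(
            self.energies.copy(),
            shift(self.dipoles_right),
            dipoles_left=None if self.dipoles_left is None else shift(self.dipoles_left),
            parity=self.parity,
        )


@dataclass(frozen=True)
class TwoPhotonTensor:
    """3x3 second-order transition moment tensor(s) at ``omega = E_J/2``."""

    final_state: int
    photon_energy: float
    left: np.ndarray | None = None
    right: np.ndarray | None = None

    def single(self) -> np.ndarray:
        """The one populated matrix (for single-side construction)."""
        if (self.left is None) == (self.right is None):
            raise ValueError("expected exactly one populated side")
        return self.left if self.left is not None else self.right


def _check_final_state(system: ElectronicStateSet, J: int) -> None:
    if not (0 < J < system.n_states):
        raise IndexError(
            f"final state J={J} outside the excited states of a "
            f"{system.n_states}-state set"
        )


def _denominators(system: ElectronicStateSet, J: int, resonance_tol: float) -> np.ndarray:
    omega = system.energies[J] / 2.0
    den = system.energies - omega
    bad = np.abs(den) < resonance_tol
    if np.any(bad):
        which = np.nonzero(bad)[0].tolist()
        raise ResonanceError(
            f"state(s) {which} lie within {resonance_tol:g} au of half the "
            f"final-state energy E_{J}/2 = {omega:g} au"
        )
    return den


def second_order_moment(
    system: ElectronicStateSet,
    J: int,
    side: str = "right",
    resonance_tol: float = RESONANCE_TOL,
) -> TwoPhotonTensor:
    """Second-order transition moment tensor for the 0 -> J transition.

    Evaluates ``S_ab = sum_K [mu_a^{0K} mu_b^{KJ} + mu_b^{0K} mu_a^{KJ}]
    / (E_K - E_J/2)`` over *all* states of the set at the degenerate photon
    energy ``omega = E_J/2``, using the requested side's dipole matrix.  The
    result is symmetric under Cartesian index exchange.

    Raises
    ------
    IndexError
        If ``J`` is the ground state or outside the set.
    ResonanceError
        If any denominator magnitude falls below ``resonance_tol``.
    """
    _check_final_state(system, J)
    den = _denominators(system, J, resonance_tol)
    mu = system.moments(side)
    # A_ab = sum_K mu_a^{0K} mu_b^{KJ} / den_K ; S = A + A^T
    A = np.einsum("k,ka,kb->ab", 1.0 / den, mu[0], mu[:, J])
    S = A + A.T
    omega = float(system.energies[J] / 2.0)
    if side == "left":
        return TwoPhotonTensor(final_state=J, photon_energy=omega, left=S)
    return TwoPhotonTensor(final_state=J, photon_energy=omega, right=S)


def rotational_average(
    left: np.ndarray,
    right: np.ndarray,
    weights: tuple[float, float, float] = POLARIZATION_WEIGHTS,
) -> float:
    """Isotropic orientational average of two second-order moment tensors.

    ``(1/15) sum_ab [F L_aa R_bb + G L_ab R_ab + H L_ab R_ba]`` with
    ``(F, G, H) = weights``.  For ``left == right`` (Hermitian theory) the
    result is a full contraction of a symmetric tensor with itself and is
    therefore non-negative.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != (3, 3) or right.shape != (3, 3):
        raise ValueError("tensors must be 3x3")
    if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
        raise ValueError("non-finite tensor input")
    F, G, H = weights
    return float(
        (
            F * np.trace(left) * np.trace(right)
            + G * np.sum(left * right)
            + H * np.sum(left * right.T)
        )
        / 15.0
    )


def full_sos_delta(
    system: ElectronicStateSet, J: int, resonance_tol: float = RESONANCE_TOL
) -> float:
    """Two-photon transition strength from the complete sum over states.

    Composes the left and right second-order moments over every state of the
    set and rotationally averages them.  Within the truncated state space
    this is the reference ("response-like") value against which the few-state
    models are judged.
    """
    SL = second_order_moment(system, J, side="left", resonance_tol=resonance_tol).single()
    SR = second_order_moment(system, J, side="right", resonance_tol=resonance_tol).single()
    return rotational_average(SL, SR)


def term_label(J: int, K: int, L: int) -> str:
    """Conventional name of a GFSM term, e.g. ``delta_0211``."""
    if max(J, K, L) < 10:
        return f"delta_0{J}{K}{L}"
    return f"delta_0,{J},{K},{L}"


@dataclass(frozen=True)
class FsmTerm:
    """One GFSM contribution ``delta_0JKL``.

    ``value = TERM_CONSTANT * magnitude_prefactor * sum(channels)`` where the
    three channels are the interdipole cosine products
    ``cos t(0K,KJ) cos t(0L,LJ)``, ``cos t(0K,0L) cos t(KJ,LJ)`` and
    ``cos t(0K,LJ) cos t(KJ,0L)``, and ``magnitude_prefactor`` is the product
    of the four dipole magnitudes over the two energy denominators
    ``(E_K - E_J/2)(E_L - E_J/2)``.  A term containing a (numerically) zero
    dipole is exactly zero with ``channels=None``.
    """

    final_state: int
    intermediates: tuple[int, int]
    value: float
    channels: tuple[float, float, float] | None
    magnitude_prefactor: float
    denominators: tuple[float, float]

    @property
    def label(self) -> str:
        K, L = self.intermediates
        return term_label(self.final_state, K, L)


def gfsm_term(
    system: ElectronicStateSet,
    J: int,
    K: int,
    L: int,
    resonance_tol: float = RESONANCE_TOL,
    zero_tol: float = ZERO_DIPOLE_TOL,
) -> FsmTerm:
    """The GFSM term ``delta_0JKL`` for intermediate pair (K, L).

    For a non-Hermitian set the K-channel dipoles come from the left moment
    matrix and the L-channel dipoles from the right one; a Hermitian set uses
    its single matrix on both sides.
    """
    _check_final_state(system, J)
    n = system.n_states
    for X in (K, L):
        if not (0 <= X < n):
            raise IndexError(f"intermediate state {X} outside the {n}-state set")
    omega = system.energies[J] / 2.0
    dK = float(system.energies[K] - omega)
    dL = float(system.energies[L] - omega)
    if min(abs(dK), abs(dL)) < resonance_tol:
        raise ResonanceError(
            f"denominator for intermediate pair ({K}, {L}) within "
            f"{resonance_tol:g} au of resonance at omega = E_{J}/2"
        )
    muL = system.moments("left")
    muR = system.moments("right")
    u, v = muL[0, K], muL[K, J]
    w, x = muR[0, L], muR[L, J]
    mags = np.array(
        [np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(w), np.linalg.norm(x)]
    )
    if np.any(mags < zero_tol):
        return FsmTerm(
            final_state=J,
            intermediates=(K, L),
            value=0.0,
            channels=None,
            magnitude_prefactor=0.0,
            denominators=(dK, dL),
        )
    uh, vh, wh, xh = u / mags[0], v / mags[1], w / mags[2], x / mags[3]
    channels = (
        float(np.dot(uh, vh) * np.dot(wh, xh)),
        float(np.dot(uh, wh) * np.dot(vh, xh)),
        float(np.dot(uh, xh) * np.dot(vh, wh)),
    )
    prefactor = float(np.prod(mags) / (dK * dL))
    value = TERM_CONSTANT * prefactor * sum(channels)
    return FsmTerm(
        final_state=J,
        intermediates=(K, L),
        value=value,
        channels=channels,
        magnitude_prefactor=prefactor,
        denominators=(dK, dL),
    )


@dataclass(frozen=True)
class FsmResult:
    """Aggregated few-state-model decomposition for one 0 -> J transition."""

    model: str
    final_state: int
    total: float
    terms: dict[tuple[int, int], FsmTerm]
    intermediate_states: tuple[int, ...]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def to_records(self) -> list[dict]:
        """One flat record per term (TSV-serializable)."""
        out = []
        for (K, L), t in self.terms.items():
            ch = t.channels if t.channels is not None else (None, None, None)
            out.append(
                {
                    "model": self.model,
                    "final_state": self.final_state,
                    "K": K,
                    "L": L,
                    "label": t.label,
                    "value_au": t.value,
                    "channel_1": ch[0],
                    "channel_2": ch[1],
                    "channel_3": ch[2],
                    "denominator_K_au": t.denominators[0],
                    "denominator_L_au": t.denominators[1],
                }
            )
        return out


def _model_label(n_intermediates: int) -> str:
    if n_intermediates == 0:
        return "2SM"
    if n_intermediates == 1:
        return "3SM"
    return f"NSM({n_intermediates + 2})"


def fsm_delta(
    system: ElectronicStateSet,
    J: int,
    intermediates=(),
    resonance_tol: float = RESONANCE_TOL,
    zero_tol: float = ZERO_DIPOLE_TOL,
) -> FsmResult:
    """Few-state-model two-photon strength with the given intermediate states.

    Terms are enumerated over all ordered pairs (K, L) drawn from
    ``{0, J} + intermediates``: 4 terms for the two-state model (no
    intermediates), 9 for the three-state model (one intermediate).  With
    every other state of the set admitted as an intermediate, the total
    equals :func:`full_sos_delta` to numerical precision.
    """
    _check_final_state(system, J)
    inter = tuple(int(i) for i in intermediates)
    if len(set(inter)) != len(inter):
        raise ValueError("intermediate states must be distinct")
    if any(i in (0, J) for i in inter):
        raise ValueError("0 and the final state J are always included; "
                         "intermediates must be other states")
    states = (0,) + inter + (J,)
    terms: dict[tuple[int, int], FsmTerm] = {}
    for K in states:
        for L in states:
            terms[(K, L)] = gfsm_term(
                system, J, K, L, resonance_tol=resonance_tol, zero_tol=zero_tol
            )
    total = float(sum(t.value for t in terms.values()))
    return FsmResult(
        model=_model_label(len(inter)),
        final_state=J,
        total=total,
        terms=terms,
        intermediate_states=inter,
    )


def channel_classification(result: FsmResult) -> dict[tuple[int, int], str]:
    """Label every term of a decomposition as constructive (positive),
    destructive (negative) or null (exactly zero)."""
    out = {}
    for key, t in result.terms.items():
        if t.value < 0:
            out[key] = "destructive"
        elif t.value == 0:
            out[key] = "null"
        else:
            out[key] = "constructive"
    return out
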