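"""Comparative two-photon analysis over a compound cohort.

Builds the per-compound summary (one-/two-photon wavelengths, biological
window placement), the two- and three-state-model decomposition reports with
dominant-term and destructive-interference identification, the best
intermediate-state selection against a reference strength, and the cohort
summary (energy ranges, fold changes, red-shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .core import ElectronicStateSet, FsmResult, fsm_delta, full_sos_delta
from .synthetic import CompoundRecord
from .units import in_biological_window, two_photon_wavelength, ev_to_nm

__all__ = [
    "DecompositionReport",
    "CohortSummary",
    "TRANSITIONS",
    "compound_summary",
    "energy_range",
    "delta_range",
    "fold_change",
    "decompose",
    "best_intermediate",
    "cohort_report",
    "plot_decomposition",
]

TRANSITIONS = ("S0->S1", "S0->S2")


def _check_records(records: list[CompoundRecord]) -> list[CompoundRecord]:
    ids = sorted(r.compound_id for r in records)
    if ids != list(range(1, 14)):
        missing = sorted(set(range(1, 14)) - set(ids))
        raise ValueError(f"cohort requires compounds 1-13; missing {missing}")
    return sorted(records, key=lambda r: r.compound_id)


def compound_summary(records: list[CompoundRecord]) -> pd.DataFrame:
    """Per-compound, per-transition table: energy, oscillator strength,
    two-photon strength (printed 1e4 au units), one- and two-photon
    wavelengths, and biological-window flag.  Sorted by compound id."""
    rows = []
    for r in _check_records(records):
        for transition in TRANSITIONS:
            de = r.energy(transition)
            lam2 = two_photon_wavelength(de)
            rows.append(
                {
                    "compound": r.compound_id,
                    "polarity": r.polarity_class,
                    "transition": transition,
                    "delta_e_ev": de,
                    "f": r.oscillator(transition),
                    "delta_1e4au": r.strength(transition),
                    "lambda_1pa_nm": ev_to_nm(de),
                    "lambda_2pa_nm": lam2,
                    "in_window": in_biological_window(lam2),
                }
            )
    return pd.DataFrame(rows)


def energy_range(records: list[CompoundRecord], transition: str) -> tuple[float, float]:
    """(min, max) excitation energy in eV over the cohort for one transition."""
    if transition not in TRANSITIONS:
        raise ValueError(f"transition must be one of {TRANSITIONS}")
    energies = [r.energy(transition) for r in records]
    return (min(energies), max(energies))


def delta_range(records: list[CompoundRecord], transition: str) -> tuple[float, float]:
    """(min, max) two-photon strength (1e4 au) over the cohort."""
    if transition not in TRANSITIONS:
        raise ValueError(f"transition must be one of {TRANSITIONS}")
    deltas = [r.strength(transition) for r in records]
    return (min(deltas), max(deltas))


def fold_change(
    records: list[CompoundRecord],
    transition: str,
    numerator_id: int,
    denominator_id: int,
) -> float:
    """Ratio of two compounds' two-photon strengths for one transition."""
    by_id = {r.compound_id: r for r in records}
    num = by_id[numerator_id].strength(transition)
    den = by_id[denominator_id].strength(transition)
    if den == 0:
        raise ZeroDivisionError(
            f"compound {denominator_id} has zero strength for {transition} "
            "(symmetry-forbidden reference transition)"
        )
    return num / den


@dataclass(frozen=True)
class DecompositionReport:
    """Labelled few-state-model decomposition for one transition.

    ``dominant_term`` is the label of the largest-|value| term (ties broken
    lexicographically; ``None`` when every term vanishes);
    ``destructive_terms`` are labels of negative terms.
    """

    subject: str
    transition: str
    model: str
    terms: dict[str, float]
    total: float
    reference: float | None
    dominant_term: str | None
    destructive_terms: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject,
                "transition": self.transition,
                "model": self.model,
                "term": label,
                "value_au": value,
                "destructive": label in self.destructive_terms,
                "dominant": label == self.dominant_term,
            }
            for label, value in self.terms.items()
        ]
        return pd.DataFrame(rows)


def _report_from_result(
    result: FsmResult, subject: str, reference: float | None
) -> DecompositionReport:
    labelled = {t.label: t.value for t in result.terms.values()}
    if any(v != 0 for v in labelled.values()):
        dominant = min(
            labelled, key=lambda lab: (-abs(labelled[lab]), lab)
        )
    else:
        dominant = None
    destructive = tuple(sorted(lab for lab, v in labelled.items() if v < 0))
    return DecompositionReport(
        subject=subject,
        transition=f"S0->S{result.final_state}",
        model=result.model,
        terms=labelled,
        total=result.total,
        reference=reference,
        dominant_term=dominant,
        destructive_terms=destructive,
    )


def decompose(
    system: ElectronicStateSet,
    J: int,
    model: str = "2SM",
    intermediate: int | None = None,
    subject: str = "system",
    reference: float | None = None,
) -> DecompositionReport:
    """Few-state decomposition of the 0 -> J strength with term labels.

    For the three-state model an intermediate must be supplied unless state 1
    is available (the conventional lowest-excited-state choice).  ``reference``
    may carry an external response value; when omitted for a report that needs
    one, :func:`core.full_sos_delta` is the natural in-package reference.
    """
    if model == "2SM":
        result = fsm_delta(system, J, ())
    elif model == "3SM":
        if intermediate is None:
            intermediate = 1 if J != 1 else 2
        result = fsm_delta(system, J, (intermediate,))
    else:
        raise ValueError("model must be '2SM' or '3SM'")
    return _report_from_result(result, subject=subject, reference=reference)


def best_intermediate(
    system: ElectronicStateSet,
    J: int,
    reference_delta: float,
    candidates,
) -> int:
    """Intermediate state whose three-state-model strength is closest to the
    reference value; ties go to the lowest state index."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate intermediate state")
    best, best_err = None, np.inf
    for I in sorted(candidates):
        err = abs(fsm_delta(system, J, (I,)).total - reference_delta)
        if err < best_err:
            best, best_err = I, err
    return best


@dataclass(frozen=True)
class CohortSummary:
    """Headline comparative numbers over the 13-compound cohort."""

    energy_range_s1_ev: tuple[float, float]
    energy_range_s2_ev: tuple[float, float]
    delta_range_s1_1e4au: tuple[float, float]
    delta_range_s2_1e4au: tuple[float, float]
    max_delta_s2_compound: int
    fold_change_s2: float
    fold_change_pair: tuple[int, int]
    red_shift_nm: tuple[int, int]
    s1_active_compounds: tuple[int, ...]
    window_flags: dict[str, dict[int, bool]]

    def to_dict(self) -> dict:
        return {
            "energy_range_s1_ev": list(self.energy_range_s1_ev),
            "energy_range_s2_ev": list(self.energy_range_s2_ev),
            "delta_range_s1_1e4au": list(self.delta_range_s1_1e4au),
            "delta_range_s2_1e4au": list(self.delta_range_s2_1e4au),
            "max_delta_s2_compound": self.max_delta_s2_compound,
            "fold_change_s2": self.fold_change_s2,
            "fold_change_pair": list(self.fold_change_pair),
            "red_shift_nm": list(self.red_shift_nm),
            "s1_active_compounds": list(self.s1_active_compounds),
            "window_flags": {
                t: {str(k): v for k, v in flags.items()}
                for t, flags in self.window_flags.items()
            },
        }


def cohort_report(records: list[CompoundRecord]) -> CohortSummary:
    """Comparative summary of the cohort.

    The fold change contrasts the strongest S0->S2 absorber against the
    unsubstituted reference (the compound with the largest S0->S2 gap); the
    red-shift pair gives those two compounds' two-photon wavelengths, which
    tracks whether donor substitution moves the excitation into the
    650-1100 nm tissue window.
    """
    records = _check_records(records)
    by_id = {r.compound_id: r for r in records}
    reference_id = max(records, key=lambda r: r.de_s2_ev).compound_id
    strongest_id = max(records, key=lambda r: r.delta_s2).compound_id
    window_flags = {
        t: {
            r.compound_id: in_biological_window(two_photon_wavelength(r.energy(t)))
            for r in records
        }
        for t in TRANSITIONS
    }
    return CohortSummary(
        energy_range_s1_ev=energy_range(records, "S0->S1"),
        energy_range_s2_ev=energy_range(records, "S0->S2"),
        delta_range_s1_1e4au=delta_range(records, "S0->S1"),
        delta_range_s2_1e4au=delta_range(records, "S0->S2"),
        max_delta_s2_compound=strongest_id,
        fold_change_s2=fold_change(records, "S0->S2", strongest_id, reference_id),
        fold_change_pair=(strongest_id, reference_id),
        red_shift_nm=(
            two_photon_wavelength(by_id[reference_id].de_s2_ev),
            two_photon_wavelength(by_id[strongest_id].de_s2_ev),
        ),
        s1_active_compounds=tuple(
            r.compound_id for r in records if r.delta_s1 > 0
        ),
        window_flags=window_flags,
    )


def plot_decomposition(report: DecompositionReport, path) -> None:
    """Static bar chart of a few-state decomposition (term values in au)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(report.terms)
    values = [report.terms[lab] for lab in labels]
    colors = ["#b2182b" if v < 0 else "#2166ac" for v in values]
    fig, ax = plt.subplots(figsize=(1.2 + 0.7 * len(labels), 3.2))
    ax.bar(range(len(labels)), values, color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(r"$\delta_{0JKL}$ (au)")
    ax.set_title(f"{report.subject} {report.transition} ({report.model})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
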