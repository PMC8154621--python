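"""JSON interchange for few-state systems and tabular report writing.

A state-set document carries excitation energies in eV (human-facing, like
the reference dataset) and dipole vectors in au; the reader converts energies
to au at the boundary so the computational core never sees eV.  The schema is
the single ingestion point for electronic-structure data: excited-state
blocks from quantum-chemistry output (TURBOMOLE/DALTON-style) are transcribed
into it by hand or by the user's own scripts.

Example document::

    {
      "schema_version": "1",
      "n_states": 3,
      "energies_ev": [3.2, 4.1],
      "dipoles": [
        {"bra": 0, "ket": 1, "vector_au": [0.0, 0.0, 2.1]},
        {"bra": 1, "ket": 2, "vector_au": [0.0, 1.3, 0.0]}
      ],
      "parity": ["gerade", "ungerade", "gerade"],
      "metadata": {"method": "RI-CC2/cc-pVDZ"}
    }

Pairs given in one orientation only are mirrored (Hermitian completion)
unless a ``left_dipoles`` block marks the data as non-Hermitian.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .core import ElectronicStateSet
from .units import au_to_ev, ev_to_au

__all__ = [
    "SCHEMA_VERSION",
    "DipoleEntry",
    "StateSetDocument",
    "StateSetError",
    "read_state_set",
    "write_state_set",
    "write_report",
]

SCHEMA_VERSION = "1"


class StateSetError(ValueError):
    """A state-set document failed schema or physics validation."""


class DipoleEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bra: int = Field(ge=0)
    ket: int = Field(ge=0)
    vector_au: tuple[float, float, float]

    @field_validator("vector_au")
    @classmethod
    def _finite(cls, v):
        if not all(math.isfinite(x) for x in v):
            raise ValueError("dipole vector components must be finite")
        return v


class StateSetDocument(BaseModel):
    """Schema of the few-state interchange format (see module docstring)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    n_states: int = Field(ge=2)
    energies_ev: list[float]
    dipoles: list[DipoleEntry]
    left_dipoles: list[DipoleEntry] | None = None
    parity: list[str] | None = None
    metadata: dict = Field(default_factory=dict)

    @field_validator("energies_ev")
    @classmethod
    def _positive_finite(cls, v):
        for e in v:
            if not (math.isfinite(e) and e > 0):
                raise ValueError(f"excited-state energy must be positive and finite, got {e}")
        return v

    def _check_entries(self, entries, label):
        seen = set()
        for d in entries:
            if d.bra >= self.n_states or d.ket >= self.n_states:
                raise StateSetError(
                    f"{label}: state pair ({d.bra}, {d.ket}) outside the "
                    f"{self.n_states}-state set"
                )
            if (d.bra, d.ket) in seen:
                raise StateSetError(f"{label}: duplicate entry for pair ({d.bra}, {d.ket})")
            seen.add((d.bra, d.ket))

    def to_state_set(self) -> ElectronicStateSet:
        if len(self.energies_ev) != self.n_states - 1:
            raise StateSetError(
                f"expected {self.n_states - 1} excited-state energies, "
                f"got {len(self.energies_ev)}"
            )
        self._check_entries(self.dipoles, "dipoles")
        if self.left_dipoles is not None:
            self._check_entries(self.left_dipoles, "left_dipoles")

        energies = np.concatenate([[0.0], ev_to_au(np.asarray(self.energies_ev))])

        def dense(entries, hermitianize):
            mu = np.zeros((self.n_states, self.n_states, 3))
            given = {(d.bra, d.ket) for d in entries}
            for d in entries:
                mu[d.bra, d.ket] = d.vector_au
            if hermitianize:
                for d in entries:
                    if d.bra != d.ket and (d.ket, d.bra) not in given:
                        mu[d.ket, d.bra] = d.vector_au
            return mu

        hermitian = self.left_dipoles is None
        mu_right = dense(self.dipoles, hermitianize=hermitian)
        mu_left = None if hermitian else dense(self.left_dipoles, hermitianize=False)
        try:
            return ElectronicStateSet(
                energies, mu_right, dipoles_left=mu_left, parity=self.parity
            )
        except ValueError as exc:
            raise StateSetError(str(exc)) from exc


def read_state_set(path) -> ElectronicStateSet:
    """Read and validate a state-set JSON document into an
    :class:`~gfsm.core.ElectronicStateSet` (energies converted eV -> au)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StateSetError(f"{path}: not valid JSON ({exc})") from exc
    try:
        doc = StateSetDocument.model_validate(payload)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise StateSetError(f"{path}: schema violation ({msgs})") from exc
    return doc.to_state_set()


def write_state_set(system: ElectronicStateSet, path, metadata: dict | None = None) -> None:
    """Serialize a state set to the JSON interchange format.

    Every nonzero dipole pair is written explicitly (both orientations for
    off-diagonal pairs), so a read-back reproduces the system exactly up to
    the eV round trip of the energies.
    """

    def entries(mat):
        out = []
        n = mat.shape[0]
        for p in range(n):
            for q in range(n):
                if np.any(mat[p, q] != 0):
                    out.append(
                        {"bra": p, "ket": q, "vector_au": [float(x) for x in mat[p, q]]}
                    )
        return out

    doc = {
        "schema_version": SCHEMA_VERSION,
        "n_states": system.n_states,
        "energies_ev": [float(au_to_ev(e)) for e in system.energies[1:]],
        "dipoles": entries(system.dipoles_right),
    }
    if system.dipoles_left is not None:
        doc["left_dipoles"] = entries(system.dipoles_left)
    if system.parity is not None:
        doc["parity"] = list(system.parity)
    doc["metadata"] = metadata or {}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _format_value(col: str, value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float):
        # printed-unit strength columns mirror the dataset's 2-decimal style
        if col.endswith("_1e4au"):
            return f"{value:.2f}"
        return f"{value:.6g}"
    return str(value)


def write_report(report, path, format: str = "tsv") -> None:
    """Write a report object to TSV or JSON with deterministic layout.

    Accepts a DataFrame, a dataclass with ``to_frame``/``to_dict``, or a
    plain dict.  TSV floats carry 6 significant digits, except columns in the
    dataset's printed 1e4-au strength unit, which keep 2 decimals.
    """
    path = Path(path)
    if hasattr(report, "to_frame"):
        frame = report.to_frame()
    elif isinstance(report, pd.DataFrame):
        frame = report
    else:
        frame = None

    if format == "json":
        if frame is not None:
            payload = frame.to_dict(orient="records")
        elif hasattr(report, "to_dict"):
            payload = report.to_dict()
        else:
            payload = report
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if format != "tsv":
        raise ValueError("format must be 'tsv' or 'json'")
    if frame is None:
        if hasattr(report, "to_dict"):
            report = report.to_dict()
        frame = pd.DataFrame(
            [{"key": k, "value": v} for k, v in report.items()]
        )
    lines = ["\t".join(str(c) for c in frame.columns)]
    for _, row in frame.iterrows():
        lines.append("\t".join(_format_value(col, row[col]) for col in frame.columns))
    path.write_text("\n".join(lines) + "\n")
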