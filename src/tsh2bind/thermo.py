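"""Binding free-energy bookkeeping from dissociation constants.

Each binding step contributes dG = -RT ln K with K = 1/Kd (Kd in molar),
so dG = RT ln Kd_M; steps sum to a total and totals are compared between
constructs as ddG relative to a reference interaction.  The default
temperature is 298.15 K (equilibrium fluorescence at 25 C); calorimetric
steps measured at 20 C may carry 293.15 K per entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ParameterError

__all__ = ["GAS_CONSTANT_KCAL", "delta_g", "LedgerEntry", "EnergyLedger", "total_delta_g", "ddg"]

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.98720425e-3

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def delta_g(kd: float, temperature_K: float = 298.15, unit: str = "nM") -> float:
    """Binding free energy (kcal/mol) of one step: -RT ln(1/Kd).

    ``kd`` is interpreted in ``unit`` (default nM) and converted to molar;
    any Kd below 1 M therefore yields a negative free energy.
    """
    if kd <= 0 or not math.isfinite(kd):
        raise ParameterError(f"Kd must be finite and > 0, got {kd!r}")
    if temperature_K <= 0:
        raise ParameterError(f"temperature must be > 0 K, got {temperature_K!r}")
    try:
        kd_molar = kd * _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ParameterError(
            f"unknown concentration unit {unit!r}; allowed: {sorted(_UNIT_TO_MOLAR)}"
        ) from None
    return GAS_CONSTANT_KCAL * temperature_K * math.log(kd_molar)


@dataclass(frozen=True)
class LedgerEntry:
    label: str
    kd_nM: float
    temperature_K: float = 298.15

    @property
    def dg_kcal_mol(self) -> float:
        return delta_g(self.kd_nM, self.temperature_K, unit="nM")


@dataclass
class EnergyLedger:
    """Per-step binding free energies for one receptor:ligand interaction."""

    entries: list[LedgerEntry] = field(default_factory=list)
    name: str = ""

    @classmethod
    def from_kds(
        cls,
        kds_nM: Sequence[float],
        labels: Sequence[str] | None = None,
        temperatures_K: Sequence[float] | float = 298.15,
        name: str = "",
    ) -> "EnergyLedger":
        n = len(kds_nM)
        if labels is None:
            labels = [f"step{i + 1}" for i in range(n)]
        if isinstance(temperatures_K, (int, float)):
            temperatures_K = [float(temperatures_K)] * n
        if not (len(labels) == len(temperatures_K) == n):
            raise ParameterError("labels, Kds and temperatures must have equal length")
        return cls(
            entries=[LedgerEntry(l, float(k), float(t)) for l, k, t in zip(labels, kds_nM, temperatures_K)],
            name=name,
        )

    def add(self, label: str, kd_nM: float, temperature_K: float = 298.15) -> None:
        self.entries.append(LedgerEntry(label, kd_nM, temperature_K))

    @property
    def total(self) -> float:
        """Total binding free energy (kcal/mol): sum over steps."""
        if not self.entries:
            raise ParameterError("cannot total an empty ledger")
        return sum(e.dg_kcal_mol for e in self.entries)

    def ddg(self, reference: "EnergyLedger") -> float:
        """ddG = total(self) - total(reference), in kcal/mol."""
        return self.total - reference.total

    def __iter__(self) -> Iterable[LedgerEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def total_delta_g(ledger: EnergyLedger) -> float:
    """Functional alias for :attr:`EnergyLedger.total`."""
    return ledger.total


def ddg(ledger: EnergyLedger, reference: EnergyLedger) -> float:
    """Functional alias for :meth:`EnergyLedger.ddg`."""
    return ledger.ddg(reference)
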