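"""Mass-action network for tandem-SH2 domain : ITAM-Y2P binding.

The receptor (a tandem-SH2 module such as the regulatory module of ZAP-70
or Syk) is resolved into six species distinguished by conformation
(open/closed) and by the occupancy of the two phosphate-binding pockets:

========== =========================================================
Ropen00    open apo-state, both pockets free
Ropen01    open encounter complex, C-SH2 pocket occupied
Rclosed00  ligand-independent closed intermediate
Rclosed01  partially bound closed intermediate (C-SH2 occupied)
Rclosed10  partially bound closed intermediate (N-SH2 occupied)
Rclosed11  fully bound closed holo-state
========== =========================================================

All transitions obey mass action with the ligand ``L`` treated as a fixed
external concentration (pseudo-first-order binding; the double-binding
event Rclosed00 -> Rclosed11 is second order in ``L``).  Transitions into
the holo-state from the partially bound intermediates carry dimensionless
penalty weights ``w1``/``w2`` (a "thermodynamic brake": forward rate
``wi*kf`` reduced relative to the encounter on-rate ``kf``); ``w3``
penalizes the direct Ropen00 -> Rclosed10 route.

Units are fixed package-wide: concentrations in nM, time in s, so ``kf``
is nM^-1 s^-1 and ``k3_plus`` is nM^-2 s^-1.

Because ``L`` is external, the right-hand side is *linear* in the state:
``dx/dt = A(L) x`` with ``A`` a Metzler matrix whose columns sum to zero
(total receptor is conserved).  :func:`rate_matrix` exposes that matrix;
the simulation layer exploits it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "SPECIES",
    "REDUCED_SPECIES",
    "VARIANTS",
    "RateConstants",
    "ReducedRateConstants",
    "StateVector",
    "ReducedStateVector",
    "DerivedKds",
    "rate_matrix",
    "reduced_rate_matrix",
    "rhs_full",
    "rhs_reduced",
    "apply_variant",
    "derived_kds",
    "zap70_reference",
    "syk_reference",
    "reduced_reference",
    "REFERENCE_KDS",
]

#: Species order used for every state array in the full model.
SPECIES = ("Ropen00", "Ropen01", "Rclosed00", "Rclosed01", "Rclosed10", "Rclosed11")

#: Species order of the reduced four-species model.  ``Rclosed01_10`` lumps
#: the two partially bound closed intermediates.
REDUCED_SPECIES = ("Ropen00", "Ropen01", "Rclosed01_10", "Rclosed11")

#: Published model variants, realized as parameter masks on the full network.
VARIANTS = ("full", "encounter_only", "syk_no_penalty", "reduced")


class DerivedKds(NamedTuple):
    """Step dissociation constants implied by a parameter set (nM)."""

    kd1: float
    kd2: float
    kd1star: float


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the full six-species network.

    Parameters
    ----------
    kf : float
        Bimolecular on-rate of the C-SH2 encounter step (nM^-1 s^-1).
    kb : float
        Encounter off-rate Ropen01 -> Ropen00 (s^-1).
    w1, w2, w3 : float
        Dimensionless penalty weights in [0, 1] scaling the forward rates
        into Rclosed11 (via Rclosed01 and Rclosed10) and into Rclosed10
        directly from the apo-state.
    kb1, kb2 : float
        Off-rates Rclosed11 -> Rclosed01 and Rclosed11 -> Rclosed10 (s^-1).
    kb3 : float
        Off-rate Rclosed10 -> Ropen00 (s^-1).
    kclose, kopen : float
        Ligand-independent conformational rates Ropen01 <-> Rclosed01 (s^-1).
    kclose_prime, kopen_prime : float
        Ligand-independent rates Ropen00 <-> Rclosed00 (s^-1).
    k1_plus, k2_plus : float
        On-rates Rclosed00 -> Rclosed10 / Rclosed01 (nM^-1 s^-1).
    k1_minus, k2_minus : float
        Corresponding off-rates (s^-1).
    k3_plus : float
        Double-binding on-rate Rclosed00 -> Rclosed11 (nM^-2 s^-1).
    k3_minus : float
        Corresponding off-rate (s^-1).
    """

    kf: float
    kb: float
    w1: float
    w2: float
    w3: float
    kb1: float
    kb2: float
    kb3: float
    kclose: float
    kopen: float
    kclose_prime: float
    kopen_prime: float
    k1_plus: float
    k1_minus: float
    k2_plus: float
    k2_minus: float
    k3_plus: float
    k3_minus: float

    def validate(self, strict: bool = True) -> "RateConstants":
        """Check non-negativity of all rates and, if *strict*, wi <= 1.

        Returns ``self`` so the call can be chained.  ``strict=False``
        permits penalty weights above one for exploratory use.
        """
        for name, value in self.as_dict().items():
            if not math.isfinite(value) or value < 0:
                raise ParameterError(
                    f"rate constant {name!r} must be finite and >= 0, got {value!r}"
                )
        if strict:
            for name in ("w1", "w2", "w3"):
                value = getattr(self, name)
                if value > 1:
                    raise ParameterError(
                        f"penalty weight {name!r} must be <= 1 (got {value}); "
                        "pass strict=False to allow weights above one"
                    )
        return self

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **changes: float) -> "RateConstants":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ReducedRateConstants:
    """Rate constants of the reduced four-species model.

    ``k_plus``/``k_minus`` are the ligand-independent open <-> closed rates
    of the partially bound intermediates; ``w1``/``w2`` penalize the two
    routes into the holo-state, whose off-rates both equal ``kb``.
    """

    kf: float
    kb: float
    k_plus: float
    k_minus: float
    w1: float
    w2: float

    def validate(self, strict: bool = True) -> "ReducedRateConstants":
        for name, value in self.as_dict().items():
            if not math.isfinite(value) or value < 0:
                raise ParameterError(
                    f"rate constant {name!r} must be finite and >= 0, got {value!r}"
                )
        if strict:
            for name in ("w1", "w2"):
                if getattr(self, name) > 1:
                    raise ParameterError(
                        f"penalty weight {name!r} must be <= 1; "
                        "pass strict=False to allow weights above one"
                    )
        return self

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def replace(self, **changes: float) -> "ReducedRateConstants":
        return dataclasses.replace(self, **changes)

    @property
    def kd1(self) -> float:
        return self.kb / self.kf


class StateVector(NamedTuple):
    """Concentrations (nM) of the six full-model species."""

    Ropen00: float
    Ropen01: float = 0.0
    Rclosed00: float = 0.0
    Rclosed01: float = 0.0
    Rclosed10: float = 0.0
    Rclosed11: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6,):
            raise ParameterError(f"full-model state must have 6 entries, got {arr.shape}")
        return cls(*arr)

    @property
    def total(self) -> float:
        return float(sum(self))


class ReducedStateVector(NamedTuple):
    """Concentrations (nM) of the four reduced-model species."""

    Ropen00: float
    Ropen01: float = 0.0
    Rclosed01_10: float = 0.0
    Rclosed11: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ReducedStateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4,):
            raise ParameterError(f"reduced state must have 4 entries, got {arr.shape}")
        return cls(*arr)

    @property
    def total(self) -> float:
        return float(sum(self))


def _check_ligand(L: float) -> float:
    L = float(L)
    if not math.isfinite(L) or L < 0:
        raise ParameterError(f"ligand concentration must be finite and >= 0, got {L!r}")
    return L


# (from, to, rate expression) edges of the full network.  Each unimolecular
# flux appears exactly once, which guarantees column sums of zero in the
# rate matrix (mass conservation).
def _full_edges(rates: RateConstants, L: float) -> list[tuple[int, int, float]]:
    i = {name: k for k, name in enumerate(SPECIES)}
    r = rates
    return [
        (i["Ropen00"], i["Ropen01"], r.kf * L),
        (i["Ropen01"], i["Ropen00"], r.kb),
        (i["Ropen00"], i["Rclosed10"], r.w3 * r.kf * L),
        (i["Rclosed10"], i["Ropen00"], r.kb3),
        (i["Ropen00"], i["Rclosed00"], r.kclose_prime),
        (i["Rclosed00"], i["Ropen00"], r.kopen_prime),
        (i["Ropen01"], i["Rclosed01"], r.kclose),
        (i["Rclosed01"], i["Ropen01"], r.kopen),
        (i["Rclosed00"], i["Rclosed10"], r.k1_plus * L),
        (i["Rclosed10"], i["Rclosed00"], r.k1_minus),
        (i["Rclosed00"], i["Rclosed01"], r.k2_plus * L),
        (i["Rclosed01"], i["Rclosed00"], r.k2_minus),
        (i["Rclosed00"], i["Rclosed11"], r.k3_plus * L * L),
        (i["Rclosed11"], i["Rclosed00"], r.k3_minus),
        (i["Rclosed01"], i["Rclosed11"], r.w1 * r.kf * L),
        (i["Rclosed11"], i["Rclosed01"], r.kb1),
        (i["Rclosed10"], i["Rclosed11"], r.w2 * r.kf * L),
        (i["Rclosed11"], i["Rclosed10"], r.kb2),
    ]


def _reduced_edges(rates: ReducedRateConstants, L: float) -> list[tuple[int, int, float]]:
    i = {name: k for k, name in enumerate(REDUCED_SPECIES)}
    r = rates
    return [
        (i["Ropen00"], i["Ropen01"], r.kf * L),
        (i["Ropen01"], i["Ropen00"], r.kb),
        (i["Ropen01"], i["Rclosed01_10"], r.k_plus),
        (i["Rclosed01_10"], i["Ropen01"], r.k_minus),
        (i["Ropen01"], i["Rclosed11"], r.w1 * r.kf * L),
        (i["Rclosed11"], i["Ropen01"], r.kb),
        (i["Rclosed01_10"], i["Rclosed11"], r.w2 * r.kf * L),
        (i["Rclosed11"], i["Rclosed01_10"], r.kb),
    ]


def _edges_to_matrix(edges: list[tuple[int, int, float]], n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for src, dst, k in edges:
        A[dst, src] += k
        A[src, src] -= k
    return A


def rate_matrix(rates: RateConstants, L: float, strict: bool = True) -> np.ndarray:
    """Return the 6x6 matrix ``A(L)`` with ``dx/dt = A x`` for the full model."""
    rates.validate(strict=strict)
    L = _check_ligand(L)
    return _edges_to_matrix(_full_edges(rates, L), 6)


def reduced_rate_matrix(
    rates: ReducedRateConstants, L: float, strict: bool = True
) -> np.ndarray:
    """Return the 4x4 matrix ``A(L)`` for the reduced model."""
    rates.validate(strict=strict)
    L = _check_ligand(L)
    return _edges_to_matrix(_reduced_edges(rates, L), 4)


def rhs_full(state, L: float, rates: RateConstants) -> np.ndarray:
    """Time derivatives (nM/s) of the six full-model species.

    ``state`` may be a :class:`StateVector` or any length-6 sequence in
    :data:`SPECIES` order.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (6,):
        raise ParameterError(f"full-model state must have 6 entries, got {x.shape}")
    return rate_matrix(rates, L) @ x


def rhs_reduced(state, L: float, rates: ReducedRateConstants) -> np.ndarray:
    """Time derivatives (nM/s) of the four reduced-model species."""
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ParameterError(f"reduced state must have 4 entries, got {x.shape}")
    return reduced_rate_matrix(rates, L) @ x


def apply_variant(base: RateConstants, variant: str) -> RateConstants:
    """Apply a published variant's parameter mask to *base*.

    ``full``
        identity.
    ``encounter_only``
        single-site binding through the C-SH2 pocket only (singly
        phosphorylated ligand, or an N-SH2 pocket mutant): w1 = w2 = w3 = 0
        and every rate outside the Ropen00 <-> Ropen01 <-> Rclosed01 chain
        set to zero.
    ``syk_no_penalty``
        no thermodynamic brake and a negligible ligand-free closed state:
        w1 = w2 = w3 = 1, kb1 = kb2 = kb3 = kb, and the Rclosed00 exchange
        rates set to zero.
    """
    base.validate()
    if variant == "full":
        return base
    if variant == "encounter_only":
        return base.replace(
            w1=0.0, w2=0.0, w3=0.0,
            kb1=0.0, kb2=0.0, kb3=0.0,
            k1_plus=0.0, k1_minus=0.0,
            k2_plus=0.0, k2_minus=0.0,
            k3_plus=0.0, k3_minus=0.0,
            kclose_prime=0.0, kopen_prime=0.0,
        )
    if variant == "syk_no_penalty":
        return base.replace(
            w1=1.0, w2=1.0, w3=1.0,
            kb1=base.kb, kb2=base.kb, kb3=base.kb,
            k1_plus=0.0, k1_minus=0.0,
            k2_plus=0.0, k2_minus=0.0,
            k3_plus=0.0, k3_minus=0.0,
            kclose_prime=0.0, kopen_prime=0.0,
        )
    if variant == "reduced":
        raise ParameterError(
            "the 'reduced' variant is a four-species system parameterized by "
            "ReducedRateConstants; it is not a mask on the full network"
        )
    raise ParameterError(
        f"unknown variant {variant!r}; allowed variants are {VARIANTS}"
    )


def derived_kds(rates: RateConstants) -> DerivedKds:
    """Step dissociation constants (nM) implied by a parameter set.

    Kd1 = kb/kf (encounter step), Kd2 = kb1/(w1*kf) (penalized N-SH2 step),
    Kd1* = kb2/(w2*kf) (remodeled C-SH2 site).  A zero penalty weight makes
    the corresponding constant undefined; it is reported as ``inf``.
    """
    rates.validate(strict=False)
    if rates.kf <= 0:
        raise ParameterError("kf must be > 0 to derive dissociation constants")
    kd1 = rates.kb / rates.kf
    kd2 = rates.kb1 / (rates.w1 * rates.kf) if rates.w1 > 0 else math.inf
    kd1star = rates.kb2 / (rates.w2 * rates.kf) if rates.w2 > 0 else math.inf
    return DerivedKds(kd1, kd2, kd1star)


#: Dissociation-constant anchors of the reference ZAP-70 parameter set (nM):
#: Kd1 = 2 nM, Kd2 = 10 uM, Kd1* = 100 nM.
REFERENCE_KDS = DerivedKds(kd1=2.0, kd2=1.0e4, kd1star=100.0)


def zap70_reference(
    kd1: float = REFERENCE_KDS.kd1,
    kd2: float = REFERENCE_KDS.kd2,
    kd1star: float = REFERENCE_KDS.kd1star,
    kf: float = 8.0e-4,
    w1: float = 0.01,
    w2: float = 0.1,
) -> RateConstants:
    """Reference parameter set for the ZAP-70 tandem-SH2 module.

    Only the three dissociation constants are experimental anchors
    (Kd1 = 2 nM, Kd2 = 10 uM, Kd1* = 100 nM); the microscopic rates
    distributing each Kd between on- and off-rates, and the conformational
    rates, are package defaults chosen so that the simulated kinetics fall
    in the experimentally observed regime (encounter pseudo-first-order
    rate ~ 24 s^-1 at 30 uM ligand; slow phase of order 0.1 s^-1; apo
    conformational equilibrium biased open).  Off-rates are derived from
    the anchors by construction: kb = Kd1*kf, kb1 = Kd2*w1*kf,
    kb2 = Kd1star*w2*kf.
    """
    kb = kd1 * kf
    kb1 = kd2 * w1 * kf
    kb2 = kd1star * w2 * kf
    return RateConstants(
        kf=kf,
        kb=kb,
        w1=w1,
        w2=w2,
        w3=0.1,
        kb1=kb1,
        kb2=kb2,
        kb3=kb1,
        kclose=10.0,
        kopen=1.0,
        kclose_prime=1.0e-3,
        kopen_prime=1.0,
        k1_plus=1.0e-5,
        k1_minus=1.0e-2,
        k2_plus=1.0e-5,
        k2_minus=1.0e-2,
        k3_plus=1.0e-9,
        k3_minus=1.0e-3,
    ).validate()


def syk_reference(kd: float = 65.0, kf: float = 8.0e-4) -> RateConstants:
    """Reference parameter set for the Syk tandem-SH2 module.

    Syk binds ITAM-Y2P with a single apparent Kd of roughly 65 nM and no
    slow phase; the ``syk_no_penalty`` mask (no brake, negligible
    ligand-free closed state) is applied to an anchor set with
    kb = Kd*kf at every binding step.  Without a stabilizing allosteric
    network there is no conformational bias, so the open/closed exchange
    of the partially bound intermediate is fast and symmetric
    (kclose = kopen = 30 /s); the transient is then a single fast phase
    with no slow component.  The steady-state curve of this network is
    close to, but not exactly, an independent-site hyperbola: at detailed
    balance the three singly bound species carry equal statistical weight,
    giving a mild apparent negative cooperativity (fitted Hill
    coefficient ~ 0.86), in line with the weak negative cooperativity
    observed for Syk.
    """
    base = zap70_reference(kd1=kd, kd2=kd, kd1star=kd, kf=kf, w1=1.0, w2=1.0).replace(
        kclose=30.0, kopen=30.0
    )
    return apply_variant(base, "syk_no_penalty")


def reduced_reference(
    kd1: float = REFERENCE_KDS.kd1,
    kf: float = 8.0e-4,
    k_plus: float = 7.0e-5,
    k_minus: float = 7.0e-4,
    w1: float = 0.01,
    w2: float = 0.1,
) -> ReducedRateConstants:
    """Reference parameters of the reduced model (k-/k+ = 10)."""
    return ReducedRateConstants(
        kf=kf, kb=kd1 * kf, k_plus=k_plus, k_minus=k_minus, w1=w1, w2=w2
    ).validate()
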