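"""Synthetic experiments with the statistical structure the estimators assume.

Two instrument geometries are emulated:

* equilibrium tryptophan-quench titrations (0.5 uM receptor titrated with
  ligand, normalized intensity versus concentration, replicate SD), and
* two-window stopped-flow transients (fast window 1 s / 101 points, slow
  window 200 s / 1500 points, 100 nM protein mixed with 30 uM ligand,
  plus a protein-only blank trace).

Signals are generated either from the kinetic model itself or from the
phenomenological laws the estimators fit (Hill equation, sums of
exponentials), with i.i.d. Gaussian replicate noise scaled to the dynamic
range.  Ground truth is stored alongside the data so recovery tests can
close the loop.  The same seed always reproduces the same bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import ParameterError
from .estimate import TitrationData
from .simulate import WINDOWS, KineticTrace, dose_response, kinetic_profile

__all__ = [
    "NoiseSpec",
    "ExperimentBundle",
    "gen_titration",
    "gen_stopped_flow",
    "preprocess_traces",
    "DEFAULT_PROTEIN_NM",
    "DEFAULT_LIGAND_NM",
]

#: Stopped-flow mixing defaults: 100 nM protein, 30 uM ligand.
DEFAULT_PROTEIN_NM = 100.0
DEFAULT_LIGAND_NM = 30_000.0


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian replicate noise: SD as a fraction of the dynamic range.

    Defaults (1% of range, 3 averaged replicates) emulate the tight error
    bars of triplicate fluorescence experiments.
    """

    sd: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("noise SD must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicate count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ExperimentBundle:
    """Generated data plus the ground truth that produced it."""

    kind: str
    truth: dict[str, Any]
    data: Any
    blank: KineticTrace | None = None
    replicates: np.ndarray | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    meta: dict[str, Any] = field(default_factory=dict)


def _replicate(mean: np.ndarray, scale: float, noise: NoiseSpec, rng: np.random.Generator):
    reps = mean[None, :] + rng.normal(0.0, noise.sd * scale, (noise.replicates, mean.size))
    avg = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if noise.replicates > 1 else np.zeros_like(avg)
    return reps, avg, sd


def gen_titration(
    truth: dict[str, Any],
    ligand_grid: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> ExperimentBundle:
    """Synthetic equilibrium titration.

    ``truth`` is either a Hill-law parameterization ``{"kd", "nh",
    "bmax"}`` or a model-based one ``{"rates", "variant"}`` whose mean
    signal is the steady-state bound fraction from :func:`dose_response`.
    """
    if ligand_grid is None:
        ligand_grid = np.logspace(-1, 5, 30)
    grid = np.asarray(ligand_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("ligand grid is empty")
    if np.any(grid < 0) or (grid.size >= 2 and np.any(np.diff(grid) <= 0)):
        raise ParameterError("ligand grid must be non-negative and strictly increasing")
    if "rates" in truth:
        curve = dose_response(
            truth["rates"], truth.get("variant", "full"), grid, method="direct"
        )
        mean = curve.phi_b
        generator = "model_dose_response"
    else:
        kd, nh, bmax = float(truth["kd"]), float(truth["nh"]), float(truth["bmax"])
        mean = np.zeros_like(grid)
        pos = grid > 0
        mean[pos] = bmax * grid[pos] ** nh / (kd**nh + grid[pos] ** nh)
        generator = "hill_law"
    span = float(mean.max() - mean.min()) or 1.0
    reps, avg, sd = _replicate(mean, span, noise, noise.rng())
    data = TitrationData(ligand_nM=grid, signal=avg, sd=sd if noise.replicates > 1 else None)
    return ExperimentBundle(
        kind="titration",
        truth=dict(truth),
        data=data,
        replicates=reps,
        noise=noise,
        meta={"generator": generator, "seed": noise.seed},
    )


def _phenomenological_unbound(t: np.ndarray, truth: dict[str, Any]) -> np.ndarray:
    y = np.ones_like(t)
    k_fast, a_fast = truth.get("k_fast"), truth.get("a_fast", 0.0)
    k_slow, a_slow = truth.get("k_slow"), truth.get("a_slow", 0.0)
    if k_fast and a_fast:
        y = y - a_fast * (1.0 - np.exp(-float(k_fast) * t))
    if k_slow and a_slow:
        y = y - a_slow * (1.0 - np.exp(-float(k_slow) * t))
    return y


def gen_stopped_flow(
    truth: dict[str, Any],
    protein_nM: float = DEFAULT_PROTEIN_NM,
    ligand_nM: float = DEFAULT_LIGAND_NM,
    window: str = "fast",
    noise: NoiseSpec = NoiseSpec(),
    baseline: float = 0.2,
    amplitude: float = 1.0,
    blank_drift: float = 0.0,
    dead_time_s: float = 0.0,
) -> ExperimentBundle:
    """Synthetic stopped-flow transient plus a protein-only blank.

    ``truth`` is either model-based (``{"rates", "variant"}``; the
    unbound-fraction transient comes from :func:`kinetic_profile`) or
    phenomenological (``{"k_fast", "a_fast", "k_slow", "a_slow"}``; an
    explicit sum of exponential phases, a phase being omitted when its
    rate or amplitude is missing).  The recorded intensity is
    ``baseline + amplitude * phi_ub(t)``, so binding quenches the signal;
    the blank holds the t = 0 intensity, optionally with a linear drift.
    ``dead_time_s`` truncates the first points of the acquisition.
    """
    if window not in WINDOWS:
        raise ParameterError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    t_end, n_points = WINDOWS[window]
    t = np.linspace(0.0, t_end, n_points)
    if dead_time_s > 0:
        t = t[t >= dead_time_s]
    if "rates" in truth:
        profile = kinetic_profile(
            truth["rates"],
            truth.get("variant", "full"),
            L0=ligand_nM,
            R0=protein_nM,
            t_end=float(t[-1]),
            n_points=t.size,
            window="custom",
        )
        # kinetic_profile uses a uniform grid from 0; re-evaluate on t when
        # a dead time shifted the grid
        phi_ub = np.interp(t, profile.time_s + (t[0] if dead_time_s > 0 else 0.0), profile.value)
        generator = "model_kinetics"
    else:
        phi_ub = _phenomenological_unbound(t, truth)
        generator = "exponential_phases"
    mean_intensity = baseline + amplitude * phi_ub
    rng = noise.rng()
    reps, avg, sd = _replicate(mean_intensity, amplitude, noise, rng)
    sample = KineticTrace(
        time_s=t,
        value=avg,
        observable="intensity",
        window=window,
        ligand_nM=ligand_nM,
        receptor_nM=protein_nM,
        sd=sd if noise.replicates > 1 else None,
    )
    blank_mean = np.full_like(t, baseline + amplitude) + blank_drift * t
    _, blank_avg, _ = _replicate(blank_mean, amplitude, noise, rng)
    blank = KineticTrace(
        time_s=t,
        value=blank_avg,
        observable="intensity",
        window=window,
        ligand_nM=0.0,
        receptor_nM=protein_nM,
    )
    return ExperimentBundle(
        kind="stopped_flow",
        truth=dict(truth),
        data=sample,
        blank=blank,
        replicates=reps,
        noise=noise,
        meta={
            "generator": generator,
            "seed": noise.seed,
            "window": window,
            "baseline": baseline,
            "amplitude": amplitude,
        },
    )


def preprocess_traces(raw: KineticTrace, blank: KineticTrace) -> KineticTrace:
    """Normalize to the t = 0 intensity, then subtract the normalized blank.

    Each trace is divided by its own first-point (maximum) intensity; the
    blank-normalized trace is then subtracted pointwise.  The result
    starts at zero and decays as binding quenches the sample, which is
    the form :func:`tsh2bind.estimate.fit_association` expects.
    """
    if raw.time_s.shape != blank.time_s.shape or not np.allclose(raw.time_s, blank.time_s):
        raise ParameterError("sample and blank traces must share the same time grid")
    if raw.value[0] == 0 or blank.value[0] == 0:
        raise ParameterError("cannot normalize a trace whose t=0 intensity is zero")
    corrected = raw.value / raw.value[0] - blank.value / blank.value[0]
    return KineticTrace(
        time_s=raw.time_s.copy(),
        value=corrected,
        observable="normalized_intensity",
        window=raw.window,
        ligand_nM=raw.ligand_nM,
        receptor_nM=raw.receptor_nM,
    )
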