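"""Iterative gradient-descent inference for the cross-domain CRF.

The loop follows three steps: (1) transform the undersampled k-space
data to the spatial domain for the initial (zero-filled) estimate, and
sample the active cliques from its magnitude; (2) compute the analytic
gradient of the total energy; (3) take a descent step, halving the
step size whenever a trial step would increase the energy. Steps 2–3
repeat until the relative energy change falls below ``tol`` or
``max_iters`` is reached, so the recorded energy trace is non-increasing
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .kspace_ops import KSpaceData, inverse_transform
from .crf_model import CRFConfig, CliqueSet, sample_cliques, total_energy, energy_gradient

__all__ = ["SolverConfig", "ReconResult", "SolverDivergenceError", "reconstruct"]

_MAX_BACKTRACKS = 60


class SolverDivergenceError(RuntimeError):
    """Raised when the energy becomes non-finite during optimization."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the gradient-descent loop.

    ``resample_cliques_every = 0`` samples the cliques once from the
    zero-filled guide and keeps them fixed for the whole run.
    ``energy_atol`` is an absolute floor below which the energy counts
    as zero (relative change is meaningless at round-off scale).
    """

    step_size: float = 0.25
    max_iters: int = 500
    tol: float = 1e-6
    energy_atol: float = 1e-18
    resample_cliques_every: int = 0
    record_trace: bool = True

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.energy_atol < 0:
            raise ValueError("energy_atol must be non-negative")
        if self.resample_cliques_every < 0:
            raise ValueError("resample_cliques_every must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolverConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ReconResult:
    """Reconstruction output: magnitude image, energy trace, and status."""

    image: np.ndarray
    energy_trace: list[float]
    iterations: int
    converged: bool
    complex_image: np.ndarray = field(repr=False, default=None)
    cliques: CliqueSet = field(repr=False, default=None)


def reconstruct(
    kdata: KSpaceData, crf: CRFConfig, sol: SolverConfig | None = None
) -> ReconResult:
    """Reconstruct an image from undersampled k-space data.

    Deterministic for fixed configuration seeds. Raises
    :class:`SolverDivergenceError` if the energy ever becomes
    non-finite.
    """
    sol = sol or SolverConfig()
    h, w = kdata.shape
    Y = inverse_transform(kdata.coeffs)
    if not np.all(np.isfinite(Y)):
        raise SolverDivergenceError("non-finite zero-filled initialization")
    guide = np.abs(Y)
    cliques = sample_cliques(h, w, guide, crf)

    energy = total_energy(Y, kdata, guide, cliques, crf)
    if not np.isfinite(energy):
        raise SolverDivergenceError("non-finite energy at initialization")
    trace = [energy]
    iterations = 0
    converged = False

    for it in range(1, sol.max_iters + 1):
        if sol.resample_cliques_every and it % sol.resample_cliques_every == 0:
            resample_cfg = CRFConfig(**{**asdict(crf), "seed": (crf.seed + it) % (2**31 - 1)})
            cliques = sample_cliques(h, w, guide, resample_cfg)
            energy = total_energy(Y, kdata, guide, cliques, crf)
            trace[-1] = energy

        grad = energy_gradient(Y, kdata, guide, cliques, crf)
        if not np.all(np.isfinite(grad)):
            raise SolverDivergenceError(f"non-finite gradient at iteration {it}")

        step = sol.step_size
        accepted = False
        for _ in range(_MAX_BACKTRACKS):
            trial = Y - step * grad
            trial_energy = total_energy(trial, kdata, guide, cliques, crf)
            if np.isfinite(trial_energy) and trial_energy <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no descent direction at any step size: stationary
            break

        rel_change = (energy - trial_energy) / max(energy, np.finfo(float).tiny)
        Y = trial
        energy = trial_energy
        iterations = it
        trace.append(energy)
        if rel_change < sol.tol or energy <= sol.energy_atol:
            converged = True
            break

    if not np.isfinite(energy):
        raise SolverDivergenceError(f"non-finite energy after iteration {iterations}")

    return ReconResult(
        image=np.abs(Y),
        energy_trace=trace if sol.record_trace else [],
        iterations=iterations,
        converged=converged,
        complex_image=Y,
        cliques=cliques,
    )
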