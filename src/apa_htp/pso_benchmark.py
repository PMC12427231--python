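"""Global-best particle swarm benchmark minimizing the hotspot-to-target
quotient over per-antenna amplitudes and phases.

Each particle carries 2N real parameters (amplitudes and phases).  Before
evaluation a candidate is power-normalized, which makes the objective
scale-invariant in the amplitudes by construction.  Velocity/position
updates are the standard constriction-style gbest scheme; amplitudes reflect
at their bounds, phases wrap modulo 360 degrees.  Fully reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apa import ExcitationVector, normalize_power
from .errors import NumericalError
from .fields import FieldMatrix, superpose_field
from .phantom import RegionPartition, TissuePhantom
from .sar_metrics import compute_htq, compute_sar

__all__ = ["PSOConfig", "PSOResult", "run_pso"]


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 100
    max_iter: int = 200
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int = 0
    amplitude_max: float = 10.0
    plateau_window: int = 50
    plateau_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("PSO coefficients must be positive")


@dataclass
class PSOResult:
    best_excitation: ExcitationVector
    best_htq_trace: np.ndarray
    iterations_run: int
    seed: int

    @property
    def best_htq(self) -> float:
        return float(self.best_htq_trace[-1])


def _to_complex(position: np.ndarray, n: int) -> np.ndarray:
    amp, phase_deg = position[:n], position[n:]
    return amp * np.exp(1j * np.deg2rad(phase_deg))


def run_pso(
    matrix: FieldMatrix,
    partition: RegionPartition,
    phantom: TissuePhantom,
    p0_watt: float = 1.0,
    r0_ohm: float | None = None,
    cfg: PSOConfig | None = None,
) -> PSOResult:
    """Minimize HTQ over antenna feedings with a seeded gbest swarm."""
    if cfg is None:
        cfg = PSOConfig()
    if r0_ohm is None:
        r0_ohm = matrix.r0_ohm
    n = matrix.n_antennas
    rng = np.random.default_rng(cfg.seed)

    def objective(position: np.ndarray) -> float:
        b = _to_complex(position, n)
        if not np.any(b):
            return np.inf
        exc = normalize_power(b, p0_watt, r0_ohm)
        sar = compute_sar(superpose_field(matrix, exc.coefficients), phantom, "peak")
        return compute_htq(sar, partition)

    dim = 2 * n
    lo = np.zeros(dim)
    hi = np.concatenate([np.full(n, cfg.amplitude_max), np.full(n, 360.0)])

    pos = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    vel = rng.uniform(-0.1, 0.1, size=(cfg.swarm_size, dim)) * (hi - lo)

    fitness = np.array([objective(p) for p in pos])
    if not np.isfinite(fitness).any():
        raise NumericalError("non-finite objective for every initial particle")

    pbest_pos = pos.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmin(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])

    trace = [gbest_fit]
    for it in range(cfg.max_iter):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest_pos - pos)
            + cfg.social * r2 * (gbest_pos - pos)
        )
        pos = pos + vel

        # amplitudes reflect at [0, amax]
        amp = pos[:, :n]
        over = amp > cfg.amplitude_max
        amp[over] = 2 * cfg.amplitude_max - amp[over]
        under = amp < 0
        amp[under] = -amp[under]
        np.clip(amp, 0.0, cfg.amplitude_max, out=amp)
        vel[:, :n][over | under] *= -1.0
        # phases wrap
        pos[:, n:] %= 360.0

        fitness = np.array([objective(p) for p in pos])
        improved = fitness < pbest_fit
        pbest_pos[improved] = pos[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest_pos = pbest_pos[g].copy()
        trace.append(gbest_fit)

        if len(trace) > cfg.plateau_window:
            past = trace[-cfg.plateau_window - 1]
            if past - gbest_fit <= cfg.plateau_tol * past:
                break

    best_exc = normalize_power(_to_complex(gbest_pos, n), p0_watt, r0_ohm)
    return PSOResult(
        best_excitation=best_exc,
        best_htq_trace=np.asarray(trace),
        iterations_run=len(trace) - 1,
        seed=cfg.seed,
    )
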