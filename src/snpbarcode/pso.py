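"""Particle swarm search over SNP barcodes.

Each particle is a continuous vector of length 2k: k SNP-slot coordinates in
[1, m] followed by k genotype-slot coordinates in [1, 3].  Velocities and
positions follow the classic update

    v_new = w * v_old + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x_new = x_old + v_new

with the inertia weight w decreasing linearly from w_max to w_min over the
iteration budget, r1/r2 uniform on [0, 1], and velocities clamped per
dimension.  The continuous position is decoded to a discrete barcode by
nearest-integer rounding (half away from zero) with clamping; a duplicated
SNP index is repaired by a uniform redraw among the unused indices and the
continuous coordinate is overwritten with the repaired integer.  pbest and
gbest advance only on strict fitness improvement, so runs are reproducible
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .barcode import Barcode, count_matches, fitness
from .genotype_io import GenotypeDataset


@dataclass
class SwarmConfig:
    """Swarm hyperparameters; defaults follow standard practice for this search
    (population 50, 100 iterations, w from 0.9 to 0.4, c1 = c2 = 2)."""

    k: int = 2
    population_size: int = 50
    max_iterations: int = 100
    w_max: float = 0.9
    w_min: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: Optional[np.ndarray] = None  # per-dimension; default = dimension range
    seed: Optional[int] = None
    objective: str = "signed"           # or "absolute"
    stochastic_scope: str = "per_dimension"  # or "per_particle"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 <= self.w_min <= self.w_max:
            raise ValueError("require 0 <= w_min <= w_max")
        if self.k < 2:
            raise ValueError("barcode size k must be >= 2")
        if self.objective not in ("signed", "absolute"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.stochastic_scope not in ("per_particle", "per_dimension"):
            raise ValueError(f"unknown stochastic_scope {self.stochastic_scope!r}")

    def velocity_clamp(self, m: int) -> np.ndarray:
        """v_max per dimension: the dimension's range (m-1 for SNP slots,
        2 for genotype slots) unless overridden."""
        if self.v_max is not None:
            return np.broadcast_to(np.asarray(self.v_max, float), (2 * self.k,)).copy()
        return np.array([float(m - 1)] * self.k + [2.0] * self.k)


@dataclass
class Particle:
    position: np.ndarray            # length 2k, continuous
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: int
    pbest_barcode: Barcode


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: int
    gbest_barcode: Barcode
    iteration: int = 0
    trace: list[int] = field(default_factory=list)  # gbest fitness per iteration


@dataclass
class PSOResult:
    barcode: Barcode
    n_high: int
    n_low: int
    fitness: int
    trace: list[int]
    config: SwarmConfig


def inertia_weight(iteration: int, cfg: SwarmConfig) -> float:
    """Linearly decreasing inertia: w_max at iteration 0, w_min at the end."""
    t, T = iteration, cfg.max_iterations
    if not 0 <= t <= T:
        raise ValueError(f"iteration {t} outside 0..{T}")
    return (cfg.w_max - cfg.w_min) * (T - t) / T + cfg.w_min


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def decode(position: np.ndarray, m: int, rng: np.random.Generator) -> Barcode:
    """Map a continuous position to a valid barcode (repairing duplicates).

    SNP and genotype slots are rounded half away from zero and clamped to
    [1, m] and [1, 3].  When a rounded SNP index collides with an earlier
    slot, the later slot is redrawn uniformly from the unused indices and
    the continuous coordinate is overwritten in place with the repair.
    """
    k = len(position) // 2
    snp = np.clip(_round_half_away(position[:k]), 1, m).astype(int)
    geno = np.clip(_round_half_away(position[k:]), 1, 3).astype(int)
    used: set[int] = set()
    for j in range(k):
        if snp[j] in used:
            pool = [i for i in range(1, m + 1) if i not in used]
            snp[j] = int(rng.choice(pool))
            position[j] = float(snp[j])
        used.add(int(snp[j]))
    return Barcode(tuple(int(i) for i in snp), tuple(int(g) for g in geno)).canonical()


def update_velocity(
    p: Particle,
    gbest_position: np.ndarray,
    w: float,
    cfg: SwarmConfig,
    v_max: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity update with fresh r1, r2 and per-dimension clamping.

    r1 and r2 are drawn per dimension by default (the canonical PSO
    formulation, which keeps the swarm exploring longer on this small
    discrete landscape); ``per_particle`` draws one scalar pair per update.
    """
    if cfg.stochastic_scope == "per_particle":
        r1, r2 = rng.uniform(), rng.uniform()
    else:
        r1 = rng.uniform(size=p.position.shape)
        r2 = rng.uniform(size=p.position.shape)
    v = (
        w * p.velocity
        + cfg.c1 * r1 * (p.pbest_position - p.position)
        + cfg.c2 * r2 * (gbest_position - p.position)
    )
    return np.clip(v, -v_max, v_max)


def update_position(position: np.ndarray, v_new: np.ndarray, m: int) -> np.ndarray:
    """x_new = x_old + v, clamped to [1, m] (SNP slots) and [1, 3] (genotype)."""
    k = len(position) // 2
    x = position + v_new
    x[:k] = np.clip(x[:k], 1.0, float(m))
    x[k:] = np.clip(x[k:], 1.0, 3.0)
    return x


def _evaluate(ds: GenotypeDataset, bc: Barcode, cfg: SwarmConfig, cache: dict) -> tuple[int, int, int]:
    key = (bc.snp_indices, bc.genotype_codes)
    hit = cache.get(key)
    if hit is None:
        n_high, n_low = count_matches(ds, bc)
        hit = (n_high, n_low, fitness(n_high, n_low, cfg.objective))
        cache[key] = hit
    return hit


def init_population(
    cfg: SwarmConfig,
    m: int,
    rng: np.random.Generator,
    ds: GenotypeDataset,
    cache: Optional[dict] = None,
) -> SwarmState:
    """Random initial swarm: SNP slots sampled without replacement per
    particle, genotype slots uniform on {1,2,3}, velocities uniform in
    [-v_max, v_max]; pbest = initial position, gbest = best initial pbest."""
    if cfg.k > m:
        raise ValueError(f"k={cfg.k} exceeds the number of SNPs m={m}")
    cache = {} if cache is None else cache
    v_max = cfg.velocity_clamp(m)
    particles: list[Particle] = []
    for _ in range(cfg.population_size):
        snps = rng.choice(np.arange(1, m + 1), size=cfg.k, replace=False)
        genos = rng.integers(1, 4, size=cfg.k)
        position = np.concatenate([snps, genos]).astype(float)
        velocity = rng.uniform(-v_max, v_max)
        bc = decode(position, m, rng)
        _, _, fit = _evaluate(ds, bc, cfg, cache)
        particles.append(
            Particle(
                position=position,
                velocity=velocity,
                pbest_position=position.copy(),
                pbest_fitness=fit,
                pbest_barcode=bc,
            )
        )
    best = max(particles, key=lambda p: p.pbest_fitness)
    return SwarmState(
        particles=particles,
        gbest_position=best.pbest_position.copy(),
        gbest_fitness=best.pbest_fitness,
        gbest_barcode=best.pbest_barcode,
        trace=[best.pbest_fitness],
    )


def step(
    state: SwarmState,
    ds: GenotypeDataset,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    cache: Optional[dict] = None,
) -> SwarmState:
    """Advance the swarm one iteration (in place; returns the state).

    Every particle moves against the incumbent gbest; pbest is replaced
    only on strict improvement, and gbest is reset after the sweep when
    some pbest strictly exceeds it — ties keep the incumbent."""
    cache = {} if cache is None else cache
    m = ds.n_snps
    w = inertia_weight(state.iteration, cfg)
    v_max = cfg.velocity_clamp(m)
    for p in state.particles:
        p.velocity = update_velocity(p, state.gbest_position, w, cfg, v_max, rng)
        p.position = update_position(p.position, p.velocity, m)
        bc = decode(p.position, m, rng)
        _, _, fit = _evaluate(ds, bc, cfg, cache)
        if fit > p.pbest_fitness:
            p.pbest_fitness = fit
            p.pbest_position = p.position.copy()
            p.pbest_barcode = bc
    best = max(state.particles, key=lambda q: q.pbest_fitness)
    if best.pbest_fitness > state.gbest_fitness:
        state.gbest_fitness = best.pbest_fitness
        state.gbest_position = best.pbest_position.copy()
        state.gbest_barcode = best.pbest_barcode
    state.iteration += 1
    state.trace.append(state.gbest_fitness)
    return state


def run_pso(ds: GenotypeDataset, cfg: SwarmConfig) -> PSOResult:
    """Full swarm run: initialization plus max_iterations steps.

    Returns the global best barcode with its carrier counts, fitness and the
    per-iteration gbest trace.  The dataset must already be dichotomized.
    """
    if ds.group is None:
        raise ValueError("dataset must be dichotomized before the search")
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    state = init_population(cfg, ds.n_snps, rng, ds, cache)
    for _ in range(cfg.max_iterations):
        step(state, ds, cfg, rng, cache)
    n_high, n_low = count_matches(ds, state.gbest_barcode)
    return PSOResult(
        barcode=state.gbest_barcode,
        n_high=n_high,
        n_low=n_low,
        fitness=state.gbest_fitness,
        trace=list(state.trace),
        config=cfg,
    )
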