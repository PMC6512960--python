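"""Bead-spring polymer sampling coupled to the 1D LEF dynamics.

A chromatin fiber is a chain of beads (default 10 kb per bead, one bead per
lattice site) connected by harmonic bonds, with soft-core repulsion that
permits chain crossing, spherical confinement at a target volume density, and
overdamped (Brownian) Langevin dynamics.  Loops held by LEFs appear as extra
harmonic bonds between the current leg positions; the coupled run alternates
one LEF step with a fixed number of integrator steps (default 250).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import lef_engine
from ._kernels import brownian_dynamics
from .errors import ConfigError, IntegrationError
from .lef_engine import Barrier, SimConfig1D


@dataclass
class Conformation:
    """A single chain conformation, coordinates in monomer-diameter units."""

    coordinates: np.ndarray  # (n_monomers, 3)
    monomer_size: float = 10.0  # kb per monomer

    @property
    def n_monomers(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class ForceField:
    """Energies in kT, lengths in monomer diameters, friction sets the time unit.

    ``confinement_density`` is the monomer volume fraction used to derive the
    confinement radius; set it (or ``repulsion_strength``) to 0 to disable the
    corresponding term.  The integration timestep is capped at
    ``0.5 * friction / bond_stiffness`` for Euler stability.
    """

    bond_stiffness: float = 30.0
    bond_rest_length: float = 1.0
    repulsion_strength: float = 3.0
    repulsion_radius: float = 1.0
    confinement_density: float = 0.2
    confinement_stiffness: float = 5.0
    temperature: float = 1.0
    friction: float = 1.0
    timestep: float = 0.01

    def __post_init__(self):
        for name in (
            "bond_stiffness",
            "bond_rest_length",
            "repulsion_strength",
            "repulsion_radius",
            "confinement_density",
            "confinement_stiffness",
            "temperature",
            "friction",
            "timestep",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.timestep <= 0 or self.friction <= 0 or self.bond_stiffness <= 0:
            raise ConfigError("timestep, friction and bond_stiffness must be positive")

    @property
    def effective_timestep(self) -> float:
        return min(self.timestep, 0.5 * self.friction / self.bond_stiffness)

    def confinement_radius(self, n_monomers: int) -> float:
        """Sphere radius holding ``n_monomers`` at the target volume fraction.

        Solves ``n * (pi/6 d^3) = density * (4/3) pi R^3`` with d = 1.
        Returns 0 (confinement off) when the density is 0.
        """
        if self.confinement_density <= 0:
            return 0.0
        return (n_monomers / (8.0 * self.confinement_density)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CouplingSchedule:
    """How 3D integration interleaves with 1D LEF steps.

    ``equilibration_1d_steps = None`` uses the default
    ``max(2 * lifetime_steps, 5 * n_sites)`` LEF steps, covering both LEF
    turnover and the time for a LEF to traverse the chain.
    """

    steps_per_1d: int = 250
    equilibration_1d_steps: int | None = None
    sample_every_1d_steps: int = 10

    def __post_init__(self):
        if self.steps_per_1d < 1:
            raise ConfigError("steps_per_1d must be >= 1")
        if self.sample_every_1d_steps < 1:
            raise ConfigError("sample_every_1d_steps must be >= 1")

    def resolve_equilibration(self, config: SimConfig1D) -> int:
        if self.equilibration_1d_steps is not None:
            return self.equilibration_1d_steps
        return int(max(2 * config.lifetime_steps, 5 * config.n_sites))


@dataclass
class Ensemble:
    """A set of conformations plus the configs and seed that generated them."""

    coordinates: np.ndarray  # (n_conformations, n_monomers, 3)
    monomer_size: float
    seed: int | None = None
    config1d: SimConfig1D | None = None
    forcefield: ForceField | None = None
    schedule: CouplingSchedule | None = None

    @property
    def n_conformations(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.coordinates.shape[1]

    def __iter__(self):
        for xyz in self.coordinates:
            yield Conformation(xyz, self.monomer_size)


def init_conformation(
    n_monomers: int,
    mode: str = "random_walk",
    rng: np.random.Generator | None = None,
    bond_length: float = 1.0,
    monomer_size: float = 10.0,
) -> Conformation:
    """Build a starting conformation with exact unit-bond spacing.

    ``random_walk`` draws isotropic unit steps (exact ideal-chain statistics);
    ``compact_spiral`` lays the chain as a space-filling boustrophedon snake on
    a cubic lattice, giving a compact, deterministic start.
    """
    if n_monomers < 2:
        raise ConfigError(f"n_monomers must be >= 2, got {n_monomers}")
    if mode == "random_walk":
        if rng is None:
            rng = np.random.default_rng(0)
        steps = rng.standard_normal((n_monomers - 1, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        coords = np.vstack([np.zeros(3), np.cumsum(steps * bond_length, axis=0)])
    elif mode == "compact_spiral":
        side = int(np.ceil(n_monomers ** (1.0 / 3.0)))
        coords = np.empty((n_monomers, 3))
        k = 0
        for z in range(side):
            for yy in range(side):
                y = yy if z % 2 == 0 else side - 1 - yy
                xs = range(side) if (z * side + yy) % 2 == 0 else range(side - 1, -1, -1)
                for x in xs:
                    if k >= n_monomers:
                        break
                    coords[k] = (x, y, z)
                    k += 1
        coords = (coords - coords.mean(axis=0)) * bond_length
    else:
        raise ConfigError(f"unknown init mode {mode!r}")
    return Conformation(np.ascontiguousarray(coords, dtype=np.float64), monomer_size)


def _bond_array(n_monomers: int, loop_bonds) -> np.ndarray:
    backbone = np.column_stack(
        [np.arange(n_monomers - 1), np.arange(1, n_monomers)]
    ).astype(np.int64)
    if loop_bonds is None or len(loop_bonds) == 0:
        return np.ascontiguousarray(backbone)
    loops = np.asarray(
        sorted(tuple(b) for b in loop_bonds), dtype=np.int64
    ).reshape(-1, 2)
    if np.any(loops[:, 0] >= loops[:, 1]):
        raise ConfigError("loop bonds must satisfy i < j")
    return np.ascontiguousarray(np.vstack([backbone, loops]))


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def integrate(
    conformation: Conformation,
    forcefield: ForceField,
    loop_bonds=None,
    n_steps: int = 1000,
    rng: np.random.Generator | None = None,
) -> Conformation:
    """Run Brownian dynamics and return the final conformation (input untouched)."""
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.ascontiguousarray(conformation.coordinates, dtype=np.float64).copy()
    bonds = _bond_array(conformation.n_monomers, loop_bonds)
    bad = brownian_dynamics(
        x,
        bonds,
        forcefield.bond_stiffness,
        forcefield.bond_rest_length,
        forcefield.repulsion_strength,
        forcefield.repulsion_radius,
        forcefield.confinement_radius(conformation.n_monomers),
        forcefield.confinement_stiffness,
        forcefield.temperature,
        forcefield.friction,
        forcefield.effective_timestep,
        n_steps,
        _kernel_seed(rng),
    )
    if bad >= 0:
        raise IntegrationError(f"non-finite coordinate at integrator step {bad}")
    return Conformation(x, conformation.monomer_size)


def run_coupled(
    config1d: SimConfig1D,
    barriers: Sequence[Barrier] = (),
    forcefield: ForceField | None = None,
    schedule: CouplingSchedule | None = None,
    seed: int | None = None,
    n_samples: int = 200,
    init_mode: str | None = None,
    conformation: Conformation | None = None,
) -> Ensemble:
    """Run the coupled 1D-LEF / 3D-polymer simulation and sample an ensemble.

    One lattice site corresponds to one monomer.  Each iteration advances the
    LEF system by one step, rebuilds the loop-bond set from the live leg
    positions, and integrates ``schedule.steps_per_1d`` Brownian steps.
    Conformations are stored every ``sample_every_1d_steps`` LEF steps after
    the equilibration phase (during which loops grow in from freshly loaded
    LEFs, so no stretched loop bond is ever introduced).

    By default a confined run starts from the deterministic space-filling
    ``compact_spiral`` conformation, which already sits at the confined
    equilibrium density (a random-walk start would leave the slow chain-scale
    modes relaxing far longer than the TAD-scale observables need); an
    unconfined run starts from an ideal random walk.

    The 1D LEF dynamics and the 3D thermal noise draw from two independent
    streams spawned from ``seed``.  Runs of different conditions launched with
    the same seed therefore share the identical thermal-noise realization
    (common random numbers): slow chain-scale conformational fluctuations
    cancel out of between-condition ratios such as P(s) comparisons, leaving
    the difference driven by the LEF/barrier physics alone.
    """
    forcefield = forcefield or ForceField()
    schedule = schedule or CouplingSchedule()
    if seed is None:
        seed = config1d.seed
    if conformation is not None and conformation.monomer_size != config1d.site_size:
        raise ConfigError(
            f"monomer_size {conformation.monomer_size} kb != 1D site_size "
            f"{config1d.site_size} kb (1 lattice site must map to 1 monomer)"
        )
    n = config1d.n_sites
    seq = np.random.SeedSequence(seed)
    rng, rng_noise = (np.random.default_rng(c) for c in seq.spawn(2))
    if conformation is None:
        if init_mode is None:
            confined = forcefield.confinement_density > 0
            init_mode = "compact_spiral" if confined else "random_walk"
        conformation = init_conformation(
            n, init_mode, rng, forcefield.bond_rest_length, config1d.site_size
        )
    x = np.ascontiguousarray(conformation.coordinates, dtype=np.float64).copy()
    conf_radius = forcefield.confinement_radius(n)
    dt = forcefield.effective_timestep

    block_left, block_right = lef_engine._barrier_arrays(barriers, n)
    state = lef_engine.initial_state(config1d, rng)

    n_equil = schedule.resolve_equilibration(config1d)
    n_prod = n_samples * schedule.sample_every_1d_steps
    samples = np.empty((n_samples, n, 3))
    k = 0
    for step in range(n_equil + n_prod):
        lef_engine._step(state, block_left, block_right, config1d, rng)
        bound = state.legs[:, 0] >= 0
        bonds = _bond_array(n, state.legs[bound])
        bad = brownian_dynamics(
            x,
            bonds,
            forcefield.bond_stiffness,
            forcefield.bond_rest_length,
            forcefield.repulsion_strength,
            forcefield.repulsion_radius,
            conf_radius,
            forcefield.confinement_stiffness,
            forcefield.temperature,
            forcefield.friction,
            dt,
            schedule.steps_per_1d,
            _kernel_seed(rng_noise),
        )
        if bad >= 0:
            raise IntegrationError(
                f"non-finite coordinate at integrator step {bad} of LEF step {step}"
            )
        prod = step - n_equil
        if prod >= 0 and (prod + 1) % schedule.sample_every_1d_steps == 0:
            samples[k] = x
            k += 1
    return Ensemble(
        coordinates=samples[:k],
        monomer_size=config1d.site_size,
        seed=seed,
        config1d=config1d,
        forcefield=forcefield,
        schedule=schedule,
    )
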