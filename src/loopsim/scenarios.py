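"""Preset simulation scenarios for the four canonical perturbations.

All presets share a 36-Mb chain (3600 monomers, 10 kb each), CTCF-like
barriers every 300 kb with alternating orientations, the same LEF velocity and
250 integrator steps per LEF step; they differ only in processivity,
separation and barrier strength:

========== ============ ============ ================
scenario   processivity  separation   barrier strength
========== ============ ============ ================
wt         200 kb        200 kb       0.995
dcohesin   200 kb        2 Mb         0.995
dctcf      200 kb        200 kb       0.9
dwapl      1 Mb          150 kb       0.995
========== ============ ============ ================

``scale_factor`` shrinks the chain for desk-scale runs while preserving the
barrier density, LEF density and processivity (a 0.1-scale WT run is a 3.6-Mb
chain with 12 barriers and 18 LEFs).

The barrier layout alternates orientations starting with a leftward-blocking
barrier, so consecutive pairs alternate convergent (peak-forming) and
divergent.  Presets run barriers in ``transient_halt`` mode, in which a halted
leg re-tests the barrier every step; with the preset strengths this reproduces
the canonical contrasts (a 0.995 barrier outlasts the LEF lifetime, a 0.9
barrier is passed about half the time before unbinding, abolishing TADs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ConfigError
from .lef_engine import (
    LEFTWARD,
    RIGHTWARD,
    TRANSIENT_HALT,
    Barrier,
    SimConfig1D,
)
from .polymer import CouplingSchedule, ForceField

SITE_SIZE_KB = 10.0
FULL_N_SITES = 3600
BARRIER_SPACING_KB = 300.0
#: one LEF step advances both legs by one site, so this velocity makes the
#: simulation time unit equal to one LEF step
VELOCITY_KB = 2.0 * SITE_SIZE_KB

_PRESETS = {
    "wt": dict(processivity=200.0, separation=200.0, strength=0.995),
    "dcohesin": dict(processivity=200.0, separation=2000.0, strength=0.995),
    "dctcf": dict(processivity=200.0, separation=200.0, strength=0.9),
    "dwapl": dict(processivity=1000.0, separation=150.0, strength=0.995),
}


@dataclass
class Scenario:
    """A fully specified simulation condition (1D + barriers + 3D + schedule)."""

    name: str
    config: SimConfig1D
    barriers: tuple
    forcefield: ForceField
    schedule: CouplingSchedule
    scale_factor: float

    def to_json(self, indent: int = 2) -> str:
        d = {
            "schema_version": 1,
            "name": self.name,
            "scale_factor": self.scale_factor,
            "config": dataclasses.asdict(self.config),
            "barriers": [dataclasses.asdict(b) for b in self.barriers],
            "forcefield": dataclasses.asdict(self.forcefield),
            "schedule": dataclasses.asdict(self.schedule),
        }
        return json.dumps(d, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        d = json.loads(text)
        return cls(
            name=d["name"],
            config=SimConfig1D(**d["config"]),
            barriers=tuple(Barrier(**b) for b in d["barriers"]),
            forcefield=ForceField(**d["forcefield"]),
            schedule=CouplingSchedule(**d["schedule"]),
            scale_factor=d["scale_factor"],
        )


def barrier_layout(
    n_sites: int,
    strength: float,
    spacing_kb: float = BARRIER_SPACING_KB,
    site_size: float = SITE_SIZE_KB,
) -> tuple:
    """Barriers every ``spacing_kb``, orientations alternating from leftward.

    The first barrier sits half a spacing into the chain; consecutive pairs
    alternate convergent / divergent.
    """
    spacing = int(round(spacing_kb / site_size))
    sites = range(spacing // 2, n_sites, spacing)
    return tuple(
        Barrier(
            site=s,
            blocked_direction=LEFTWARD if k % 2 == 0 else RIGHTWARD,
            strength=strength,
        )
        for k, s in enumerate(sites)
    )


def scenario(
    name: str,
    scale_factor: float = 1.0,
    seed: int = 0,
    barrier_mode: str = TRANSIENT_HALT,
) -> Scenario:
    """Build a preset scenario, optionally shrunk by ``scale_factor``."""
    if name not in _PRESETS:
        raise ConfigError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(_PRESETS)}"
        )
    if not 0 < scale_factor <= 1:
        raise ConfigError(f"scale_factor must be in (0, 1], got {scale_factor}")
    p = _PRESETS[name]
    n_sites = int(round(FULL_N_SITES * scale_factor))
    config = SimConfig1D(
        n_sites=n_sites,
        site_size=SITE_SIZE_KB,
        separation=p["separation"],
        velocity=VELOCITY_KB,
        lifetime=p["processivity"] / VELOCITY_KB,
        barrier_mode=barrier_mode,
        seed=seed,
    )
    return Scenario(
        name=name,
        config=config,
        barriers=barrier_layout(n_sites, p["strength"]),
        forcefield=ForceField(),
        schedule=CouplingSchedule(),
        scale_factor=scale_factor,
    )


def run_scenario(sc: Scenario, n_samples: int = 200, seed: int | None = None):
    """Run the coupled simulation for a scenario and return the ensemble."""
    from .polymer import run_coupled

    return run_coupled(
        sc.config,
        sc.barriers,
        sc.forcefield,
        sc.schedule,
        seed=seed,
        n_samples=n_samples,
    )
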