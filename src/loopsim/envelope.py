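"""Back-of-envelope calculators for extrusion velocity and ATP budget.

These reproduce the standard sanity checks on whether measured SMC stepping
rates are fast enough to build TADs, and whether loop extrusion is an
energetically significant burden on the cell.
"""

from __future__ import annotations


def velocity_estimate(
    steps_per_sec: float, bp_per_step: float, n_motors: int = 1
) -> float:
    """Extrusion velocity in kb/min from stepping kinetics.

    With ~2 steps/sec and a ~150-bp (one-nucleosome) step, a single motor
    yields ~18 kb/min; a two-motor mechanism doubles this to ~36 kb/min.
    """
    if steps_per_sec < 0 or bp_per_step < 0 or n_motors < 0:
        raise ValueError("all inputs must be non-negative")
    return steps_per_sec * bp_per_step * n_motors * 60.0 / 1000.0


def atp_budget(
    n_extruders: float, atp_per_extruder: float = 2.0, atp_production: float = 1e9
) -> tuple[float, float]:
    """Total extrusion ATP consumption and its share of cellular production.

    Returns ``(rate, fraction_percent)``: with ~100,000 extruding complexes at
    2 ATP/s each against a ~1e9 ATP/s production rate, extrusion costs
    2e5 ATP/s, i.e. 0.02% of the budget.
    """
    if n_extruders < 0 or atp_per_extruder < 0:
        raise ValueError("extruder counts and rates must be non-negative")
    if atp_production <= 0:
        raise ValueError("atp_production must be positive")
    rate = n_extruders * atp_per_extruder
    return rate, 100.0 * rate / atp_production
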