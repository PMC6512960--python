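"""loopsim: loop-extrusion simulation of interphase chromosome folding.

1D stochastic loop-extruding-factor dynamics with directional permeable
barriers, coupled bead-spring polymer sampling, Hi-C-style contact maps,
P(s) curves, and TAD/peak/flame feature scores.
"""

__version__ = "0.1.0"

from .envelope import atp_budget, velocity_estimate
from .errors import (
    ConfigError,
    InfeasibleDensityError,
    IntegrationError,
    LoopsimError,
    StateSpaceError,
    UndefinedScoreError,
)
from .features import (
    FlameScore,
    InsulationProfile,
    PeakScore,
    corner_peak_score,
    flame_score,
    insulation_minima,
    insulation_profile,
    orientation_preference,
)
from .lef_engine import (
    CAPTURE_UNTIL_UNBINDING,
    LEFTWARD,
    RIGHTWARD,
    TRANSIENT_HALT,
    Barrier,
    LEF1DState,
    LEFTrajectory,
    SimConfig1D,
    exact_stationary_small,
    load_lef,
    run_1d,
    step_state,
    transition_matrix_small,
    unobstructed_mean_loop,
)
from .observables import (
    ContactMap,
    PsCurve,
    ShoulderMetric,
    aggregate_contact_map,
    contacts_from_conformation,
    ps_curve,
    ps_slope,
    shoulder_metric,
)
from .polymer import (
    Conformation,
    CouplingSchedule,
    Ensemble,
    ForceField,
    init_conformation,
    integrate,
    run_coupled,
)
from .scenarios import Scenario, barrier_layout, run_scenario, scenario


def build_config(
    site_size: float,
    n_sites: int,
    separation: float,
    velocity: float,
    processivity: float,
    barrier_mode: str = CAPTURE_UNTIL_UNBINDING,
    seed: int = 0,
) -> SimConfig1D:
    """Build a 1D config from the four governing parameters.

    ``processivity = lifetime * velocity`` defines the lifetime; the number of
    bound LEFs is ``round(n_sites * site_size / separation)``.
    """
    if processivity <= 0 or velocity <= 0:
        raise ConfigError("processivity and velocity must be positive")
    return SimConfig1D(
        n_sites=n_sites,
        site_size=site_size,
        separation=separation,
        velocity=velocity,
        lifetime=processivity / velocity,
        barrier_mode=barrier_mode,
        seed=seed,
    )
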