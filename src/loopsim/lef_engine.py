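"""Discrete-time stochastic dynamics of loop-extruding factors (LEFs) on a 1D lattice.

The model is the standard interphase loop-extrusion picture: cohesin-like
motors bind chromatin as two-legged units, grow a loop by translocating their
legs in opposite directions, are halted by collisions with other LEFs and by
directional, permeable barriers (CTCF-bound loci), and exchange with a
nucleoplasmic pool.  Four parameters govern the dynamics: LEF *velocity*
(total loop-growth rate, both legs combined), *lifetime* on chromatin,
*separation* between simultaneously bound LEFs (which sets the LEF number),
and barrier *strength* (1 - permeability).  The product lifetime x velocity,
the *processivity*, is the mean loop an unobstructed LEF extrudes before
unbinding.

Time discretization
-------------------
One simulation step is the time in which an unobstructed LEF grows its loop by
two lattice sites (one per leg), i.e. a step lasts ``2 * site_size / velocity``
time units.  Per step each LEF first unbinds with probability
``1 / lifetime_steps`` (and immediately reloads at a uniformly chosen free
adjacent site pair), otherwise each leg attempts one outward move.  Loop sizes
are recorded as the inclusive monomer span ``(right - left + 1) * site_size``;
with this census the mean loop at unbinding equals the configured processivity
exactly, for any lifetime.

Barrier conventions
-------------------
A barrier occupies a site and blocks *entry* attempts by legs translocating in
its ``blocked_direction``; the block fires with probability ``strength`` per
attempt.  In ``transient_halt`` mode a halted leg re-attempts (and the barrier
re-fires independently) every step; in ``capture_until_unbinding`` mode a
fired barrier captures the leg until the LEF unbinds.  An "inward-pointing"
CTCF motif on the left boundary of a TAD maps to ``blocked_direction =
"leftward"``: it halts legs extruding leftward toward it from inside the TAD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, InfeasibleDensityError, StateSpaceError

LEFTWARD = "leftward"
RIGHTWARD = "rightward"
TRANSIENT_HALT = "transient_halt"
CAPTURE_UNTIL_UNBINDING = "capture_until_unbinding"

_BARRIER_MODES = (TRANSIENT_HALT, CAPTURE_UNTIL_UNBINDING)
_DIRECTIONS = (LEFTWARD, RIGHTWARD)


@dataclass(frozen=True)
class SimConfig1D:
    """Configuration of the 1D LEF lattice simulation.

    Parameters are in genomic units: ``site_size`` in kb per lattice site,
    ``separation`` in kb, ``velocity`` in kb per unit time (total loop-growth
    rate of one LEF, both legs combined), ``lifetime`` in time units.
    """

    n_sites: int
    site_size: float
    separation: float
    velocity: float
    lifetime: float
    barrier_mode: str = CAPTURE_UNTIL_UNBINDING
    seed: int = 0
    #: sub-site barrier re-test granularity in transient_halt mode: a halted
    #: leg re-tests the barrier this many times per step (the coarse 10-kb hop
    #: aggregates ~site_size/1 kb finer hops, each an independent chance to
    #: slip past), so it remains halted with probability strength**retests.
    #: The first encounter always halts with probability = strength.
    retests_per_step: int = 10

    def __post_init__(self):
        if self.n_sites < 2:
            raise ConfigError(f"n_sites must be >= 2, got {self.n_sites}")
        for name in ("site_size", "separation", "velocity", "lifetime"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.barrier_mode not in _BARRIER_MODES:
            raise ConfigError(
                f"barrier_mode must be one of {_BARRIER_MODES}, got {self.barrier_mode!r}"
            )
        if self.n_lefs > self.n_sites // 2:
            raise InfeasibleDensityError(
                f"n_lefs = {self.n_lefs} exceeds lattice capacity "
                f"n_sites/2 = {self.n_sites // 2}"
            )
        if self.retests_per_step < 1:
            raise ConfigError("retests_per_step must be >= 1")
        if self.lifetime_steps < 1.0:
            raise ConfigError(
                "lifetime shorter than one discrete step "
                f"(processivity {self.processivity} kb < velocity step "
                f"{2 * self.site_size} kb); increase processivity or refine the lattice"
            )

    @property
    def processivity(self) -> float:
        """Mean unobstructed loop size, kb (= lifetime x velocity, exact)."""
        return self.lifetime * self.velocity

    @property
    def n_lefs(self) -> int:
        """Number of simultaneously bound LEFs (= chain length / separation)."""
        return int(round(self.n_sites * self.site_size / self.separation))

    @property
    def step_duration(self) -> float:
        """Duration of one discrete LEF step in time units."""
        return 2.0 * self.site_size / self.velocity

    @property
    def lifetime_steps(self) -> float:
        """Mean chromatin residence measured in discrete LEF steps."""
        return self.lifetime / self.step_duration

    @property
    def unbind_prob(self) -> float:
        """Per-step, per-LEF unbinding probability (= 1 / lifetime_steps)."""
        return 1.0 / self.lifetime_steps


@dataclass(frozen=True)
class Barrier:
    """A directional, permeable extrusion barrier at one lattice site.

    ``strength = 1 - permeability`` is the probability that a leg attempting to
    enter ``site`` while translocating in ``blocked_direction`` is halted.
    """

    site: int
    blocked_direction: str
    strength: float

    def __post_init__(self):
        if self.site < 0:
            raise ConfigError(f"barrier site must be >= 0, got {self.site}")
        if self.blocked_direction not in _DIRECTIONS:
            raise ConfigError(
                f"blocked_direction must be one of {_DIRECTIONS}, "
                f"got {self.blocked_direction!r}"
            )
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError(f"strength must be in [0, 1], got {self.strength}")

    @property
    def permeability(self) -> float:
        return 1.0 - self.strength


class LEF1DState:
    """Mutable state of all LEFs on the lattice.

    ``legs[i] = (left_leg, right_leg)`` with ``left_leg < right_leg``; a LEF
    whose reload was deferred (full lattice) has legs ``(-1, -1)``.
    ``captured[i]`` flags legs permanently halted at a barrier
    (capture_until_unbinding mode only); ``pressing[i]`` flags legs currently
    halted against a barrier (transient_halt mode), which re-test it at the
    sub-site granularity on subsequent steps.
    """

    __slots__ = (
        "legs", "captured", "pressing", "occupied", "n_sites", "n_deferred_loads"
    )

    def __init__(self, n_sites: int, n_lefs: int = 0):
        self.n_sites = int(n_sites)
        self.legs = np.full((n_lefs, 2), -1, dtype=np.int64)
        self.captured = np.zeros((n_lefs, 2), dtype=bool)
        self.pressing = np.zeros((n_lefs, 2), dtype=bool)
        self.occupied = np.zeros(self.n_sites, dtype=bool)
        self.n_deferred_loads = 0

    @property
    def n_lefs(self) -> int:
        return self.legs.shape[0]

    def copy(self) -> "LEF1DState":
        new = LEF1DState(self.n_sites, 0)
        new.legs = self.legs.copy()
        new.captured = self.captured.copy()
        new.pressing = self.pressing.copy()
        new.occupied = self.occupied.copy()
        new.n_deferred_loads = self.n_deferred_loads
        return new

    def validate(self) -> None:
        bound = self.legs[:, 0] >= 0
        if not np.all(self.legs[bound, 0] < self.legs[bound, 1]):
            raise AssertionError("left_leg < right_leg violated")
        sites = self.legs[bound].ravel()
        if len(sites) != len(np.unique(sites)):
            raise AssertionError("two legs occupy the same site")


def _free_adjacent_pairs(state: LEF1DState) -> np.ndarray:
    """Left indices i of all site pairs (i, i+1) with both sites unoccupied."""
    free = ~state.occupied
    return np.flatnonzero(free[:-1] & free[1:])


def _place_lef(state: LEF1DState, index: int, rng: np.random.Generator) -> bool:
    """Place LEF ``index`` at a uniformly chosen free adjacent pair.

    Returns False (deferred) when no free adjacent pair exists.
    """
    pairs = _free_adjacent_pairs(state)
    if len(pairs) == 0:
        state.legs[index] = (-1, -1)
        state.captured[index] = False
        state.n_deferred_loads += 1
        return False
    i = int(pairs[rng.integers(len(pairs))])
    state.legs[index] = (i, i + 1)
    state.captured[index] = False
    state.pressing[index] = False
    state.occupied[i] = True
    state.occupied[i + 1] = True
    return True


def load_lef(state: LEF1DState, rng: np.random.Generator) -> LEF1DState:
    """Append one LEF, loaded at a uniformly chosen free adjacent site pair.

    If no free adjacent pair exists the LEF is appended unbound (legs -1) and
    its load deferred to the next step; this is counted, not fatal.
    """
    state.legs = np.vstack([state.legs, [[-1, -1]]])
    state.captured = np.vstack([state.captured, [[False, False]]])
    state.pressing = np.vstack([state.pressing, [[False, False]]])
    _place_lef(state, state.n_lefs - 1, rng)
    return state


def _barrier_arrays(barriers: Sequence[Barrier], n_sites: int):
    """Per-site halt probabilities for leftward- and rightward-moving legs."""
    block_left = np.zeros(n_sites)
    block_right = np.zeros(n_sites)
    for b in barriers:
        if b.site >= n_sites:
            raise ConfigError(f"barrier site {b.site} outside lattice of {n_sites}")
        if b.blocked_direction == LEFTWARD:
            block_left[b.site] = b.strength
        else:
            block_right[b.site] = b.strength
    return block_left, block_right


def _step(
    state: LEF1DState,
    block_left: np.ndarray,
    block_right: np.ndarray,
    config: SimConfig1D,
    rng: np.random.Generator,
    loop_records: list | None = None,
) -> None:
    """Advance the system by one LEF step, in place.

    LEFs update in a fresh random order; a LEF that unbinds reloads immediately
    (its own freed pair is allowed) and does not translocate this step.  Legs
    update left-then-right; a move fails silently if the destination is
    occupied, off-lattice, or a blocking barrier fires.
    """
    u = config.unbind_prob
    capture = config.barrier_mode == CAPTURE_UNTIL_UNBINDING
    k = config.retests_per_step
    legs = state.legs
    captured = state.captured
    pressing = state.pressing
    occupied = state.occupied
    n = state.n_lefs
    order = rng.permutation(n) if n > 1 else range(n)
    for i in order:
        l, r = legs[i]
        if l < 0:  # deferred load from a previous step
            _place_lef(state, i, rng)
            continue
        if rng.random() < u:
            if loop_records is not None:
                loop_records.append((r - l + 1) * config.site_size)
            occupied[l] = False
            occupied[r] = False
            _place_lef(state, i, rng)
            continue
        # left leg moves leftward
        if not captured[i, 0]:
            dest = l - 1
            if dest >= 0 and not occupied[dest]:
                s = block_left[dest]
                if s > 0.0:
                    # first encounter halts with p = strength; a pressing leg
                    # re-tests at sub-site granularity on later steps
                    p_halt = s**k if pressing[i, 0] else s
                    if rng.random() < p_halt:
                        pressing[i, 0] = True
                        if capture:
                            captured[i, 0] = True
                    else:
                        pressing[i, 0] = False
                        occupied[l] = False
                        occupied[dest] = True
                        legs[i, 0] = dest
                        l = dest
                else:
                    pressing[i, 0] = False
                    occupied[l] = False
                    occupied[dest] = True
                    legs[i, 0] = dest
                    l = dest
        # right leg moves rightward
        if not captured[i, 1]:
            dest = r + 1
            if dest < state.n_sites and not occupied[dest]:
                s = block_right[dest]
                if s > 0.0:
                    p_halt = s**k if pressing[i, 1] else s
                    if rng.random() < p_halt:
                        pressing[i, 1] = True
                        if capture:
                            captured[i, 1] = True
                    else:
                        pressing[i, 1] = False
                        occupied[r] = False
                        occupied[dest] = True
                        legs[i, 1] = dest
                else:
                    pressing[i, 1] = False
                    occupied[r] = False
                    occupied[dest] = True
                    legs[i, 1] = dest


def step_state(
    state: LEF1DState,
    barriers: Sequence[Barrier],
    config: SimConfig1D,
    rng: np.random.Generator,
    loop_records: list | None = None,
) -> LEF1DState:
    """Advance ``state`` by one LEF step (in place; returned for chaining)."""
    block_left, block_right = _barrier_arrays(barriers, config.n_sites)
    _step(state, block_left, block_right, config, rng, loop_records)
    return state


def initial_state(config: SimConfig1D, rng: np.random.Generator) -> LEF1DState:
    """Load ``config.n_lefs`` LEFs sequentially at uniform free adjacent pairs."""
    state = LEF1DState(config.n_sites, 0)
    for _ in range(config.n_lefs):
        load_lef(state, rng)
    return state


@dataclass
class LEFTrajectory:
    """Sampled leg positions over time plus loop sizes recorded at unbinding.

    ``frames`` has shape (n_frames, n_lefs, 2); unbound (deferred) LEFs carry
    legs (-1, -1).  ``loop_records`` are in kb.
    """

    frames: np.ndarray
    times: np.ndarray
    loop_records: np.ndarray
    config: SimConfig1D
    barriers: tuple

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def run_1d(
    config: SimConfig1D,
    barriers: Sequence[Barrier] = (),
    n_steps: int = 1000,
    sample_every: int = 1,
    n_equilibration_steps: int = 0,
    rng: np.random.Generator | None = None,
) -> LEFTrajectory:
    """Run the 1D LEF dynamics and return a sampled trajectory.

    Deterministic given ``config.seed`` (or an explicitly passed generator).
    Frames are recorded every ``sample_every`` steps after the equilibration
    phase; loop records accumulate over the whole run.
    """
    if n_steps < 1:
        raise ConfigError(f"n_steps must be >= 1, got {n_steps}")
    if sample_every > n_steps:
        raise ConfigError(
            f"sample_every = {sample_every} exceeds n_steps = {n_steps}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    block_left, block_right = _barrier_arrays(barriers, config.n_sites)
    state = initial_state(config, rng)
    loop_records: list = []
    frames = []
    times = []
    for step in range(n_equilibration_steps + n_steps):
        _step(state, block_left, block_right, config, rng, loop_records)
        prod = step - n_equilibration_steps
        if prod >= 0 and (prod + 1) % sample_every == 0:
            frames.append(state.legs.copy())
            times.append((step + 1) * config.step_duration)
    return LEFTrajectory(
        frames=np.array(frames, dtype=np.int64).reshape(len(frames), config.n_lefs, 2),
        times=np.asarray(times, dtype=float),
        loop_records=np.asarray(loop_records, dtype=float),
        config=config,
        barriers=tuple(barriers),
    )


def unobstructed_mean_loop(
    config: SimConfig1D,
    n_events: int = 10_000,
    rng: np.random.Generator | None = None,
    return_records: bool = False,
):
    """Mean loop size (kb) at unbinding for a lone LEF on an unbounded lattice.

    Realizes the defining experiment for processivity: a single LEF with no
    barriers and no neighbours is stepped until it unbinds (probability
    ``1/lifetime_steps`` per step, checked before the move as in
    :func:`step_state`), its inclusive span recorded, and the cycle repeated
    for ``n_events`` binding events.  All events are advanced step-by-step in
    parallel; the per-step stochastic rule is identical to the lattice engine
    with walls and neighbours removed.  Converges to ``config.processivity``
    as ``n_events`` grows.
    """
    if n_events < 100:
        raise ConfigError(f"n_events must be >= 100, got {n_events}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = config.unbind_prob
    # span in sites, inclusive of both legs; a fresh LEF occupies 2 sites
    span = np.full(n_events, 2, dtype=np.int64)
    active = np.ones(n_events, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        unbinds = rng.random(len(idx)) < u
        active[idx[unbinds]] = False
        span[idx[~unbinds]] += 2
    records = span * config.site_size
    mean = float(records.mean())
    if return_records:
        return mean, records.astype(float)
    return mean


# ---------------------------------------------------------------------------
# Exact small-system oracle
# ---------------------------------------------------------------------------

_STATE_LIMIT = 100_000


FLAG_FREE, FLAG_PRESSING, FLAG_CAPTURED = 0, 1, 2


def _enumerate_states(config: SimConfig1D, flag_values):
    """All joint LEF configurations, as sorted tuples of (l, r, flagL, flagR).

    Flags: 0 = free, 1 = pressing against a barrier (transient_halt),
    2 = captured until unbinding (capture_until_unbinding).
    """
    from itertools import combinations, product

    n_sites, n_lefs = config.n_sites, config.n_lefs
    pairs = [(l, r) for l, r in combinations(range(n_sites), 2)]
    flag_choices = list(product(flag_values, repeat=2))
    singles = [(l, r, fl, fr) for (l, r) in pairs for (fl, fr) in flag_choices]
    states = []
    for combo in combinations(range(len(singles)), n_lefs):
        lefs = tuple(sorted(singles[i] for i in combo))
        sites = [s for lef in lefs for s in lef[:2]]
        if len(sites) == len(set(sites)):
            states.append(lefs)
    return states


def _state_space_estimate(config: SimConfig1D, n_flags: int) -> int:
    from math import comb

    per_lef = comb(config.n_sites, 2) * n_flags * n_flags
    return comb(per_lef, max(config.n_lefs, 1))


def _transition_dist(state, order, config, block_left, block_right):
    """Distribution over successor states for one fixed LEF update order.

    Mirrors :func:`_step` exactly: sequential updates with live occupancy,
    unbind-and-reload atomic (own pair freed first, uniform over free adjacent
    pairs), legs left-then-right, barrier fires with probability = strength.
    """
    u = config.unbind_prob
    capture = config.barrier_mode == CAPTURE_UNTIL_UNBINDING
    k_retest = config.retests_per_step
    halt_flag = FLAG_CAPTURED if capture else FLAG_PRESSING
    n_sites = config.n_sites

    def leg_outcomes(p, pos, flag, dest, occ, strength):
        """(prob, new_pos, new_flag) branches for one leg update."""
        if flag == FLAG_CAPTURED or dest < 0 or dest >= n_sites or dest in occ:
            return [(p, pos, flag)]
        if strength <= 0.0:
            return [(p, dest, FLAG_FREE)]
        p_halt = strength**k_retest if flag == FLAG_PRESSING else strength
        out = []
        if p_halt > 0:
            out.append((p * p_halt, pos, halt_flag))
        if p_halt < 1:
            out.append((p * (1 - p_halt), dest, FLAG_FREE))
        return out

    # branches: list of (prob, list-of-lef-tuples mutable)
    branches = [(1.0, [list(lef) for lef in state])]
    for i in order:
        new_branches = []
        for prob, lefs in branches:
            occupied = set()
            for k, lef in enumerate(lefs):
                if k != i:
                    occupied.add(lef[0])
                    occupied.add(lef[1])
            l, r, fl, fr = lefs[i]
            # --- unbind + reload branch ---
            free = [
                j
                for j in range(n_sites - 1)
                if j not in occupied and (j + 1) not in occupied
            ]
            if u > 0:
                if free:
                    p_each = u / len(free)
                    for j in free:
                        nl = [list(x) for x in lefs]
                        nl[i] = [j, j + 1, FLAG_FREE, FLAG_FREE]
                        new_branches.append((prob * p_each, nl))
                else:  # deferred load is out of scope for the exact oracle
                    raise StateSpaceError(0, _STATE_LIMIT)
            # --- survive branch: legs move left-then-right ---
            survive = prob * (1.0 - u)
            if survive > 0:
                occ = set(occupied) | {l, r}
                for p1, ll, nfl in leg_outcomes(
                    survive, l, fl, l - 1, occ, block_left[l - 1] if l > 0 else 0.0
                ):
                    occ2 = set(occupied) | {ll, r}
                    for p2, rr, nfr in leg_outcomes(
                        p1, r, fr, r + 1, occ2,
                        block_right[r + 1] if r + 1 < n_sites else 0.0,
                    ):
                        nl = [list(x) for x in lefs]
                        nl[i] = [ll, rr, nfl, nfr]
                        new_branches.append((p2, nl))
        branches = new_branches
    dist: dict = {}
    for p, lefs in branches:
        key = tuple(sorted(tuple(x) for x in lefs))
        dist[key] = dist.get(key, 0.0) + p
    return dist


def transition_matrix_small(config: SimConfig1D, barriers: Sequence[Barrier] = ()):
    """Exact one-step transition matrix of the LEF chain on a small system.

    Returns ``(states, T)`` where ``states`` is the list of joint
    configurations (sorted tuples of ``(l, r, flagL, flagR)``; flags: 0 free,
    1 pressing, 2 captured) and ``T[a, b]`` the probability of moving from
    ``states[a]`` to ``states[b]`` in one step, averaged over the random LEF
    update order.
    """
    from itertools import permutations

    if len(barriers) == 0:
        flag_values = (FLAG_FREE,)
    elif config.barrier_mode == CAPTURE_UNTIL_UNBINDING:
        flag_values = (FLAG_FREE, FLAG_CAPTURED)
    else:
        flag_values = (FLAG_FREE, FLAG_PRESSING)
    est = _state_space_estimate(config, len(flag_values))
    if est > _STATE_LIMIT:
        raise StateSpaceError(est, _STATE_LIMIT)
    block_left, block_right = _barrier_arrays(barriers, config.n_sites)
    states = _enumerate_states(config, flag_values)
    index = {s: a for a, s in enumerate(states)}
    n = len(states)
    T = np.zeros((n, n))
    orders = list(permutations(range(config.n_lefs)))
    w = 1.0 / len(orders)
    for a, s in enumerate(states):
        for order in orders:
            for succ, p in _transition_dist(
                s, order, config, block_left, block_right
            ).items():
                T[a, index[succ]] += w * p
    return states, T


def exact_stationary_small(
    config: SimConfig1D, barriers: Sequence[Barrier] = (), tol: float = 1e-12
):
    """Exact stationary distribution of the discrete-time chain (small systems).

    Brute-force oracle: enumerates every joint LEF configuration, builds the
    exact transition matrix, and power-iterates (with 1/2 laziness to remove
    periodicity) to the stationary distribution.  Refuses systems whose state
    space exceeds 1e5 configurations.
    """
    states, T = transition_matrix_small(config, barriers)
    n = len(states)
    pi = np.full(n, 1.0 / n)
    lazy = 0.5 * (T + np.eye(n))
    for _ in range(200_000):
        nxt = pi @ lazy
        if np.abs(nxt - pi).sum() < tol:
            pi = nxt
            break
        pi = nxt
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return states, pi
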