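"""Exception types shared across the package."""


class LoopsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LoopsimError, ValueError):
    """Invalid or inconsistent configuration values."""


class InfeasibleDensityError(ConfigError):
    """More LEFs requested than the lattice can hold (n_lefs > n_sites / 2)."""


class StateSpaceError(LoopsimError):
    """Exact enumeration refused because the state space is too large."""

    def __init__(self, n_states_estimate: int, limit: int):
        self.n_states_estimate = n_states_estimate
        self.limit = limit
        super().__init__(
            f"state space of ~{n_states_estimate} configurations exceeds the "
            f"exact-enumeration limit of {limit}"
        )


class IntegrationError(LoopsimError):
    """Non-finite coordinates encountered during 3D integration."""


class UndefinedScoreError(LoopsimError):
    """A ratio score whose background/expected term is zero."""
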