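"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, numerical failures
(BrokenBondError, IntegrationError, FitError) -> 3.
"""


class CombflowError(Exception):
    """Base class for all package errors."""


class ConfigError(CombflowError):
    """Invalid or inconsistent run configuration / malformed input file."""


class TopologyError(CombflowError):
    """Impossible comb topology request (e.g. more arms than backbone beads)."""


class BrokenBondError(CombflowError):
    """A FENE bond reached or exceeded its maximum extension l0."""

    def __init__(self, bond_index: int, i: int, j: int, r: float, l0: float):
        self.bond_index = bond_index
        self.pair = (i, j)
        self.r = r
        super().__init__(
            f"bond {bond_index} ({i}-{j}) at r={r:.6g} >= l0={l0:.6g}: "
            "broken bond / unstable integration"
        )


class PlacementError(CombflowError):
    """Initial-configuration growth failed; usually the box is too small."""


class IntegrationError(CombflowError):
    """Non-finite coordinates or velocities appeared during time stepping."""


class FitError(CombflowError):
    """An estimator could not produce a meaningful fit from the given series."""
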