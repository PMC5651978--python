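"""Exception types shared across the package."""


class EvacDemError(Exception):
    """Base class for all package-specific errors."""


class DegenerateContactError(EvacDemError):
    """Two bodies coincide so closely that the contact normal is undefined."""


class InvalidGeometryError(EvacDemError):
    """A shape or wall violates its geometric invariants (e.g. zero-length segment)."""


class IntegrationError(EvacDemError):
    """The integrator produced non-finite state; names the agent and step."""

    def __init__(self, agent_id: int, step: int):
        self.agent_id = agent_id
        self.step = step
        super().__init__(
            f"non-finite position/velocity for agent {agent_id} at step {step}"
        )


class PlacementError(EvacDemError):
    """Initial non-overlapping placement of agents failed."""


class ParseError(EvacDemError):
    """A trajectory/event file is malformed; message carries the line number."""
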