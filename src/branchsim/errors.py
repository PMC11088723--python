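"""Exception hierarchy for branchsim."""


class BranchsimError(Exception):
    """Base class for all branchsim errors."""


class InvalidCategoryError(BranchsimError, KeyError):
    """An unknown severity / correctness category code."""


class ScenarioFormatError(BranchsimError, ValueError):
    """A scenario document that cannot be parsed against the schema."""


class ScenarioLinkError(ScenarioFormatError):
    """An option target or start pointer that does not resolve to a node."""


class InvalidScenarioError(BranchsimError, ValueError):
    """A structurally parsed scenario that fails validation rules."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"scenario failed validation: {lines}")


class PlayStateError(BranchsimError, RuntimeError):
    """An engine operation applied to a state in the wrong status."""


class UnknownOptionError(BranchsimError, KeyError):
    """An option id not offered by the current node."""


class PathExplosionError(BranchsimError, RuntimeError):
    """Path enumeration would exceed the configured cap."""


class ParameterError(BranchsimError, ValueError):
    """Invalid or infeasible numeric parameters."""
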