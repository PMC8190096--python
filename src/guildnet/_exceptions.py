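"""Exception hierarchy for guildnet."""


class GuildnetError(Exception):
    """Base class for all guildnet errors."""


class InvalidDesignError(GuildnetError, ValueError):
    """A simulation design field is out of range."""


class CorrelationBlockError(GuildnetError, ValueError):
    """A planted correlation block is not positive definite."""


class LineageParseError(GuildnetError, ValueError):
    """A lineage string contains a malformed rank token."""


class ConsistencyError(GuildnetError, ValueError):
    """Tables that must cover the same taxa do not."""


class GenusGuildConflictError(GuildnetError, ValueError):
    """A genus maps to more than one guild class."""


class MethodAssumptionError(GuildnetError, ValueError):
    """Input violates an assumption of the estimator (e.g. too few genera)."""


class SolverError(GuildnetError, ValueError):
    """The basis-variance linear system is singular."""


class InsufficientDesignError(GuildnetError, ValueError):
    """Too few sites/groups with both arms for the requested contrast."""


class StageFailureError(GuildnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
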