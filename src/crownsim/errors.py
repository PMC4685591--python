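"""Exception hierarchy for crownsim."""


class CrownsimError(Exception):
    """Base class for all crownsim errors."""


class NewickParseError(CrownsimError):
    """Malformed Newick input; the message carries the parser's position info."""


class TreeValidationError(CrownsimError):
    """A tree violates a structural invariant (negative lengths, bad root, ...)."""


class UnknownFixtureError(CrownsimError):
    """Requested fixture name is not in the catalogue."""


class UndefinedCrownError(CrownsimError):
    """Crown group is undefined: fewer than two extant tips."""


class LineageCapError(CrownsimError):
    """A simulation exceeded the living-lineage safety cap (supercritical blow-up)."""


class SurvivorShortfallError(CrownsimError):
    """Survival-conditioned sampling exhausted its batch budget.

    Carries the number of survivors found so callers can diagnose
    near-certain-extinction regimes.
    """

    def __init__(self, message: str, survivors_found: int = 0):
        super().__init__(message)
        self.survivors_found = survivors_found
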