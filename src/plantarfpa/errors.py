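"""Exception hierarchy shared across the package."""


class PlantarFPAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PlantarFPAError, ValueError):
    """A value violates an operation's preconditions."""


class InvalidConfigError(PlantarFPAError, ValueError):
    """A configuration value is out of range or inconsistent."""


class FormatError(PlantarFPAError, ValueError):
    """An on-disk artifact is malformed.

    Carries the offending path and, where known, the line (or row/column)
    so parse failures are actionable.
    """

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f", line {line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DegenerateBoxError(PlantarFPAError, ValueError):
    """An angle-box has zero area, so no foot axis can be derived."""


class DegenerateTestError(PlantarFPAError, ValueError):
    """A statistical test is undefined (e.g. zero error variance)."""


class UndefinedAPError(PlantarFPAError, ValueError):
    """Average precision is undefined because there are no ground truths."""


class EmptyEvaluationError(PlantarFPAError, ValueError):
    """No overlapping non-missing images remain to evaluate."""
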