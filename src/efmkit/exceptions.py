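"""Exception hierarchy.

All efmkit errors derive from :class:`EfmError` so callers can catch the
package's failures with a single except clause while still discriminating
format problems from contract violations.
"""


class EfmError(Exception):
    """Base class for all efmkit errors."""


class FormatError(EfmError, ValueError):
    """An input file is malformed (missing columns, undecodable values)."""


class EmptyTraceError(EfmError, ValueError):
    """Fewer than two valid samples remain after parsing/cleaning."""


class TraceDataError(EfmError, ValueError):
    """A trace violates a data precondition (non-monotone time, too short)."""


class ParameterError(EfmError, ValueError):
    """A parameter is outside its admissible domain."""


class StateError(EfmError, RuntimeError):
    """An operation was called before its prerequisite stage ran."""


class NotSteadyError(StateError):
    """Steady flow was requested from a trace classified non-steady."""


class ValidationError(EfmError, ValueError):
    """A record failed its invariants; the message names the field."""
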