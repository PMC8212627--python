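"""Exception hierarchy shared across labwatch modules."""


class LabwatchError(Exception):
    """Base class for all labwatch errors."""


class ParseError(LabwatchError):
    """A message or file could not be parsed; the message names the offending field."""


class UnitError(LabwatchError):
    """A result carried units with no known conversion to canonical units."""


class ResultValidationError(LabwatchError):
    """A laboratory result violated a field-level invariant."""


class RuleApplicationError(LabwatchError):
    """A rule was applied to a result of a parameter it does not watch."""


class ConfigError(LabwatchError):
    """A configuration document is invalid."""


class ClockRegressionError(LabwatchError):
    """tick() was called with a timestamp earlier than the engine clock."""


class StaleResultError(LabwatchError):
    """A result was older than the configured retention horizon."""


class UnknownPatientError(LabwatchError):
    """An operation referenced a patient the engine has never seen."""


class UnknownAlgorithmError(LabwatchError):
    """An operation referenced an algorithm id not present in the rule configuration."""


class UnknownNotificationError(LabwatchError):
    """A call was recorded against a notification id that does not exist."""


class DuplicateCallError(LabwatchError):
    """A second call was recorded against an already-documented notification."""


class MismatchedLogsError(LabwatchError):
    """Outcome computation was given an event log and engine state from different runs."""
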