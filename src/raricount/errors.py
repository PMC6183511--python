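"""Exception hierarchy for raricount."""


class RaricountError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RaricountError):
    """Malformed or invalid taxa configuration file."""


class UnknownTaxonError(RaricountError):
    """A taxon id that is not part of the session's counting list."""


class DuplicateTaxonError(RaricountError):
    """Attempt to add a taxon whose id already exists."""


class RareModeViolation(RaricountError):
    """Counting a taxon that was excluded when rare mode was entered.

    Mirrors the greyed-out buttons of the counting interface: the action is
    rejected outright and session state is left untouched.
    """


class UndoError(RaricountError):
    """Nothing to undo, or the most recent action is not undoable."""


class StateError(RaricountError):
    """Operation illegal in the session's current mode/state."""


class CheckpointError(RaricountError):
    """Corrupt, unreadable or version-mismatched checkpoint file."""


class SODFormatError(RaricountError):
    """Structurally unreadable SOD file (ragged grid, bad labels, unknown version)."""


class SODValidationError(RaricountError):
    """A document that fails validation against its field definition."""

    def __init__(self, message, findings=None):
        super().__init__(message)
        self.findings = list(findings or [])
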