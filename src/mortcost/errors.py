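"""Exception hierarchy: configuration errors (bad spec/config values) are
distinguished from data errors (inconsistent or incomplete inputs) so the
CLI can map them to distinct exit codes."""


class MortcostError(Exception):
    """Base class for package errors."""


class ConfigurationError(MortcostError, ValueError):
    """A spec or config field violates its invariant."""


class DataError(MortcostError, ValueError):
    """Input data is inconsistent with what an operation requires."""
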