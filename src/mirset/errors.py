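"""Error hierarchy; each fatal class maps to a distinct CLI exit code."""


class MirsetError(Exception):
    """Base class for all fatal errors raised by this package."""

    exit_code = 1


class InputError(MirsetError):
    """A required input file is missing or unreadable, or output is unwritable."""

    exit_code = 2


class FormatError(MirsetError):
    """An input file parsed to zero valid records, or strict parsing hit a bad line."""

    exit_code = 3


class LogicError(MirsetError):
    """Inconsistent in-memory state or an infeasible configuration."""

    exit_code = 4
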