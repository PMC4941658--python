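"""Exception hierarchy.

All msapkit errors derive from :class:`MsapError`; parsing and validation
errors additionally derive from :class:`ValueError` so that generic callers
can catch them without importing this module.
"""


class MsapError(Exception):
    """Base class for all msapkit errors."""


class FormatError(MsapError, ValueError):
    """A file's layout is wrong (bad header, missing column, empty table)."""


class CellValueError(MsapError, ValueError):
    """A single cell holds an illegal value; message carries row/column coordinates."""


class DuplicateIdError(MsapError, ValueError):
    """A locus or gene identifier occurs more than once."""


class ConfigError(MsapError, ValueError):
    """A run or simulation configuration violates its invariants."""
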