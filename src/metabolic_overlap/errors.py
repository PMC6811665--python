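"""Exception hierarchy shared across the package."""


class MetabolicOverlapError(Exception):
    """Base class for all package errors."""


class TableFormatError(MetabolicOverlapError, ValueError):
    """A tabular input file is structurally malformed (missing column, bad cell)."""


class ValidationError(MetabolicOverlapError, ValueError):
    """Input parsed but violates a domain invariant (duplicate id, out-of-range value)."""


class EquationParseError(TableFormatError):
    """A reaction equation string could not be parsed."""


class TreeError(MetabolicOverlapError, ValueError):
    """A phylogenetic tree is malformed or lacks branch lengths."""


class ConfigError(MetabolicOverlapError, ValueError):
    """A simulation or survey configuration is inconsistent."""
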