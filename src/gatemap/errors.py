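"""Exception hierarchy shared across the pipeline."""


class GatemapError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(GatemapError):
    """A coordinate line could not be parsed; the message names the line number."""


class TopologyError(GatemapError):
    """Models of one ensemble disagree in atom identity or order."""


class EmptyInputError(GatemapError):
    """An input stream yielded no usable records."""


class FormatOverflowError(GatemapError):
    """A value does not fit the fixed-column PDB field width."""


class ResidueLookupError(GatemapError):
    """A residue reference did not resolve to exactly one residue."""


class UnsupportedResidueError(GatemapError):
    """Residue type has no entry in the terminal-charged-atom table."""


class EmptySelectionError(GatemapError):
    """A selection (atoms of a residue, RMSD atoms) matched nothing."""


class AlignmentError(GatemapError):
    """Alignment records are inconsistent (lengths, duplicate ids, missing groups)."""


class UnstableRatioError(GatemapError):
    """Residual-current denominator is below the stability floor."""


class TraceError(GatemapError):
    """A current trace violates its sampling or pulse-window contract."""


class GenerationError(GatemapError):
    """A synthetic-data generator could not satisfy its geometric constraints."""


class ConfigError(GatemapError):
    """A run configuration failed schema or file-existence validation."""
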