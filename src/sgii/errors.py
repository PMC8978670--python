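"""Exception hierarchy for the sgii package.

All package-specific failures derive from :class:`SGIIError` so callers
(notably the CLI) can distinguish data problems from programming errors.
"""


class SGIIError(Exception):
    """Base class for all sgii errors."""


class InputFormatError(SGIIError):
    """A malformed input file (edge list, FASTA, labels, config)."""


class NamespaceCollisionError(InputFormatError):
    """An identifier appears both as a lncRNA and as a protein."""


class InvalidSequenceError(SGIIError):
    """A nucleotide sequence that cannot be scored (bad character, too short)."""


class GraphError(SGIIError):
    """Graph too small for a measure, or an unknown node was requested."""


class ConvergenceError(SGIIError):
    """An iterative solver failed to reach its tolerance."""


class MissingScoreError(SGIIError):
    """A scoreable lncRNA lacks a centrality or GIC score at classify time."""


class ConfigError(SGIIError):
    """Invalid parameter values or configuration keys."""
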