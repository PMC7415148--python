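"""Exception hierarchy shared across the package.

Every failure mode carries the offending text so that table-level callers
can skip-and-log individual rows without losing track of what failed.
"""


class LipresidueError(Exception):
    """Base class for all package-specific failures."""


class UnparseableNameError(LipresidueError):
    """A natural-language fatty-acid or ester name could not be decoded."""


class UnparseableChainError(LipresidueError):
    """A chain token (e.g. ``P-22:1``) does not match the chain grammar."""


class MalformedIdentifierError(LipresidueError):
    """Structurally broken identifier, e.g. unbalanced parentheses."""


class UnparseableLipidError(LipresidueError):
    """No parsing route could decode a lipid identifier."""


class NoSampleColumnsError(LipresidueError):
    """Column screening removed every column of an input table."""


class NothingExtractedError(LipresidueError):
    """Every input row failed to parse; the output would be empty."""


class IncompleteDesignError(LipresidueError):
    """A group design references samples that are missing or unpaired."""
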