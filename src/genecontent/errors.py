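"""Exception hierarchy shared across the package."""


class GeneContentError(Exception):
    """Base class for all package-specific errors."""


class InputError(GeneContentError, ValueError):
    """Invalid user-supplied value or inconsistent inputs."""


class TreeError(InputError):
    """Malformed or inconsistent species tree."""


class BlastFormatError(InputError):
    """Malformed BLAST tabular input; message names the offending line."""


class ClusterFormatError(InputError):
    """Malformed cluster file (e.g. a protein listed in two clusters)."""


class QueryError(InputError):
    """Malformed or invalid clade-quantifier query."""
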