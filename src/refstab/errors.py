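"""Exception hierarchy shared across the package."""


class RefStabError(Exception):
    """Base class for all refstab errors."""


class InputError(RefStabError, ValueError):
    """Malformed input file or table (unparseable cell, duplicate key, missing metadata)."""


class ValidationError(RefStabError, ValueError):
    """A Ct matrix violates a structural invariant (bounds, minimum size, labels)."""


class AnalysisError(RefStabError, ValueError):
    """A stability or normalization routine received data it cannot analyse."""
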