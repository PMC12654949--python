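"""Exception hierarchy with stable CLI exit codes."""


class KnotLayersError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(KnotLayersError):
    """Unreadable or missing input (bad path, unknown chain, empty manifest)."""

    exit_code = 3


class FormatError(KnotLayersError):
    """Input exists but cannot be interpreted (parse failures)."""

    exit_code = 4


class EmptyResultError(InputError):
    """Input parsed fine but contained nothing usable (e.g. no nucleotide chains)."""

    exit_code = 3


class ConsistencyError(KnotLayersError):
    """Internal cross-checks failed (index maps, pair/decomposition mismatch)."""

    exit_code = 5


class ModeError(ConsistencyError):
    """Operation received records produced under an incompatible selection mode."""

    exit_code = 5
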