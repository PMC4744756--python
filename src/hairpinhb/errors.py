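"""Exception hierarchy.

Three failure families map onto distinct CLI exit codes: configuration
problems (bad thresholds, malformed bond configs), input/output problems
(missing or structurally broken trajectory files), and computation problems
(e.g. a pathway walk that cannot reach its end state).
"""


class HairpinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HairpinError):
    """Invalid configuration: thresholds, bond definitions, Markov specs."""


class ValidationError(ConfigurationError):
    """Invalid argument values passed to an operation."""


class TrajectoryError(HairpinError):
    """Unreadable or structurally inconsistent trajectory input."""


class AtomLookupError(HairpinError):
    """An atom identifier resolved to zero or more than one atom."""

    def __init__(self, identifier: str, n_matches: int):
        self.identifier = identifier
        self.n_matches = n_matches
        word = "no atoms" if n_matches == 0 else f"{n_matches} atoms"
        super().__init__(f"atom identifier {identifier!r} matched {word} (need exactly 1)")


class AlignmentError(HairpinError):
    """Frame-by-frame alignment between two geometry series failed."""


class PathwayError(HairpinError):
    """The greedy pathway walk got stuck before reaching the end state."""

    def __init__(self, message: str, partial_path: list[str]):
        self.partial_path = list(partial_path)
        super().__init__(f"{message} (partial path: {' -> '.join(partial_path)})")
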