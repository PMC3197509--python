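"""Exception hierarchy for pymedusa."""


class MedusaError(Exception):
    """Base class for all pymedusa errors."""


class DuplicateNodeError(MedusaError):
    """A node with this name already exists in the network."""


class UnknownNodeError(MedusaError):
    """An operation referenced a node name that is not in the network."""


class EdgeTypeCapacityError(MedusaError):
    """Edge-type capacity exceeded: a node pair already carries 8 edge records."""


class DuplicateEdgeError(MedusaError):
    """An edge with the same (source, target, edge_type) identity already exists."""


class InvalidPatternError(MedusaError):
    """A search pattern failed to compile as a regular expression."""


class ParseError(MedusaError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
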