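"""Exception hierarchy for hetpaths."""


class HetPathsError(Exception):
    """Base class for all hetpaths errors."""


class GraphValidationError(HetPathsError, ValueError):
    """Raised when an edge list / type table violates the graph contract."""


class UnknownNodeError(HetPathsError, KeyError):
    """Raised when a queried node id is not present in the graph."""

    def __init__(self, node: str):
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown node id: {self.node!r}"


class MetaPathError(HetPathsError, ValueError):
    """Raised for malformed meta-paths or endpoint/type mismatches."""


class MetricError(HetPathsError, ValueError):
    """Raised for unknown/duplicate metric names or invalid metric parameters."""
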