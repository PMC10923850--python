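"""Exception hierarchy shared across the package."""


class TreestratError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TreestratError, ValueError):
    """A value violates a precondition (non-binary cell, bad prevalence, ...)."""


class ShapeError(TreestratError, ValueError):
    """A vector/matrix does not match the topology it is paired with."""


class CapacityError(TreestratError, ValueError):
    """A problem size exceeds the limit of the requested algorithm."""


class SchemaError(TreestratError, ValueError):
    """A serialized artifact has an unknown or inconsistent schema."""
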