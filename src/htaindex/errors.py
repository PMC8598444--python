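"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


class InferenceError(RuntimeError):
    """Raised when a statistical quantity is degenerate or undefined."""


class CapacityError(RuntimeError):
    """Raised when an exact computation would exceed its enumeration guard."""
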