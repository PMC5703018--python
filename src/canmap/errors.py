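"""Exceptions shared by the attractor modules."""

__all__ = ["VelocityRangeError", "DivergenceError", "UndecodableStateError"]


class VelocityRangeError(ValueError):
    """A velocity is outside the range representable on the nu axis."""


class DivergenceError(RuntimeError):
    """Network rates became non-finite during integration."""


class UndecodableStateError(RuntimeError):
    """The population vector is too weak for a meaningful phase estimate."""
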