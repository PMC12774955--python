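"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class GridError(ValidationError):
    """A sampling grid is too small or inconsistent."""


class SingularSystemError(ValidationError):
    """The two-wavelength extinction matrix is (numerically) singular."""


class ReconstructionError(RuntimeError):
    """The iterative reconstruction diverged (non-finite state)."""
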