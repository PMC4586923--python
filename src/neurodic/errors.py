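"""Exception taxonomy for the package."""


class RangeError(ValueError):
    """A potential (or other quantity) lies outside the model's working range."""


class DesignationError(ValueError):
    """Reference timescales cannot be designated automatically for this model."""


class MarkerError(RuntimeError):
    """A voltage marker (threshold or up-state) could not be located."""


class WindowError(ValueError):
    """A clamp trace does not span the extraction windows."""


class SolverError(RuntimeError):
    """An ODE integration or linear solve failed or is ill-conditioned."""
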