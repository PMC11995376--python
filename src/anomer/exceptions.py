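"""Exception hierarchy shared across the package."""


class AnomerError(Exception):
    """Base class for all package-specific errors."""


class CompositionError(AnomerError, ValueError):
    """Invalid species data or solution composition (negative loadings,
    fractions outside [0, 1], missing species, unknown basis)."""


class ModelValidityError(AnomerError, ValueError):
    """A thermodynamic model was evaluated outside its declared validity
    window, or a parameter combination makes the model unphysical
    (e.g. a non-positive equilibrium isomer ratio)."""


class ConvergenceError(AnomerError, RuntimeError):
    """A numerical routine failed to converge to the requested tolerance."""


class NoSolutionError(AnomerError, RuntimeError):
    """A root-finding bracket contains no sign change: the requested
    equilibrium does not exist for the given parameters."""


class ConfigError(AnomerError, ValueError):
    """A configuration file is missing, unparseable, or violates the
    documented parameter bounds."""
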