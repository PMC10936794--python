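"""Exception hierarchy shared across the package."""


class VentilabError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VentilabError, ValueError):
    """A physical or configuration parameter violates its invariant."""


class ConfigurationError(VentilabError, ValueError):
    """A scenario / controller / benchmark configuration is inconsistent."""


class SignalError(VentilabError, ValueError):
    """A signal fed to a controller or filter is malformed (e.g. non-finite)."""


class AlignmentError(VentilabError, ValueError):
    """Stored and current iteration series have incompatible lengths."""


class DivergenceError(VentilabError, RuntimeError):
    """A closed-loop simulation left its admissible envelope."""


class SchemaError(VentilabError, ValueError):
    """A generated or supplied table does not match the declared schema."""


class EncodingError(VentilabError, ValueError):
    """A category outside the fitted registry was encountered."""


class DegenerateColumnError(VentilabError, ValueError):
    """A column has no spread and cannot be standardized."""


class StratificationError(VentilabError, ValueError):
    """A class is too small to stratify."""


class PlanError(VentilabError, ValueError):
    """A cross-validation plan is infeasible for the sample count."""


class DomainError(VentilabError, ValueError):
    """A rule-network input lies outside its declared discrete domain."""


class DegenerateROCError(VentilabError, ValueError):
    """ROC requested on single-class labels."""
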