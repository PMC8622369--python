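"""Exception hierarchy for caeprep.

All caeprep errors derive from :class:`CaeprepError` so callers can catch the
package's failures with a single ``except`` clause while still receiving the
standard-library category (``ValueError``/``RuntimeError``) they would expect.
"""


class CaeprepError(Exception):
    """Base class for all caeprep errors."""


class ConfigurationError(CaeprepError, ValueError):
    """A parameter or configuration value violates a documented constraint."""


class ShapeError(CaeprepError, ValueError):
    """Array dimensions are incompatible with the requested operation."""


class SplitError(CaeprepError, ValueError):
    """A train/validation split cannot honour its contract (e.g. singleton class)."""


class ParseError(CaeprepError, ValueError):
    """A text input (CSV metric table, config file) could not be parsed."""


class CapabilityError(CaeprepError, RuntimeError):
    """A requested backend or pretrained weight set is not available.

    Raised instead of silently substituting a different model.
    """


class TrainingError(CaeprepError, ValueError):
    """The dataset cannot support the requested training procedure."""
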