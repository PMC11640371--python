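"""Exception hierarchy shared across the pipeline stages."""


class CadEyeError(Exception):
    """Base class for all package errors."""


class ShapeError(CadEyeError, ValueError):
    """An array has the wrong number of axes, channels, or incompatible sizes."""


class ParameterError(CadEyeError, ValueError):
    """A configuration value is outside its admissible set."""


class DataError(CadEyeError, ValueError):
    """Labels, splits or manifests violate a data contract."""
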