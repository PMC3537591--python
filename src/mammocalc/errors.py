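"""Exception hierarchy for the pipeline."""


class MammocalcError(Exception):
    """Base class for all package errors."""


class FormatError(MammocalcError):
    """Unreadable or unsupported image file."""


class ParseError(MammocalcError):
    """Malformed lesion-metadata text; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DimensionError(MammocalcError):
    """Image or window dimensions incompatible with the operation."""


class DegenerateInputError(MammocalcError):
    """Input without enough variation for the operation (e.g. constant image)."""


class DegenerateFeatureError(MammocalcError):
    """A feature column is constant and cannot be standardized."""


class StructureError(MammocalcError):
    """A pyramid or model object is internally inconsistent."""


class LevelError(MammocalcError):
    """Requested decomposition depth exceeds what the input size allows."""


class LabelError(MammocalcError):
    """Class labels missing or single-class where two classes are required."""


class EmptyRegionError(MammocalcError):
    """A region measurement was requested on an empty mask."""


class PlacementError(MammocalcError):
    """Synthetic spot placement could not satisfy its constraints."""


class ConfigError(MammocalcError):
    """Invalid or unknown configuration key/value."""
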