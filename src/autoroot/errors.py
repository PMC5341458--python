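"""Exception types shared across the package."""


class AutoRootError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AutoRootError):
    """Invalid configuration: bad geometry, bounds, mode names, path mismatches."""


class ImageFormatError(AutoRootError):
    """Input image exists but has an unsupported layout or bit depth."""


class EmptyWellError(AutoRootError):
    """Raised by trait operations whose contract requires a non-empty well.

    The batch pipeline never lets this propagate: wells with no detected
    seed points are emitted as flagged all-zero records instead.
    """
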