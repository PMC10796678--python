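"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`ChirpEFRError`
so callers can catch the package's own failures without masking programming
errors.
"""


class ChirpEFRError(Exception):
    """Base class for all chirpefr errors."""


class ConfigurationError(ChirpEFRError, ValueError):
    """A parameter set is internally inconsistent or out of range."""


class AliasingError(ConfigurationError):
    """The requested sample rate cannot represent the requested signal."""


class FixtureFormatError(ChirpEFRError, ValueError):
    """An on-disk epochs/ITPC container is malformed or incomplete."""
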