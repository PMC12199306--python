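"""Exception hierarchy for hypershape."""


class HypershapeError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(HypershapeError):
    """A structure file could not be parsed under its named standard."""


class EmptyMoleculeError(HypershapeError):
    """A parsed structure contained zero atoms."""


class ElementError(HypershapeError):
    """Unknown or unsupported element symbol."""


class FeatureTableError(HypershapeError):
    """Per-atom feature table could not be aligned or parsed."""


class FeatureError(HypershapeError):
    """A feature extractor failed for a specific atom/dimension."""


class FrameError(HypershapeError):
    """Invalid input to the principal-component frame routines."""


class IncomparableFingerprintsError(HypershapeError):
    """Fingerprints differ in length, method, scheme or chirality flag."""


class FixtureSpecError(HypershapeError):
    """Invalid synthetic-fixture specification."""
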