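"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A scenario/config field violates its invariant; message names the field."""


class GridMismatchError(ValueError):
    """Wavelength or time-frequency grids of two objects do not match."""


class RankDeficientError(ValueError):
    """The extinction design matrix is rank-deficient; message names the columns."""


class DegenerateSignalError(ValueError):
    """A zero-variance (flat-line) signal was passed where a CWT is required."""
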