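"""Exception hierarchy shared across the pipeline."""


class HippoatrophyError(Exception):
    """Base class for all package errors."""


class ValidationError(HippoatrophyError, ValueError):
    """Invalid input data or parameters; the message names the offender."""


class SingularDesignError(HippoatrophyError, ValueError):
    """Rank-deficient design matrix; no silent pseudo-inverse is taken."""


class UnderdeterminedError(HippoatrophyError, ValueError):
    """Fewer observations than the fit requires."""


class DegenerateInputError(HippoatrophyError, ValueError):
    """Input with no variance (or otherwise degenerate) where spread is required."""


class MCARNotApplicableError(HippoatrophyError, ValueError):
    """Missing-data test requested on data with a single missingness pattern."""
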