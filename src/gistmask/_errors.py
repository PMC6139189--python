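"""Exception types shared across the pipeline stages."""


class GistMaskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GistMaskError, ValueError):
    """A configuration value is non-physical or inconsistent."""


class BoundsError(GistMaskError, ValueError):
    """A requested region falls outside the slide bounds."""


class FormatError(GistMaskError, ValueError):
    """An input image or table does not have the expected format."""


class GeometryError(GistMaskError, ValueError):
    """An exclusion polygon or window geometry is invalid."""


class InfeasibleSelectionError(GistMaskError, RuntimeError):
    """Fewer disjoint valid windows exist than were requested.

    Carries ``achievable_k``, the largest feasible selection size.
    """

    def __init__(self, requested_k: int, achievable_k: int, kind: str):
        self.requested_k = requested_k
        self.achievable_k = achievable_k
        self.kind = kind
        super().__init__(
            f"cannot select {requested_k} disjoint {kind} windows; "
            f"only {achievable_k} achievable"
        )


class UndefinedScoreError(GistMaskError, ZeroDivisionError):
    """A ratio score is undefined because the pooled denominator is zero."""


class DegenerateInputError(GistMaskError, ValueError):
    """A statistical routine received an input it cannot analyse
    (single-class labels, empty group, constant vector, no events...)."""
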