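"""Exception hierarchy for the PA/US skin-analysis pipeline."""


class PaskinError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PaskinError):
    """Invalid or inconsistent scan geometry (non-monotone positions, bad spans...)."""


class FormatError(PaskinError):
    """A scan container is structurally invalid (missing geometry, shape mismatch)."""


class DataError(PaskinError):
    """Scan payload violates data invariants (NaN, negative amplitudes)."""


class DegenerateInputError(PaskinError):
    """An operation received input with no usable structure (e.g. constant image)."""


class UndefinedMetricError(PaskinError):
    """A lesion metric is undefined for this scan (empty mask, too few samples)."""
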