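"""Exception hierarchy for the embryograd pipeline."""


class EmbryoGradError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EmbryoGradError):
    """Invalid or infeasible configuration (e.g. nuclei cannot be placed)."""


class EmbryoNotFoundError(EmbryoGradError):
    """No sufficiently large bright region in the frame."""


class MultipleEmbryosError(EmbryoGradError):
    """Two comparable bright regions; the frame is ambiguous."""


class AnnulusDegenerateError(EmbryoGradError):
    """Inward offset of the outer boundary self-intersects."""


class OutsideAnnulusError(EmbryoGradError):
    """A point expected inside the nuclear-layer annulus is not."""


class FitError(EmbryoGradError):
    """Nonlinear least-squares gradient fit failed or left its bounds."""


class AlignmentError(EmbryoGradError):
    """Embryos share no overlapping aligned frames."""


class NucleusTooSmallError(EmbryoGradError):
    """Removing the 5x5 spot neighborhood emptied the nucleus."""
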