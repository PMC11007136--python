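"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers can react
to specific failure modes (e.g. a missing label vs. a malformed file) instead
of parsing message strings.
"""


class DigispecError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(DigispecError):
    """A volume file could not be interpreted as a labeled volume."""


class NonIntegerDataError(VolumeFormatError):
    """Voxel data are not integer-typed."""


class UnknownLabelError(VolumeFormatError):
    """Voxel grid contains label codes outside the known set."""


class NonPositiveSpacingError(VolumeFormatError):
    """Voxel spacing has a non-positive component."""


class EmptySupportError(DigispecError):
    """The requested label support contains no voxels."""


class SupportTouchesBoundaryError(DigispecError):
    """The label support touches the grid edge; pad before meshing."""


class AbsentLabelError(DigispecError):
    """A label required for an operation is absent from the grid."""


class GridMismatchError(DigispecError):
    """Two gridded objects do not share shape, spacing and origin."""


class TumorOutsideSpecimenError(DigispecError):
    """The tumor is not strictly inside the specimen support."""


class TumorUnresolvedError(DigispecError):
    """Voxel spacing too coarse to resolve the tumor (<3 voxels on an axis)."""


class TumorAnnihilatedError(DigispecError):
    """An erosion removed every tumor voxel.

    Attributes
    ----------
    min_bias_mm : float
        Smallest (most negative) bias that still leaves the tumor nonempty;
        any requested bias must be strictly greater than this.
    """

    def __init__(self, min_bias_mm: float):
        self.min_bias_mm = float(min_bias_mm)
        super().__init__(
            f"erosion annihilated the tumor; bias must exceed {min_bias_mm:.3f} mm"
        )


class DegenerateLandmarksError(DigispecError):
    """Landmark configuration cannot constrain a similarity transform."""


class LandmarkCountError(DigispecError):
    """Landmark sets have unequal or insufficient point counts."""


class SectionOrderError(DigispecError):
    """Section spacing jitter at least as large as the mean thickness."""


class StackConsistencyError(DigispecError):
    """Transform/spacing counts do not match the section stack."""


class ConeGeometryError(DigispecError):
    """Invalid cone parameters or degenerate reference points."""


class MucosaFitError(DigispecError):
    """Too few or collinear mucosa vertices for a plane fit."""


class NoTumorSectionError(DigispecError):
    """Conventional assessment requires at least one tumor-bearing section."""


class CallsMismatchError(DigispecError):
    """Region-call sequences have different lengths or non-binary entries."""
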