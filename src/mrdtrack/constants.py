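"""Assay-level constants.

The unit conversions here anchor every cell-equivalent calculation in the
package: genomic DNA mass is converted to diploid-genome equivalents at
6.53 pg per human diploid cell, so a 20 ug (2x10^7 pg) input corresponds to
3,062,787 nucleated-cell equivalents.
"""

from dataclasses import dataclass

from .errors import InvalidParameterError

#: Mass of one human diploid genome in picograms.
PG_PER_DIPLOID_CELL = 6.53


@dataclass(frozen=True)
class AssayConstants:
    """Fixed analytical parameters of the assay.

    Parameters
    ----------
    pg_per_diploid_cell:
        DNA mass of one diploid human genome, in pg. Converts input DNA mass
        to total nucleated-cell equivalents.
    detection_target:
        Detection probability defining the limit of detection (LoD): the
        malignant-cell count detected in this fraction of samples.
    rte_threshold:
        Relative-total-error bound defining the limit of quantitation (LoQ):
        the lowest level quantifiable within this RMSE/expected ratio.
    lob_alpha:
        Type-I error rate for the limit of blank (LoB); the LoB is the
        (1 - lob_alpha) quantile of blank-sample measurements.
    """

    pg_per_diploid_cell: float = PG_PER_DIPLOID_CELL
    detection_target: float = 0.95
    rte_threshold: float = 0.70
    lob_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.pg_per_diploid_cell <= 0:
            raise InvalidParameterError("pg_per_diploid_cell must be > 0")
        for name in ("detection_target", "rte_threshold", "lob_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")


DEFAULT_CONSTANTS = AssayConstants()
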