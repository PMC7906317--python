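"""Exception hierarchy shared across the package.

Configuration problems (bad column maps, impossible scenario parameters) are kept
distinct from data problems (rows failing invariants, irreconcilable alleles) so the
CLI can map them to different exit codes.
"""

from __future__ import annotations


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """The run was misconfigured (missing column, bad threshold, absent file)."""


class SumstatsValidationError(MRError):
    """One or more rows of a summary-statistics table violate field invariants.

    Attributes
    ----------
    problems : list of (row, message)
        1-based data-row numbers (header excluded) with a description each.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}: {msg}" for r, msg in self.problems)
        super().__init__(f"invalid summary-statistics rows: {lines}")


class IncompatibleAllelesError(MRError):
    """Exposure and outcome allele sets cannot be reconciled, even after
    strand complementing."""


class EmptyInstrumentSetError(MRError):
    """A filtering or exclusion step left no usable instruments."""


class DegenerateInstrumentError(MRError):
    """A Wald ratio was requested for a variant with a zero exposure effect."""


class InsufficientInstrumentsError(MRError):
    """An estimator's minimum instrument count was not met."""


class SingularDesignError(MRError):
    """Egger regression design matrix is singular (all exposure effects equal)."""


class AllOutliersError(MRError):
    """MR-PRESSO flagged every instrument; no outlier-corrected estimate exists."""


class PipelineError(MRError):
    """A pipeline stage failed; carries the stage name and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.__cause__ = cause
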