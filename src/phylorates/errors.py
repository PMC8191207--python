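"""Typed exceptions and warnings shared across the package."""


class PhyloratesError(Exception):
    """Base class for all package errors."""


class NewickParseError(PhyloratesError, ValueError):
    """Malformed Newick input; the message names the offending token."""


class TreeStructureError(PhyloratesError, ValueError):
    """Tree violates a structural invariant (duplicate tips, bad branch length)."""


class UnknownSpeciesError(PhyloratesError, KeyError):
    """A species/tip label was not found in the tree."""


class RatesTableError(PhyloratesError, ValueError):
    """Branch-rates table is malformed or inconsistent with its tree."""


class FitError(PhyloratesError, ValueError):
    """Regression cannot be computed (singular covariance, constant predictor,
    too few species)."""


class TooFewSpeciesError(FitError):
    """Fewer species with complete data than the configured minimum."""


class NestingError(PhyloratesError, ValueError):
    """Likelihood-ratio inputs violate model nesting (lnL1 < lnL0)."""


class AlignmentError(PhyloratesError, ValueError):
    """Protein alignment is malformed or a requested species is missing."""


class SimulationError(PhyloratesError, ValueError):
    """Invalid simulation configuration or degenerate generated system."""


class ConfigError(PhyloratesError, ValueError):
    """Invalid run configuration."""


class UltrametricityWarning(UserWarning):
    """Root-to-tip path sums differ beyond tolerance; PGLS assumes an
    ultrametric (time-calibrated) tree but remains defined."""
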