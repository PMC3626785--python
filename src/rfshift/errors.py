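"""Exception hierarchy for rfshift."""


class RFShiftError(Exception):
    """Base class for all rfshift errors."""


class CohortFormatError(RFShiftError):
    """Malformed cohort file: missing columns, unknown categories, bad types."""


class CohortIntegrityError(RFShiftError):
    """Cohort rows violate domain invariants (ranges, grids, duplicates)."""


class EmptyDesignError(RFShiftError):
    """No complete-case rows available for a (visit, group, model) design."""


class MatchingError(RFShiftError):
    """Matched sub-cohort cannot be formed (insufficient patients, no labels)."""


class ParameterError(RFShiftError):
    """Invalid fitting parameter (e.g. mtry exceeding the number of predictors)."""


class PredictionError(RFShiftError):
    """Prediction input is missing a predictor used by a tree."""


class SchemaError(RFShiftError):
    """Prediction input columns do not match the training design."""


class DegenerateOutcomeError(RFShiftError):
    """Outcome has zero variance; variance explained is undefined."""


class SimulationError(RFShiftError):
    """Synthetic cohort generation failed (infeasible configuration)."""
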