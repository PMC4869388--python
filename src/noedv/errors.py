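"""Exception hierarchy for dataset validation and measure computation."""


class NoedvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NoedvError):
    """A table does not follow the expected layout (e.g. no phenotype column)."""


class MalformedGenotypeError(NoedvError):
    """A genotype cell is outside {0, 1, 2}; carries the offending row/column."""

    def __init__(self, row: int, column: str, value: object):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"genotype value {value!r} at row {row}, column {column} is not in {{0, 1, 2}}"
        )


class MalformedPhenotypeError(NoedvError):
    """A phenotype entry is outside {0, 1}."""


class DegeneratePhenotypeError(NoedvError):
    """Phenotype carries no information (single class, H(C) = 0)."""


class MissingOrderError(NoedvError):
    """A normalization context was requested for an order with no combinations."""


class UndefinedNormalizationError(NoedvError):
    """The per-order mean co-information magnitude is zero; NCI is undefined."""


class ReferenceError_(NoedvError):
    """An effect list refers to a SNP name unknown to the dataset."""


class InfeasibleModelError(NoedvError):
    """A penetrance model cannot produce the requested case/control quotas."""
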