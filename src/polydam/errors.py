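"""Exception hierarchy for the polydam pipeline."""


class PolydamError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PolydamError):
    """Invalid configuration value."""


class MalformedRecordError(PolydamError):
    """An input record (BED/TSV/WIG line) violates the format contract."""


class AlignmentError(PolydamError):
    """Two per-fragment structures do not share a fragment universe."""


class EmptyLibraryError(PolydamError):
    """A count table sums to zero reads; normalization is undefined."""


class TooFewFragmentsError(PolydamError):
    """Not enough unmasked fragments for a robust statistic."""


class UndefinedStatisticError(PolydamError):
    """A correlation or rate has an empty or zero-variance input."""


class OrderingError(PolydamError):
    """Fragments were not sorted in genome order."""
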