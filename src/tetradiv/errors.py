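"""Exception hierarchy shared by all tetradiv modules."""


class TetradivError(Exception):
    """Base class for all errors raised by tetradiv."""


class ConfigurationError(TetradivError):
    """Invalid user-supplied configuration (rates, thresholds, ploidy...)."""


class FormatError(TetradivError):
    """Malformed on-disk input (FASTA/GFF3/BED/TSV)."""


class ValidationError(FormatError):
    """Record parsed but violates a domain invariant."""


class SimulationError(TetradivError):
    """The simulator cannot satisfy the requested targets."""


class AnalysisError(TetradivError):
    """An analysis stage received inputs it cannot operate on."""


class UndefinedStatisticError(AnalysisError):
    """A requested statistic has no defined value (e.g. zero denominator)."""
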