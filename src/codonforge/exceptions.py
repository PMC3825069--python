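"""Exception hierarchy for codonforge."""


class CodonForgeError(Exception):
    """Base class for all codonforge-specific errors."""


class FrameError(CodonForgeError, ValueError):
    """Sequence length is not a multiple of three (no codon reading frame)."""


class UndefinedStatisticError(CodonForgeError, ValueError):
    """A statistic is undefined for the given input (e.g. no synonymous
    codons, empty count table, constant predictor)."""
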