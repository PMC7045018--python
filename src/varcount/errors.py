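"""Exception hierarchy for the varcount package."""


class VarCountError(Exception):
    """Base class for all varcount errors."""


class ParseError(VarCountError):
    """An input file could not be parsed (message names the offending line where known)."""


class ValidationError(VarCountError):
    """Inputs parsed but violate a contract (bad tokens, duplicate ids, infeasible config)."""


class PhaseError(VarCountError):
    """Compound-heterozygote detection was asked for on unphased genotypes.

    Unphased cohorts must go through trio-based transmission phasing instead
    (:mod:`varcount.trio`).
    """
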