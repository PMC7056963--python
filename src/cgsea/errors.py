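"""Exception hierarchy shared across the package."""


class CgseaError(Exception):
    """Base class for all package-specific errors."""


class InputError(CgseaError):
    """An input file is missing, unreadable, or malformed."""


class ConfigurationError(CgseaError):
    """A run parameter violates its contract (e.g. permutations < 1)."""


class DegenerateSetError(CgseaError):
    """A gene set cannot be scored: no members in the ranked universe,
    or the set spans the whole universe (the miss term is undefined)."""


class DegenerateWeightError(DegenerateSetError):
    """All member statistics are exactly zero with w > 0, so the hit
    normalizer NR vanishes."""


class DegenerateNullError(CgseaError):
    """The permutation null has zero spread; NES is undefined."""
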