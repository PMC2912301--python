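"""Exception types shared across the package."""


class GbpcrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GbpcrError, ValueError):
    """An input violated a documented contract (bad file, bad argument)."""


class UnestimableLevelError(GbpcrError, RuntimeError):
    """A segment's class posterior normalizer is numerically zero.

    This happens when the boundary estimator misses a clear change-point, so
    that no single aberration class can explain the pooled segment; the error
    names the offending segment so the caller can switch to a better boundary
    estimator or raise ``k_max``.
    """

    def __init__(self, chrom, start, end):
        self.chrom = chrom
        self.start = start
        self.end = end
        where = f"{chrom}:" if chrom is not None else ""
        super().__init__(
            f"unestimable level for segment {where}({start}, {end}]: "
            "posterior normalizer is zero; a boundary was likely missed"
        )
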