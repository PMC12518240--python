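"""Exception hierarchy shared across the pipeline stages."""


class EpheclassError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(EpheclassError):
    """A count table or metadata file could not be parsed."""


class ValidationError(EpheclassError):
    """Input data violates a structural invariant (ids, counts, labels)."""


class EmptyDatasetError(EpheclassError):
    """An operation left zero samples (or zero features) to work with."""


class ConsensusUnattainableError(EpheclassError):
    """The consensus feature-selection scan skipped over the requested NSF.

    Carries the scan trace so callers can report which intersection sizes
    were actually attainable.
    """

    def __init__(self, nsf: int, trace: list[tuple[int, int]]):
        self.nsf = nsf
        self.trace = list(trace)
        sizes = ", ".join(f"t={t}:{s}" for t, s in self.trace)
        super().__init__(
            f"could not find a consensus of {nsf} features common to all three "
            f"feature-selection methods (trace: {sizes})"
        )
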