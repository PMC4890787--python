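"""Exception hierarchy shared across the pipeline stages."""


class MbsvError(Exception):
    """Base class for all package errors."""


class CoordinateError(MbsvError):
    """A 1-based coordinate or interval falls outside its sequence."""


class GenerationError(MbsvError):
    """A synthetic-data request is internally inconsistent."""


class ConfigurationError(MbsvError):
    """Invalid or degenerate configuration values."""


class GridError(MbsvError):
    """Two tracks that must share a window/position grid do not."""


class ModelError(MbsvError):
    """A statistical model cannot be fit (singularity, confounding...)."""


class AssemblyError(MbsvError):
    """No derived-allele walk is consistent with the junction evidence."""


class AmbiguousAssemblyError(AssemblyError):
    """Several walks fit the junctions; ``candidates`` lists them all.

    Cassette rotations are indistinguishable from short-read junctions and
    copy counts alone — independent evidence (e.g. the fine-mapped trait
    interval) must pin the insertion locus."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            f"ambiguous assembly: {len(candidates)} junction-consistent orders: "
            f"{candidates}"
        )


class ClassificationError(MbsvError):
    """A junction consensus cannot be reconciled with its flanks."""


class EvidenceError(MbsvError):
    """Recombinant evidence contradicts every candidate copy assignment."""
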