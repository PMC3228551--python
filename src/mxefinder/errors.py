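class MxeError(Exception):
    """Base class for all mxefinder errors."""


class FormatError(MxeError):
    """Malformed input file (FASTA/GFF3/matrix)."""


class StructureError(MxeError):
    """Inconsistent gene structure (overlapping exons, internal stops, ...)."""


class ScoringError(MxeError):
    """Pathological scoring input (e.g. non-positive self-score)."""


class GenerationError(MxeError):
    """Infeasible synthetic-fixture request."""
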