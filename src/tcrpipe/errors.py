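"""Exception hierarchy for the pipeline."""


class TcrPipeError(Exception):
    """Base class for all tcrpipe errors."""


class ReferenceDBError(TcrPipeError):
    """Invalid or inconsistent segment reference."""


class SimulationError(TcrPipeError):
    """Infeasible simulation request (e.g. unplaceable spike-in)."""


class AlignmentError(TcrPipeError):
    """Segment assignment cannot run (e.g. empty reference slice)."""


class FileFormatError(TcrPipeError):
    """Malformed input file; message names the offending record/line."""


class EmptyRepertoireError(TcrPipeError):
    """No eligible reads/clonotypes to aggregate."""


class PipelineError(TcrPipeError):
    """End-to-end pipeline failure."""
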