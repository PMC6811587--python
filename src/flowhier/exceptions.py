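"""Exception hierarchy shared across the package.

All data/validation failures derive from :class:`FlowHierError` so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class FlowHierError(ValueError):
    """Base class for all flowhier data and validation errors."""


class FormatError(FlowHierError):
    """An input file is malformed (missing column, unparsable value)."""


class ReferentialError(FlowHierError):
    """A flow endpoint references a cell id absent from the cell table."""


class EmptyNetworkError(FlowHierError):
    """A trip network carries zero total flow."""


class DegenerateDistributionError(FlowHierError):
    """An outflow distribution is all-zero and has no Lorenz curve."""


class ConsistencyError(FlowHierError):
    """Objects passed together disagree (e.g. a flow endpoint without a level)."""


class AllocationError(FlowHierError):
    """A trip model cannot allocate an origin's out-trips to any destination."""


class CollinearityError(FlowHierError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class SampleSizeError(FlowHierError):
    """Too few complete observations for the requested statistic."""
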