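"""Exception hierarchy for tillerscan.

All operational failures raise a subclass of :class:`TillerscanError` with a
message that names the offending input, so batch drivers can report per-file
errors without dying.
"""


class TillerscanError(Exception):
    """Base class for all tillerscan failures."""


class CloudIOError(TillerscanError):
    """A point-cloud file could not be read or written."""


class MalformedFileError(CloudIOError):
    """A cloud file exists but its content violates the format."""


class EmptyCloudError(TillerscanError):
    """An operation produced or received a cloud with no points."""


class EmptySliceError(TillerscanError):
    """A horizontal slice selected no points."""


class FilterError(TillerscanError):
    """Statistical outlier removal could not run or removed everything."""


class RadiusSearchError(TillerscanError):
    """The stepped radius search exhausted its radius range."""


class DegenerateGeometryError(TillerscanError):
    """Input geometry is too degenerate for the requested operation
    (collinear projection, coplanar cloud, ...)."""


class EmptyMeshError(TillerscanError):
    """The alpha shape contains no boundary triangle at the given alpha."""


class AlphaSweepError(TillerscanError):
    """No alpha in the sweep produced an acceptable reconstruction."""


class EvaluationError(TillerscanError):
    """Accuracy statistics could not be computed (degenerate sample)."""


class SpecError(TillerscanError):
    """A synthetic plant specification is geometrically impossible."""
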