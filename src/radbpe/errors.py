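"""Exception types raised across the pipeline."""


class RadbpeError(Exception):
    """Base class for all package errors."""


class GeometryError(RadbpeError):
    """Phantom geometry is inconsistent (e.g. tumor not strictly inside the breast)."""


class NoBreastFoundError(RadbpeError):
    """Breast segmentation produced an empty mask."""


class InvalidSeedError(RadbpeError):
    """Region-growing seed point lies outside the requested intensity band."""


class DegenerateClusteringError(RadbpeError):
    """Clustering input carries no contrast (all intensities identical, or all
    candidate columns constant)."""


class EmptyRegionError(RadbpeError):
    """An operation that needs at least one valid voxel/sample received none."""


class PairingError(RadbpeError):
    """Paired model comparison received results from different CV partitions."""
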