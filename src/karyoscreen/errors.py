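"""Exception types shared across the package."""


class KaryoscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(KaryoscreenError, ValueError):
    """Invalid configuration (unknown class label, bad parameter value)."""


class GridMismatchError(KaryoscreenError, ValueError):
    """Profiles built on different bin grids were combined."""


class NoInformativeMarkersError(KaryoscreenError, ValueError):
    """Lineage inference attempted with zero informative marker loci."""
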