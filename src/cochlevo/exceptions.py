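"""Exception hierarchy for cochlevo."""


class CochlevoError(Exception):
    """Base class for all package errors."""


class MalformedTreeError(CochlevoError):
    """Newick/NEXUS text could not be parsed into a valid phylogeny."""


class TreeInvariantError(CochlevoError):
    """A parsed tree violates a structural invariant (branch lengths, labels...)."""


class NoOverlapError(CochlevoError):
    """Tree tips and trait-table species share no names."""

    def __init__(self, tip_labels, species):
        self.tip_labels = sorted(tip_labels)
        self.species = sorted(species)
        super().__init__(
            "no overlap between tree tips and trait species; "
            f"tips={self.tip_labels} species={self.species}"
        )


class GeometryError(CochlevoError):
    """Degenerate landmark geometry (too few points, collinear projection...)."""


class InsufficientLandmarksError(GeometryError):
    """A landmark path has fewer than two points."""


class DomainError(CochlevoError):
    """A numeric argument is outside its mathematical domain."""


class SingularDesignError(CochlevoError):
    """Design matrix (or phylogenetic covariance) is rank deficient."""


class ConvergenceError(CochlevoError):
    """An optimiser or sampler failed to converge."""


class ConfigError(CochlevoError):
    """Invalid simulation or pipeline configuration."""
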