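"""Exception hierarchy for geometric build-up solvers."""


class GeobuildError(Exception):
    """Base class for all geobuild errors."""


class DegenerateBase(GeobuildError):
    """A metric base is (near-)coplanar or (near-)collinear and cannot
    uniquely determine a point."""


class InconsistentDistances(GeobuildError):
    """Input distances are mutually inconsistent beyond tolerance; the
    placement residual check failed."""


class NoIntersection(GeobuildError):
    """The three spheres of a 3-point trilateration do not intersect."""


class AmbiguousPlacement(GeobuildError):
    """Both mirror candidates match the disambiguating distance; the
    reference atom is too close to the base plane."""


class NotRealizable(GeobuildError):
    """A distance set admits no embedding in 3-space (fails the
    realizability test)."""


class NoInitialBase(GeobuildError):
    """The distance graph contains no non-degenerate 4-clique to seed the
    build-up."""


class RankDeficient(UserWarning):
    """Cross-covariance rank < 2: the optimal rotation is not unique.
    Issued as a warning; the SVD's deterministic output is used."""


class MismatchedAtoms(GeobuildError):
    """Two structures to be compared do not cover the same atom ids."""


class GenerationFailure(GeobuildError):
    """The synthetic generator exhausted its retry budget."""


class ParseError(GeobuildError):
    """A coordinate or distance-list file is malformed."""


class EmptySelection(GeobuildError):
    """A PDB selection matched no atoms."""


class IndexOutOfRange(GeobuildError):
    """A file refers to an atom index outside the declared range."""
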