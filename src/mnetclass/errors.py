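"""Exceptions and warnings shared across the pipeline stages."""


class MNetClassError(Exception):
    """Base class for all package errors."""


class EmptySample(MNetClassError):
    """A sample column sums to zero and cannot be normalized."""


class AllFiltered(MNetClassError):
    """No taxon survives the abundance/prevalence filter."""


class NoValidThreshold(MNetClassError):
    """No grid threshold yields a permutation-significant scale-free fit."""


class EmptyNetworkError(MNetClassError):
    """An operation requires at least one edge."""


class IsolatedNode(MNetClassError):
    """A random-walk quantity was requested for a degree-zero node."""


class InvalidBlocks(MNetClassError):
    """Planted bicluster blocks overlap or exceed the matrix dimensions."""


class AllConstant(MNetClassError):
    """Every indicator is constant; entropy weights are undefined."""


class SingularFit(MNetClassError):
    """Regression cannot be fitted (zero variance in the predictor)."""


class NoTruth(MNetClassError):
    """Evaluation requested against an empty set of true clusters."""


class FewerThanTwoObjects(MNetClassError):
    """RSR-EWM scoring needs at least two objects."""


class MNetClassWarning(UserWarning):
    """Base class for package warnings."""


class ConstantTaxonWarning(MNetClassWarning):
    """A taxon is constant across samples; its correlations are set to 0."""


class EmptyNetworkWarning(MNetClassWarning):
    """No edge survived sparsification."""


class DegenerateFitWarning(MNetClassWarning):
    """Too few distinct degrees for a power-law fit (R^2 undefined)."""


class SingletonGraphWarning(MNetClassWarning):
    """Path-based indicators are undefined on a single-node graph."""


class ConstantIndicatorWarning(MNetClassWarning):
    """An indicator is constant across objects and carries no weight."""


class MultipleBestWarning(MNetClassWarning):
    """Several objects tie for the best composite score."""


class NegativeSlopeWarning(MNetClassWarning):
    """The WRSR ~ probit regression slope is not positive."""
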