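"""Exception hierarchy for facetlink."""


class FacetLinkError(Exception):
    """Base class for all facetlink errors."""


class ModelInputError(FacetLinkError, ValueError):
    """Non-finite or otherwise invalid numeric input to a model primitive."""


class DimensionError(FacetLinkError, ValueError):
    """Shapes or declared dimensions do not agree."""


class DataError(FacetLinkError, ValueError):
    """A rating dataset violates its contract (scores, indices, duplicates)."""


class DesignError(FacetLinkError, ValueError):
    """An invalid rater-assignment design request (e.g. N_R outside [2, R])."""


class LayoutError(FacetLinkError, ValueError):
    """Common rater/task counts exceed test dimensions or pairs collide."""


class ConfigError(FacetLinkError, ValueError):
    """An experiment or sampler configuration is invalid."""


class ScopeError(FacetLinkError, ValueError):
    """An error-index scope selects no free parameters."""


class ContractError(FacetLinkError, ValueError):
    """An estimation contract was violated (e.g. a masked entry moved)."""


class ParseError(FacetLinkError, ValueError):
    """A file could not be parsed.  Carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
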