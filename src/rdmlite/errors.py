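"""Exception hierarchy for the rdmlite store and pipelines."""


class RdmError(Exception):
    """Base class for all rdmlite validation and pipeline errors."""


class CatalogueError(RdmError):
    """Invalid catalogue structure, rule, or merge document."""


class UnknownDatasetError(CatalogueError):
    """A dataset id or name that the catalogue does not contain."""


class UnknownColumnError(CatalogueError):
    """A column name that the referenced dataset does not contain."""


class LoadError(RdmError):
    """A load-engine precondition failure (not a row-level rejection)."""


class QualityError(RdmError):
    """A data-quality request that cannot be computed."""


class CohortError(RdmError):
    """An invalid filter, definition tree, or commit request."""


class ExtractionError(RdmError):
    """An invalid extraction configuration."""


class ExtractionVetoed(RdmError):
    """A disclosure-control component blocked the release.

    Carries the persisted audit (with crash messages) and, for the CHI
    scanner, the findings that triggered the veto.
    """

    def __init__(self, message, audit=None, findings=None):
        super().__init__(message)
        self.audit = audit
        self.findings = findings or []
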