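"""Exception hierarchy for the toolkit.

All errors raised on bad user input derive from :class:`NeoscreenError` so a
CLI wrapper can catch one base class and exit cleanly.
"""


class NeoscreenError(Exception):
    """Base class for all toolkit errors."""


class FormatError(NeoscreenError):
    """A file (VCF, BED, table) is malformed or violates format invariants."""


class MissingSampleError(NeoscreenError):
    """Requested sample identifier is absent from a VCF header."""


class DegenerateVariantError(NeoscreenError):
    """Variant normalization reduced REF and ALT to identical alleles."""


class PanelError(NeoscreenError):
    """Gene panel definition is internally inconsistent."""


class ScenarioError(NeoscreenError):
    """A synthetic-sample scenario is incompatible with the chosen gene."""


class InsufficientHistoryError(NeoscreenError):
    """Too few historical values to derive a data-driven QC threshold."""


class MissingControlError(NeoscreenError):
    """The per-plate internal control sample (position H12) is absent."""
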