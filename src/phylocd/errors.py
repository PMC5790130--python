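"""Exception hierarchy."""


class PhylocdError(Exception):
    """Base class for all package errors."""


class NewickParseError(PhylocdError, ValueError):
    """Malformed Newick/NEXUS input."""


class ValidationError(PhylocdError, ValueError):
    """Structurally invalid tree, sample, or matrix."""


class DomainError(PhylocdError, ValueError):
    """Operation called outside its domain (e.g. too few shared taxa)."""
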