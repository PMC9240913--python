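"""Exception hierarchy for the contact-analysis pipeline."""


class ContactAnalysisError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ContactAnalysisError):
    """A structure file could not be parsed."""


class NumberingError(ContactAnalysisError):
    """Residue numbering is ambiguous (insertion codes, duplicate indices)."""


class EnsembleError(ContactAnalysisError):
    """Frames or vectors of an ensemble are mutually inconsistent."""


class WindowError(ContactAnalysisError):
    """Residue-index windows of two objects do not match or are invalid."""


class GeometryError(ContactAnalysisError):
    """A requested coordinate fixture is geometrically infeasible."""
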