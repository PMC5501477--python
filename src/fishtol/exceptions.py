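"""Exception hierarchy shared across the package."""


class FishtolError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(FishtolError):
    """Raised on malformed newick input.

    Parameters
    ----------
    message : str
    offset : int, optional
        Character offset into the input at which the problem was detected.
    """

    def __init__(self, message, offset=None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class TreeValidationError(FishtolError):
    """A parsed or constructed tree violates a structural invariant."""


class MalformedLabelError(FishtolError):
    """A tip label does not follow the Family_Genus_species_Code convention."""


class GraftError(FishtolError):
    """Base class for grafting failures."""


class NegativeStemError(GraftError):
    """Requested crown age meets or exceeds the age of the attachment's parent node."""


class NonMonophyleticAttachmentError(GraftError):
    """Selector tips are not monophyletic in the backbone."""

    def __init__(self, message, displaced=()):
        self.displaced = tuple(displaced)
        super().__init__(message)


class LabelCollisionError(GraftError):
    """Donor tip labels collide with backbone tips outside the replaced clade."""


class TaxonomyError(FishtolError):
    """A taxonomy table violates the ranked-hierarchy contract."""
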