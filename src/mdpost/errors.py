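"""Exception hierarchy.

``TransformationRequired`` is a control-flow signal, not a failure: a
calculator catching it knows which derived property to compute and write
back before retrying the load.
"""


class MDPostError(Exception):
    """Base class for all package errors."""


class StoreExistsError(MDPostError):
    """A trajectory store already exists at the target path."""


class ShapeMismatchError(MDPostError):
    """An ingested batch does not match the declared species layout."""


class UnitSystemError(MDPostError):
    """Unit systems of file and store disagree, or an unknown preset."""


class TruncatedFileError(MDPostError):
    """A trajectory file ended mid-frame."""

    def __init__(self, message: str, byte_offset: int | None = None):
        super().__init__(message)
        self.byte_offset = byte_offset


class TransformationRequired(MDPostError):
    """A requested property is absent but derivable from stored data."""

    def __init__(self, species: str | None, property_name: str, hint: str = ""):
        self.species = species
        self.property_name = property_name
        self.hint = hint
        where = f"{species}/" if species else "Observables/"
        msg = f"property '{where}{property_name}' is not stored and needs a transformation"
        if hint:
            msg += f" ({hint})"
        super().__init__(msg)


class MissingInputError(MDPostError):
    """A required raw input is absent and no transformation can produce it."""


class BatchPlanError(MDPostError):
    """Data cannot be processed within the given memory budget."""
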