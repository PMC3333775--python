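"""Exception hierarchy for omicsets."""


class OmicsetsError(Exception):
    """Base class for all omicsets errors."""


class AlignmentError(OmicsetsError):
    """Samples (or genes) of the supplied inputs cannot be aligned."""


class DegeneratePhenotypeError(OmicsetsError):
    """Phenotype carries no usable contrast (one class, no events, ...)."""


class InputError(OmicsetsError):
    """Malformed or non-finite input values."""


class GMTParseError(InputError):
    """A GMT gene set file could not be parsed."""
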