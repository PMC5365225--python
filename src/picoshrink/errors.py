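"""Exception hierarchy for picoshrink."""


class PicoshrinkError(Exception):
    """Base class for all picoshrink errors."""


class FormatError(PicoshrinkError):
    """Input file is not an HDF5/FAST5 file."""


class CorruptFileError(PicoshrinkError):
    """File claims to be HDF5 but cannot be read completely."""


class EncodingError(PicoshrinkError):
    """A value cannot be represented in its declared type descriptor."""


class FastqParseError(PicoshrinkError):
    """A FASTQ dataset does not contain well-formed 4-line records."""


class ProvenanceError(PicoshrinkError):
    """Reversal metadata is missing, corrupt, or of an unknown version."""


class IrreversibleModeError(ProvenanceError):
    """Revert was requested on a file compressed with the irreversible raw
    mode; deleted intermediates can be regenerated only by re-basecalling."""


class StripRefusedError(PicoshrinkError):
    """Stripping intermediates would orphan the read (no raw signal)."""


class ParameterError(PicoshrinkError):
    """Invalid user-supplied parameter."""


class DegenerateDataError(PicoshrinkError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
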