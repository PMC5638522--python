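"""Exception hierarchy shared by all trifibril modules."""


class TrifibrilError(Exception):
    """Base class for all errors raised by trifibril."""


class StructureParseError(TrifibrilError):
    """A PDB record could not be parsed; the message names the line."""


class EmptyStructureError(TrifibrilError):
    """Input contained no ATOM records."""


class StructureFormatError(TrifibrilError):
    """A model cannot be represented in the requested file format."""


class TopologyError(TrifibrilError):
    """Chain count or chain->(filament, layer) map is inconsistent."""


class CongruenceError(TrifibrilError):
    """Two structures/frames that must share an atom list do not."""


class SelectionError(TrifibrilError):
    """A requested chain/residue/atom selection is empty or missing."""


class SequenceError(TrifibrilError):
    """A one-letter sequence contains an unknown residue code."""


class GeometryError(TrifibrilError):
    """A geometric construction (box adjustment, axis) is degenerate."""


class ArgumentError(TrifibrilError, ValueError):
    """An operation was called with an invalid argument value."""
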