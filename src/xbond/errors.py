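"""Exception hierarchy shared across the package."""


class XBondError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(XBondError):
    """A PDB record could not be parsed; the message names the offending line."""


class TopologyError(XBondError):
    """Frames of one trajectory disagree on atom count or identity."""


class SelectionSyntaxError(XBondError):
    """The selection expression violates the grammar; the message gives the position."""


class SpecificationError(XBondError):
    """An analysis specification is inconsistent (wrong multiplicity, bad labels, infeasible targets)."""


class DegenerateGeometryError(XBondError):
    """Coincident or collinear points where a well-defined angle/plane is required."""


class UnknownElementError(XBondError, KeyError):
    """Element symbol absent from the active van der Waals table."""


class ConnectivityError(XBondError):
    """Expected covalent neighbour (e.g. the carbon bonded to a halogen) not found."""
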