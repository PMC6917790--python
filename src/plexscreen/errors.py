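"""Exception hierarchy.

Every fatal condition in the pipeline raises a subclass of
:class:`PlexScreenError`; the CLI maps these to a nonzero exit status with
the failing stage named.
"""


class PlexScreenError(Exception):
    """Base class for all fatal plexscreen errors."""


class InputFormatError(PlexScreenError):
    """Malformed or inconsistent user input (FASTA, mapping CSV, naming)."""


class SearchError(PlexScreenError):
    """Search-stage failure (empty pattern set, enumeration cap exceeded)."""


class ThermoError(PlexScreenError):
    """Thermodynamic model cannot score the requested structure."""


class ExternalToolError(PlexScreenError):
    """An optional external search backend is missing or failed."""
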