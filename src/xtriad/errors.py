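"""Exception hierarchy shared across the package."""


class XTriadError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(XTriadError):
    """Malformed or inconsistent ped/map input."""


class NoDataError(XTriadError):
    """No usable families/markers remain for the requested analysis."""


class TooAmbiguousError(XTriadError):
    """A family admits more phased explanations than the configured cap."""


class WindowUninformativeError(XTriadError):
    """Fewer than two haplotypes remain in a window after pruning."""


class DegenerateParameterError(XTriadError):
    """Parameter values make the model's normalizing constant vanish."""
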