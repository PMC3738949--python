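class WigpeakError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WigpeakError, ValueError):
    """Malformed input file (genome table, alignment file, wig, peak list)."""
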