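class PolyshareError(Exception):
    """Base class for all polyshare errors."""


class InputError(PolyshareError):
    """Invalid user input (bad popmap, bad config, inconsistent samples)."""


class VcfFormatError(InputError):
    """A VCF file could not be parsed."""
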