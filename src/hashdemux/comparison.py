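"""Normalizations kept only for comparison with threshold-based methods.

The demultiplexer itself works exclusively in local (within-cell) CLR
space; the across-cell ("global") CLR used by earlier hashing tools lives
here so the two can be contrasted without being confused.
"""

from .normalization import global_clr

__all__ = ["global_clr"]
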