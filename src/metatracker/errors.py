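"""Exception hierarchy.

``MetatrackerError`` is the base for all data-level failures (malformed
input files, impossible rarefaction depths, misconfigured runs).  The CLI
maps it to exit code 1; usage errors remain exit code 2.
"""


class MetatrackerError(Exception):
    """A problem with the input data or run configuration."""


class ParseError(MetatrackerError):
    """A malformed input file; the message names the file/line where known."""
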