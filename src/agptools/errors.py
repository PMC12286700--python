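"""Exception types shared by every agptools module.

All data errors raised while reading a file carry the file label and,
when known, the 1-based line number of the first offending line, so the
command-line layer can print a message pointing at the exact input that
caused the failure instead of a bare traceback.
"""

from __future__ import annotations


class AgpError(Exception):
    """Base class for all data and format errors raised by agptools."""


class FileFormatError(AgpError):
    """A malformed line in an input file (AGP, FASTA, BED, or operations TSV).

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    file_label:
        Name shown to the user for the offending stream (a path, or e.g.
        ``"<stdin>"``).
    line_number:
        1-based line number of the first bad line, if known.
    """

    def __init__(self, message: str, file_label: str | None = None,
                 line_number: int | None = None):
        self.message = message
        self.file_label = file_label
        self.line_number = line_number
        super().__init__(str(self))

    def __str__(self) -> str:
        prefix = ""
        if self.file_label is not None:
            prefix = self.file_label
            if self.line_number is not None:
                prefix += f", line {self.line_number}"
            prefix += ": "
        elif self.line_number is not None:
            prefix = f"line {self.line_number}: "
        return prefix + self.message


class InvariantError(AgpError):
    """A document or layout constructed in memory violates AGP invariants."""
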