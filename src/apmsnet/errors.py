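"""Exception hierarchy for the AP-MS pipeline.

Every stage raises a subclass of :class:`APMSError` so the CLI can map
failures to a stage-named message and a nonzero exit status.
"""


class APMSError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(APMSError):
    """Invalid simulation or pipeline configuration."""


class EvidenceFormatError(APMSError):
    """Malformed peptide-evidence table; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnmappedPeptideError(APMSError):
    """Peptides mapping to protein IDs absent from the database."""

    def __init__(self, offenders: dict[str, list[str]]):
        self.offenders = offenders
        detail = "; ".join(
            f"{pep} -> {','.join(ids)}" for pep, ids in sorted(offenders.items())
        )
        super().__init__(f"peptides map to unknown protein IDs: {detail}")


class EmptyRunError(APMSError):
    """A run with zero total spectral counts cannot be normalized."""


class BaitNotDetectedError(APMSError):
    """Bait protein absent (or dSAF = 0) in a run that requires bait normalization."""

    def __init__(self, bait_id: str, run_id: str | None = None):
        where = f" in run {run_id}" if run_id else ""
        super().__init__(f"bait {bait_id!r} not detected{where}; cannot compute dBNSAF")
        self.bait_id = bait_id
        self.run_id = run_id


class DefinitionError(APMSError):
    """Invalid complex-definition table (duplicates, empty subunit lists)."""
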