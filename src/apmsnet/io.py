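"""Readers and writers for the pipeline's plain-text interchange formats.

Formats
-------
* protein database: FASTA (headers are protein IDs; lengths are residue counts)
* peptide evidence: TSV with columns ``peptide``, ``spectral_count``,
  ``protein_ids`` (semicolon-separated accessions)
* sample sheet: TSV with columns ``run_id``, ``bait_id``, ``condition``
  (``N`` | ``C`` | ``control``), ``replicate`` and an optional
  ``cell_context`` label

The evidence TSV is the interchange format of the pipeline: search-engine
output (e.g. DTASelect filter tables) is expected to be flattened to this
three-column contract upstream.  Duplicate peptide rows are merged by summing
their counts and taking the union of their mapping sets.

Also houses :func:`contour_length`, the worked polypeptide-extension example
used when judging whether an affinity-tag linker can span a complex.
"""

from __future__ import annotations

import io as _io
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EvidenceFormatError, ConfigurationError

EVIDENCE_COLUMNS = ("peptide", "spectral_count", "protein_ids")
SAMPLE_COLUMNS = ("run_id", "bait_id", "condition", "replicate", "cell_context")
VALID_CONDITIONS = frozenset({"N", "C", "control"})

#: Contour rise of one residue in a fully extended polypeptide chain, in Å.
RISE_PER_RESIDUE = 3.8


class ProteinDB:
    """Protein database: ordered mapping of protein ID to amino-acid sequence.

    Lengths (residue counts of the full database entry, tag included if the
    tagged construct is the entry) are the denominator of dSAF.
    """

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = sequences.items() if isinstance(sequences, Mapping) else sequences
        self._seqs: dict[str, str] = {}
        for pid, seq in items:
            if pid in self._seqs:
                raise ConfigurationError(f"duplicate protein ID {pid!r} in database")
            if len(seq) < 1:
                raise ConfigurationError(f"empty sequence for protein {pid!r}")
            self._seqs[pid] = str(seq)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinDB":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ConfigurationError(f"no FASTA records in {path}")
        return cls((r.id, str(r.seq)) for r in records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=pid, description="") for pid, seq in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {pid: len(seq) for pid, seq in self._seqs.items()}

    def sequence(self, protein_id: str) -> str:
        return self._seqs[protein_id]

    def length(self, protein_id: str) -> int:
        return len(self._seqs[protein_id])

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProteinDB) and self._seqs == other._seqs


def read_protein_fasta(path: str | Path) -> ProteinDB:
    """Read a protein FASTA into a :class:`ProteinDB`.

    Case of the sequence is irrelevant for lengths; duplicate IDs raise.
    """
    return ProteinDB.from_fasta(path)


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide-evidence TSV.

    Returns a DataFrame with columns ``peptide`` (str), ``spectral_count``
    (int) and ``proteins`` (sorted tuple of protein IDs).  Duplicate peptide
    rows are merged: counts summed, mapping sets unioned.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if list(header) != list(EVIDENCE_COLUMNS):
            raise EvidenceFormatError(
                f"expected header {list(EVIDENCE_COLUMNS)}, got {header}", line=1
            )
        rows: list[tuple[str, int, tuple[str, ...]]] = []
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != 3:
                raise EvidenceFormatError(
                    f"expected 3 tab-separated fields, got {len(fields)}", line=lineno
                )
            pep, count_s, ids_s = fields
            try:
                count = int(count_s)
            except ValueError:
                raise EvidenceFormatError(
                    f"spectral_count {count_s!r} is not an integer", line=lineno
                ) from None
            if count < 0:
                raise EvidenceFormatError(
                    f"negative spectral_count {count}", line=lineno
                )
            ids = tuple(sorted({p for p in ids_s.split(";") if p}))
            if not ids:
                raise EvidenceFormatError("empty protein_ids field", line=lineno)
            rows.append((pep, count, ids))
    return _merge_evidence_rows(rows)


def _merge_evidence_rows(
    rows: Iterable[tuple[str, int, tuple[str, ...]]]
) -> pd.DataFrame:
    counts: dict[str, int] = {}
    mappings: dict[str, set[str]] = {}
    order: list[str] = []
    for pep, count, ids in rows:
        if pep not in counts:
            counts[pep] = 0
            mappings[pep] = set()
            order.append(pep)
        counts[pep] += count
        mappings[pep].update(ids)
    return pd.DataFrame(
        {
            "peptide": order,
            "spectral_count": [counts[p] for p in order],
            "proteins": [tuple(sorted(mappings[p])) for p in order],
        }
    )


def evidence_frame(
    rows: Iterable[tuple[str, int, Iterable[str]]]
) -> pd.DataFrame:
    """Build an evidence DataFrame in memory (same merge rule as the reader)."""
    return _merge_evidence_rows(
        [(p, int(c), tuple(sorted(set(ids)))) for p, c, ids in rows]
    )


def write_evidence_table(evidence: pd.DataFrame, path: str | Path) -> None:
    out = evidence.copy()
    out["protein_ids"] = out["proteins"].map(";".join)
    out[["peptide", "spectral_count", "protein_ids"]].to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV and validate its contract."""
    sheet = pd.read_csv(path, sep="\t", dtype={"run_id": str, "bait_id": str})
    missing = [c for c in SAMPLE_COLUMNS[:4] if c not in sheet.columns]
    if missing:
        raise EvidenceFormatError(f"sample sheet missing columns {missing}")
    if "cell_context" not in sheet.columns:
        sheet["cell_context"] = ""
    sheet["cell_context"] = sheet["cell_context"].fillna("")
    validate_sample_sheet(sheet)
    return sheet[list(SAMPLE_COLUMNS)]


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    if sheet["run_id"].duplicated().any():
        dupes = sheet.loc[sheet["run_id"].duplicated(), "run_id"].tolist()
        raise EvidenceFormatError(f"duplicate run_ids in sample sheet: {dupes}")
    bad = set(sheet["condition"]) - VALID_CONDITIONS
    if bad:
        raise EvidenceFormatError(
            f"invalid condition labels {sorted(bad)}; expected one of {sorted(VALID_CONDITIONS)}"
        )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in sheet.columns]
    sheet[cols].to_csv(path, sep="\t", index=False)


def contour_length(n_residues: int, rise_per_residue: float = RISE_PER_RESIDUE) -> float:
    """Contour length (Å) of ``n_residues`` of fully extended polypeptide.

    The maximal end-to-end distance of an unstructured linker is the residue
    count times the per-residue rise (default 3.8 Å), e.g. the 27 exogenous
    residues between a HaloTag and its fusion partner span up to 102.6 Å.
    """
    if n_residues < 0:
        raise ConfigurationError("n_residues must be non-negative")
    if rise_per_residue <= 0:
        raise ConfigurationError("rise_per_residue must be positive")
    return n_residues * rise_per_residue


def frame_to_tsv_text(frame: pd.DataFrame) -> str:
    """Render a DataFrame as full-precision TSV text (byte-stable for diffs)."""
    buf = _io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    return buf.getvalue()
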