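"""Synthetic AP-MS spectral-count experiments with known ground truth.

Emulates the design of a tag-position comparison: two bait paralogs
(HDAC1/HDAC2) each expressed with an N-terminal or C-terminal affinity tag
(3 biological replicates per construct) plus tag-only control runs.  Capture
of annotated complexes is condition dependent — the N-tag condition favors
the chaperone machinery (CCT, prefoldin), the C-tag condition the
deacetylase corepressor complexes (Sin3, NuRD, CoREST, MiDAC) — and a
log-normal "frequent flyer" contaminant background is common to bait and
control runs.

Count model: each run draws a fixed total of T spectra multinomially over
the proteins present, with weights a_k · L_k (relative molar abundance times
length — spectral counts scale with length, the premise of SAF
normalization), then multinomially over each protein's nominal peptides.
Proteins get ⌈L/30⌉ nominal peptides; within a paralog family a configured
fraction of peptides is shared by the whole family (tryptic fragmentation is
not simulated — the shared/unique structure is all the quantitation stage
consumes).

Ground truth: the expected dBNSAF of prey p for bait b is a_p / a_b, since
dSAF ∝ a·L/L = a in expectation.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    ProteinDB,
    evidence_frame,
    read_evidence_table,
    read_sample_sheet,
    write_evidence_table,
    write_sample_sheet,
)
from .profiles import load_builtin_complexes

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Residue counts of the real proteins behind the default database entries
#: (baits, tag, and the curated complex subunits).  Using real lengths keeps
#: paralog families length-homogeneous, as homologs are.
KNOWN_LENGTHS = {
    "HDAC1": 482,
    "HDAC2": 488,
    "HaloTag": 297,
    "TCP1": 556,
    "CCT2": 535,
    "CCT3": 545,
    "CCT4": 539,
    "CCT5": 541,
    "CCT6A": 531,
    "CCT7": 543,
    "CCT8": 548,
    "PFDN1": 122,
    "PFDN2": 154,
    "PFDN4": 134,
    "PFDN5": 154,
    "PFDN6": 129,
    "VBP1": 197,
    "SIN3A": 1273,
    "SAP18": 153,
    "SAP30": 220,
    "SAP130": 1047,
    "SUDS3": 328,
    "ARID4B": 1312,
    "ING1": 422,
    "RBBP4": 425,
    "RBBP7": 469,
    "CHD3": 2000,
    "CHD4": 1912,
    "MTA1": 715,
    "MTA2": 668,
    "MTA3": 594,
    "GATAD2A": 633,
    "GATAD2B": 593,
    "MBD2": 411,
    "MBD3": 291,
    "RCOR1": 482,
    "RCOR3": 495,
    "KDM1A": 852,
    "HMG20B": 317,
    "PHF21A": 680,
    "DNTTIP1": 329,
    "ELMSAN1": 1023,
    "TRERF1": 1200,
}

#: Condition-dependent complex capture efficiencies.  The favored condition
#: captures strongly; the disfavored one only at trace level.
DEFAULT_CAPTURE: dict[tuple[str, str], float] = {
    ("CCT", "N"): 0.6,
    ("prefoldin", "N"): 0.4,
    ("Sin3", "N"): 0.004,
    ("NuRD", "N"): 0.004,
    ("CoREST", "N"): 0.004,
    ("MiDAC", "N"): 0.004,
    ("CCT", "C"): 0.004,
    ("prefoldin", "C"): 0.004,
    ("Sin3", "C"): 0.6,
    ("NuRD", "C"): 0.5,
    ("CoREST", "C"): 0.3,
    ("MiDAC", "C"): 0.2,
}

#: Paralog families whose members share peptides (sequence paralogs only).
DEFAULT_FAMILIES: tuple[tuple[str, ...], ...] = (
    ("HDAC1", "HDAC2"),
    ("RBBP4", "RBBP7"),
    ("MTA1", "MTA2", "MTA3"),
    ("CHD3", "CHD4"),
    ("GATAD2A", "GATAD2B"),
    ("RCOR1", "RCOR3"),
)


@dataclass
class SimulationConfig:
    """Tunable parameters of a synthetic AP-MS experiment.

    Abundances are relative molar units with the bait construct at
    ``bait_abundance`` (1.0 by default), so complex-capture efficiencies are
    directly the expected prey dBNSAF.  ``planted_preys`` maps a protein ID
    to its (bait-run, control-run) abundance pair and exists for calibration
    experiments (e.g. planting a known fold change over the background).
    """

    n_replicates: int = 3
    total_spectra_per_run: int = 20_000
    bait_abundance: float = 1.0
    baits: tuple[str, ...] = ("HDAC1", "HDAC2")
    conditions: tuple[str, ...] = ("N", "C")
    complex_capture: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE)
    )
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    contaminant_count: int = 100
    contaminant_abundance_median: float = 0.03
    contaminant_abundance_log_sd: float = 1.0
    paralog_shared_fraction: float = 0.3
    paralog_families: tuple[tuple[str, ...], ...] = DEFAULT_FAMILIES
    planted_preys: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    complexes: pd.DataFrame | None = None
    tag_protein: str = "HaloTag"
    tag_abundance: float = 1.0
    cell_context: str = "HeLa"
    seed: int = 0

    def resolved_complexes(self) -> pd.DataFrame:
        return self.complexes if self.complexes is not None else load_builtin_complexes()

    def validate(self) -> None:
        if self.total_spectra_per_run <= 0:
            raise ConfigurationError("total_spectra_per_run must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.bait_abundance < 0 or self.tag_abundance <= 0:
            raise ConfigurationError("abundances must be non-negative (tag > 0)")
        if not (0 <= self.paralog_shared_fraction <= 1):
            raise ConfigurationError("paralog_shared_fraction must lie in [0, 1]")
        cx = self.resolved_complexes()
        if cx.empty:
            raise ConfigurationError("complex definitions must be non-empty")
        for key, eff in self.complex_capture.items():
            if not (0 <= eff <= 1):
                raise ConfigurationError(f"capture efficiency {key} = {eff} outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted abundances and the expected dBNSAF they imply.

    ``true_abundance``: long frame (run_id, protein_id, abundance).
    ``true_dbnsaf``: long frame (bait_id, condition, protein_id, true_dbnsaf),
    with the bait's own value equal to 1 by construction.
    """

    true_abundance: pd.DataFrame
    true_dbnsaf: pd.DataFrame


@dataclass
class SimulationResult:
    evidence: dict[str, pd.DataFrame]
    sample_sheet: pd.DataFrame
    protein_db: ProteinDB
    truth: GroundTruth
    peptide_map: dict[str, tuple[str, ...]]


def construct_run_id(bait: str, condition: str, replicate: int) -> str:
    if condition == "N":
        return f"Halo-{bait}_rep{replicate}"
    if condition == "C":
        return f"{bait}-Halo_rep{replicate}"
    return f"control_rep{replicate}"


def _build_protein_db(config: SimulationConfig, rng: np.random.Generator) -> ProteinDB:
    cx = config.resolved_complexes()
    ids: list[str] = []
    for b in config.baits:
        ids.append(b)
    ids.append(config.tag_protein)
    for s in cx["subunit"]:
        if s not in ids:
            ids.append(s)
    for i in range(config.contaminant_count):
        ids.append(f"CONT{i + 1:04d}")
    for pid in config.planted_preys:
        if pid not in ids:
            ids.append(pid)
    seqs: dict[str, str] = {}
    for pid in ids:
        length = KNOWN_LENGTHS.get(pid, int(rng.integers(300, 1201)))
        seqs[pid] = "".join(rng.choice(AMINO_ACIDS, size=length))
    return ProteinDB(seqs)


def _build_peptides(
    config: SimulationConfig, db: ProteinDB
) -> tuple[dict[str, list[str]], dict[str, tuple[str, ...]]]:
    """Nominal peptide inventory.

    Returns (protein → its peptide slots, peptide → full mapping set).
    Each family member shares round(fraction × its own peptide count)
    peptides, drawn as a nested prefix of a family pool: pool peptide i is
    carried by every member sharing at least i+1 peptides.  (A pool peptide
    carried by a single member is effectively unique to it.)  This keeps
    every member's unique-peptide fraction at ≈ 1 − fraction, so the
    unique-evidence weights of distributed counting are proportional to each
    member's true contribution to the shared counts.
    """
    n_pep = {pid: math.ceil(db.length(pid) / 30) for pid in db.ids}
    protein_peps: dict[str, list[str]] = {}
    pep_map: dict[str, tuple[str, ...]] = {}
    family_of: dict[str, int] = {}
    families = [
        tuple(m for m in fam if m in db) for fam in config.paralog_families
    ]
    families = [f for f in families if len(f) >= 2]
    for fi, fam in enumerate(families):
        for m in fam:
            family_of[m] = fi
    n_shared = {
        pid: round(config.paralog_shared_fraction * n_pep[pid])
        for pid in family_of
    }
    shared_slots: dict[int, list[str]] = {}
    for fi, fam in enumerate(families):
        pool = [f"fam{fi}_p{i:03d}" for i in range(max(n_shared[m] for m in fam))]
        shared_slots[fi] = pool
        for i, pep in enumerate(pool):
            pep_map[pep] = tuple(sorted(m for m in fam if n_shared[m] > i))
    for pid in db.ids:
        if pid in family_of:
            shared = shared_slots[family_of[pid]][: n_shared[pid]]
        else:
            shared = []
        unique = [f"{pid}_p{i:03d}" for i in range(n_pep[pid] - len(shared))]
        for pep in unique:
            pep_map[pep] = (pid,)
        protein_peps[pid] = shared + unique
    return protein_peps, pep_map


def _run_abundances(
    config: SimulationConfig,
    bait: str | None,
    condition: str,
    contaminant_abundance: Mapping[str, float],
) -> dict[str, float]:
    """Expected relative molar abundance of each protein in one run."""
    a: dict[str, float] = {}
    if condition == "control":
        a[config.tag_protein] = config.tag_abundance
        for pid, (_, ctrl_ab) in config.planted_preys.items():
            if ctrl_ab > 0:
                a[pid] = a.get(pid, 0.0) + ctrl_ab
    else:
        if config.bait_abundance > 0:
            a[bait] = config.bait_abundance
        cx = config.resolved_complexes()
        for row in cx.itertuples(index=False):
            eff = config.complex_capture.get((row.complex, condition), 0.0)
            stoich = config.stoichiometry.get(row.subunit, 1.0)
            contrib = eff * stoich * config.bait_abundance
            if contrib > 0:
                a[row.subunit] = a.get(row.subunit, 0.0) + contrib
        for pid, (bait_ab, _) in config.planted_preys.items():
            if bait_ab > 0:
                a[pid] = a.get(pid, 0.0) + bait_ab
    for cid, ab in contaminant_abundance.items():
        a[cid] = a.get(cid, 0.0) + ab
    return a


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Draw a complete synthetic experiment.

    Per run, exactly ``total_spectra_per_run`` spectra are allocated
    multinomially over present proteins with weights a_k · L_k and then over
    each protein's peptide slots.  The same seed yields byte-identical
    output.  Control runs contain the tag protein, contaminants and planted
    preys only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    db = _build_protein_db(config, rng)
    protein_peps, pep_map = _build_peptides(config, db)
    lengths = db.lengths

    contaminant_abundance = {
        f"CONT{i + 1:04d}": config.contaminant_abundance_median
        * math.exp(rng.normal(0.0, config.contaminant_abundance_log_sd))
        for i in range(config.contaminant_count)
    }

    sheet_rows = []
    for bait in config.baits:
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                sheet_rows.append(
                    (construct_run_id(bait, cond, rep), bait, cond, rep, config.cell_context)
                )
    for rep in range(1, config.n_replicates + 1):
        sheet_rows.append(
            (
                construct_run_id(config.tag_protein, "control", rep),
                config.tag_protein,
                "control",
                rep,
                config.cell_context,
            )
        )
    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["run_id", "bait_id", "condition", "replicate", "cell_context"]
    )

    evidence: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for row in sample_sheet.itertuples(index=False):
        bait = None if row.condition == "control" else row.bait_id
        abund = _run_abundances(config, bait, row.condition, contaminant_abundance)
        proteins = sorted(abund)
        weights = np.array([abund[p] * lengths[p] for p in proteins], dtype=float)
        if weights.sum() <= 0:
            raise ConfigurationError(f"run {row.run_id} has zero total abundance")
        counts = rng.multinomial(config.total_spectra_per_run, weights / weights.sum())
        pep_counts: dict[str, int] = {}
        for pid, c in zip(proteins, counts):
            if c == 0:
                continue
            slots = protein_peps[pid]
            alloc = rng.multinomial(c, np.full(len(slots), 1.0 / len(slots)))
            for pep, pc in zip(slots, alloc):
                if pc:
                    pep_counts[pep] = pep_counts.get(pep, 0) + int(pc)
        evidence[row.run_id] = evidence_frame(
            (pep, pc, pep_map[pep]) for pep, pc in sorted(pep_counts.items())
        )
        for pid in proteins:
            truth_rows.append((row.run_id, pid, abund[pid]))

    true_abundance = pd.DataFrame(
        truth_rows, columns=["run_id", "protein_id", "abundance"]
    )
    dbnsaf_rows = []
    if config.bait_abundance > 0:
        for bait in config.baits:
            for cond in config.conditions:
                abund = _run_abundances(config, bait, cond, contaminant_abundance)
                for pid, a in sorted(abund.items()):
                    dbnsaf_rows.append((bait, cond, pid, a / config.bait_abundance))
    true_dbnsaf = pd.DataFrame(
        dbnsaf_rows, columns=["bait_id", "condition", "protein_id", "true_dbnsaf"]
    )
    truth = GroundTruth(true_abundance, true_dbnsaf)
    return SimulationResult(evidence, sample_sheet, db, truth, pep_map)


def write_fixture(result: SimulationResult, directory: str | Path) -> dict[str, Path]:
    """Write a simulated experiment as plain-text fixture files.

    Emits proteins.fasta, samples.tsv, truth tables and one evidence TSV per
    run under evidence/.  Round-trips losslessly through the package readers.
    """
    if not result.evidence:
        raise ConfigurationError("cannot write fixture with no runs")
    directory = Path(directory)
    (directory / "evidence").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = directory / "proteins.fasta"
    result.protein_db.to_fasta(paths["fasta"])
    paths["sample_sheet"] = directory / "samples.tsv"
    write_sample_sheet(result.sample_sheet, paths["sample_sheet"])
    paths["truth_abundance"] = directory / "truth_abundance.tsv"
    result.truth.true_abundance.to_csv(
        paths["truth_abundance"], sep="\t", index=False, float_format="%.17g"
    )
    paths["truth_dbnsaf"] = directory / "truth_dbnsaf.tsv"
    result.truth.true_dbnsaf.to_csv(
        paths["truth_dbnsaf"], sep="\t", index=False, float_format="%.17g"
    )
    for run_id, ev in result.evidence.items():
        p = directory / "evidence" / f"{run_id}.tsv"
        write_evidence_table(ev, p)
        paths[f"evidence/{run_id}"] = p
    return paths


def read_fixture(
    directory: str | Path,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, ProteinDB]:
    """Load a fixture directory back into memory (inverse of write_fixture)."""
    directory = Path(directory)
    db = ProteinDB.from_fasta(directory / "proteins.fasta")
    sheet = read_sample_sheet(directory / "samples.tsv")
    evidence = {
        run_id: read_evidence_table(directory / "evidence" / f"{run_id}.tsv")
        for run_id in sheet["run_id"]
    }
    return evidence, sheet, db


def null_config(
    seed: int,
    n_proteins: int = 2000,
    total_spectra_per_run: int = 50_000,
    n_replicates: int = 3,
) -> SimulationConfig:
    """Contaminant-only null: bait runs and control runs share one background.

    With bait abundance 0 no bait or complex subunit is present, so any
    enrichment call on the contaminants is a false positive.
    """
    return SimulationConfig(
        n_replicates=n_replicates,
        total_spectra_per_run=total_spectra_per_run,
        bait_abundance=0.0,
        baits=("HDAC1",),
        conditions=("N",),
        contaminant_count=n_proteins,
        paralog_families=(),
        seed=seed,
    )


def spiked_config(
    seed: int,
    n_planted: int = 40,
    fold: float = 8.0,
    control_abundance: float = 0.01,
    n_background: int = 2000,
    total_spectra_per_run: int = 50_000,
) -> SimulationConfig:
    """Null background plus planted preys enriched ``fold``-fold in bait runs."""
    planted = {
        f"SPIKE{i + 1:03d}": (fold * control_abundance, control_abundance)
        for i in range(n_planted)
    }
    cfg = null_config(
        seed, n_proteins=n_background, total_spectra_per_run=total_spectra_per_run
    )
    cfg.planted_preys = planted
    return cfg
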