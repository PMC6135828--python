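"""Distributed spectral-count quantitation: dSpC, dSAF, dNSAF and dBNSAF.

Spectral counts are a label-free abundance proxy: the number of MS/MS spectra
matched to peptides of a protein in one run.  Peptides shared between
paralogous proteins cannot be attributed directly, so shared counts are
*distributed* across the sharing set in proportion to each protein's unique
evidence:

    d_{k,j} = uSpC_k / sum_{i in share(j)} uSpC_i
    dSpC_k  = uSpC_k + sum_j d_{k,j} * sSpC_j

Length normalization then yields the distributed spectral abundance factor
dSAF_k = dSpC_k / L_k, its run-normalized form dNSAF_k = dSAF_k / sum dSAF,
and the bait-normalized dBNSAF_k = dSAF_k / dSAF_bait, a per-replicate proxy
for the prey:bait molar ratio that cancels run-to-run variation in bait
expression.

Degenerate case: a shared peptide whose entire sharing set has zero unique
evidence is split equally among the set, which preserves count conservation
(sum_k dSpC_k equals the run's total spectral counts exactly).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BaitNotDetectedError,
    EmptyRunError,
    UnmappedPeptideError,
    ConfigurationError,
)
from .io import ProteinDB

QUANT_COLUMNS = ("run_id", "protein_id", "uSpC", "dSpC", "dSAF", "dNSAF", "dBNSAF")


def classify_peptides(evidence: pd.DataFrame, db: ProteinDB) -> pd.DataFrame:
    """Classify each peptide as unique (one mapped protein) or shared.

    Returns a copy of ``evidence`` with a boolean ``unique`` column.  Every
    mapped protein ID must exist in ``db``; offenders raise
    :class:`UnmappedPeptideError` listing peptide → unknown IDs.
    """
    offenders: dict[str, list[str]] = {}
    for pep, prots in zip(evidence["peptide"], evidence["proteins"]):
        if len(prots) == 0:
            offenders[pep] = []
            continue
        unknown = [p for p in prots if p not in db]
        if unknown:
            offenders[pep] = unknown
    if offenders:
        raise UnmappedPeptideError(offenders)
    out = evidence.copy()
    out["unique"] = [len(p) == 1 for p in out["proteins"]]
    return out


def distribute_shared_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Apportion shared spectral counts by unique-evidence weights.

    Vectorized over peptides.  Returns one row per protein appearing in any
    mapping set with columns ``uSpC``, ``shared_attributed`` and ``dSpC``
    (indexed by ``protein_id``).  Proteins whose peptides all drew zero
    spectra are retained with dSpC = 0.
    """
    exploded = classified.explode("proteins").rename(columns={"proteins": "protein_id"})
    uspc = (
        exploded.loc[exploded["unique"]]
        .groupby("protein_id")["spectral_count"]
        .sum()
    )
    all_proteins = pd.Index(sorted(exploded["protein_id"].unique()), name="protein_id")
    uspc = uspc.reindex(all_proteins, fill_value=0).astype(float)

    shared = classified.loc[~classified["unique"]]
    if shared.empty:
        shared_attr = pd.Series(0.0, index=all_proteins)
    else:
        ex = shared.explode("proteins").rename(columns={"proteins": "protein_id"})
        ex = ex.reset_index(names="pep_row")
        ex["u"] = uspc.reindex(ex["protein_id"]).to_numpy()
        grp = ex.groupby("pep_row")["u"]
        denom = grp.transform("sum")
        size = grp.transform("size")
        # equal split when the whole sharing set lacks unique evidence
        weight = np.where(denom > 0, ex["u"] / denom.where(denom > 0, 1.0), 1.0 / size)
        ex["attributed"] = weight * ex["spectral_count"].to_numpy()
        shared_attr = (
            ex.groupby("protein_id")["attributed"].sum().reindex(all_proteins, fill_value=0.0)
        )
    out = pd.DataFrame(
        {"uSpC": uspc, "shared_attributed": shared_attr},
        index=all_proteins,
    )
    out["dSpC"] = out["uSpC"] + out["shared_attributed"]
    return out


def distribute_shared_counts_naive(classified: pd.DataFrame) -> pd.DataFrame:
    """Reference per-peptide loop implementation of the distribution rule.

    Independent of the vectorized path; used as an oracle in the test suite.
    """
    uspc: dict[str, float] = {}
    for _, row in classified.iterrows():
        for p in row["proteins"]:
            uspc.setdefault(p, 0.0)
        if row["unique"]:
            uspc[row["proteins"][0]] += row["spectral_count"]
    shared_attr = {p: 0.0 for p in uspc}
    for _, row in classified.iterrows():
        if row["unique"]:
            continue
        members = row["proteins"]
        denom = sum(uspc[p] for p in members)
        for p in members:
            w = uspc[p] / denom if denom > 0 else 1.0 / len(members)
            shared_attr[p] += w * row["spectral_count"]
    proteins = sorted(uspc)
    return pd.DataFrame(
        {
            "uSpC": [uspc[p] for p in proteins],
            "shared_attributed": [shared_attr[p] for p in proteins],
            "dSpC": [uspc[p] + shared_attr[p] for p in proteins],
        },
        index=pd.Index(proteins, name="protein_id"),
    )


def compute_dnsaf(
    dspc: pd.Series, lengths: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Length-normalize distributed counts: dSAF = dSpC / L, dNSAF = dSAF / ΣdSAF.

    dNSAF sums to 1 over the run and is invariant to uniform rescaling of all
    dSpC.  A run with zero total counts raises :class:`EmptyRunError`.
    """
    total = float(dspc.sum())
    if total <= 0:
        raise EmptyRunError("run has zero total spectral counts")
    lengths = pd.Series(dict(lengths)) if not isinstance(lengths, pd.Series) else lengths
    missing = [p for p in dspc.index if p not in lengths.index]
    if missing:
        raise ConfigurationError(f"no length for proteins: {missing}")
    dsaf = dspc / lengths.reindex(dspc.index).astype(float)
    dnsaf = dsaf / dsaf.sum()
    return pd.DataFrame({"dSAF": dsaf, "dNSAF": dnsaf})


def compute_dbnsaf(values: pd.Series, bait_id: str, run_id: str | None = None) -> pd.Series:
    """Normalize per-protein abundance factors to the bait's value.

    ``values`` may be dSAF or dNSAF — the run-level normalizer cancels in the
    ratio, so both give identical dBNSAF.  The bait must be detected with a
    positive value.
    """
    if bait_id not in values.index or not values[bait_id] > 0:
        raise BaitNotDetectedError(bait_id, run_id)
    out = values / values[bait_id]
    out.name = "dBNSAF"
    return out


def quantify_run(
    evidence: pd.DataFrame,
    db: ProteinDB,
    bait_id: str | None = None,
    run_id: str = "",
) -> pd.DataFrame:
    """Full per-run quantitation: classify, distribute, normalize.

    Returns a DataFrame indexed by protein_id with uSpC, shared_attributed,
    dSpC, dSAF, dNSAF and (if ``bait_id`` given) dBNSAF.
    """
    classified = classify_peptides(evidence, db)
    counts = distribute_shared_counts(classified)
    norm = compute_dnsaf(counts["dSpC"], db.lengths)
    out = counts.join(norm)
    if bait_id is not None:
        out["dBNSAF"] = compute_dbnsaf(out["dSAF"], bait_id, run_id=run_id)
    else:
        out["dBNSAF"] = np.nan
    return out


def quantify_experiment(
    evidence_by_run: Mapping[str, pd.DataFrame],
    db: ProteinDB,
    sample_sheet: pd.DataFrame,
    bait_normalize: bool = True,
) -> pd.DataFrame:
    """Quantify every run of an experiment into one long QuantMatrix.

    The bait used for dBNSAF normalization is the sample sheet's ``bait_id``
    for that run (for control runs this is the affinity-tag protein itself).
    With ``bait_normalize=False`` the dBNSAF column is left NaN — useful for
    count-only analyses where no bait is expected in the runs.
    Returns a long DataFrame with columns
    run_id, protein_id, uSpC, dSpC, dSAF, dNSAF, dBNSAF.
    """
    frames = []
    for row in sample_sheet.itertuples(index=False):
        ev = evidence_by_run[row.run_id]
        bait = row.bait_id if bait_normalize else None
        q = quantify_run(ev, db, bait_id=bait, run_id=row.run_id)
        q = q.reset_index()
        q.insert(0, "run_id", row.run_id)
        frames.append(q)
    long = pd.concat(frames, ignore_index=True)
    return long[[*QUANT_COLUMNS[:2], "uSpC", "shared_attributed", "dSpC", "dSAF", "dNSAF", "dBNSAF"]]


def aggregate_replicates(run_quants: Sequence[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run dBNSAF across the replicates of one bait group.

    Accepts either a list of per-run quant frames (indexed by protein) or a
    long frame with run_id/protein_id columns.  Non-detections (protein absent
    from a run) enter the mean as dBNSAF = 0, so means stay comparable across
    baits.  SD is the sample standard deviation (n−1 denominator; 0 when only
    one replicate).  detection_fraction = runs with dSpC > 0 / total runs.
    """
    if isinstance(run_quants, pd.DataFrame):
        runs = [g.set_index("protein_id") for _, g in run_quants.groupby("run_id")]
    else:
        runs = list(run_quants)
    if not runs:
        raise ConfigurationError("aggregate_replicates requires at least one replicate")
    n = len(runs)
    proteins = sorted(set().union(*[set(r.index) for r in runs]))
    idx = pd.Index(proteins, name="protein_id")
    vals = np.zeros((n, len(proteins)))
    detected = np.zeros((n, len(proteins)), dtype=bool)
    for i, r in enumerate(runs):
        vals[i] = r["dBNSAF"].reindex(idx, fill_value=0.0).fillna(0.0).to_numpy()
        detected[i] = (r["dSpC"].reindex(idx, fill_value=0.0) > 0).to_numpy()
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if n > 1 else np.zeros(len(proteins))
    return pd.DataFrame(
        {
            "mean_dbnsaf": mean,
            "sd_dbnsaf": sd,
            "detection_fraction": detected.sum(axis=0) / n,
            "n_replicates": n,
        },
        index=idx,
    )


def aggregate_experiment(
    quant_long: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate a long QuantMatrix per (bait_id, condition) group.

    Returns a long frame with columns bait_id, condition, protein_id,
    mean_dbnsaf, sd_dbnsaf, detection_fraction, n_replicates.
    """
    merged = quant_long.merge(
        sample_sheet[["run_id", "bait_id", "condition"]], on="run_id"
    )
    frames = []
    for (bait, cond), grp in merged.groupby(["bait_id", "condition"], sort=True):
        agg = aggregate_replicates(grp).reset_index()
        agg.insert(0, "condition", cond)
        agg.insert(0, "bait_id", bait)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def run_total(quant: pd.DataFrame) -> float:
    """Total spectral counts of a run, recovered from its dSpC column."""
    total = float(quant["dSpC"].sum())
    return total if not math.isnan(total) else 0.0
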