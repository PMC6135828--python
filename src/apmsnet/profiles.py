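"""Complex-level summaries and hierarchical clustering of abundance profiles.

Mean dBNSAF values are scaled by 1000 for presentation and clustering (the
working range of prey:bait ratios puts most values well below 1).  Profiles
are clustered on the scaled values with Euclidean dissimilarity and complete
linkage; a log2(value + 1) transform is applied only to the exported display
matrix, never to the clustering input.

A curated table of HDAC1/2-relevant complexes (CCT, prefoldin, Sin3, NuRD,
CoREST, MiDAC) ships with the package.  It is hand-curated annotation, not a
computed artifact, and is meant to be edited for other interactomes.
"""

from __future__ import annotations

from collections.abc import Iterable
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, DefinitionError

DEFAULT_SCALE = 1000.0
DEFAULT_DISPLAY_EPSILON = 1.0


def load_builtin_complexes() -> pd.DataFrame:
    """Curated complex → subunit table shipped with the package."""
    with resources.files("apmsnet.data").joinpath("complexes.tsv").open() as fh:
        return read_complex_definitions(fh)


def read_complex_definitions(path_or_buffer) -> pd.DataFrame:
    """Read a complex-definition TSV (columns: complex, subunit).

    A subunit may belong to several complexes (e.g. RBBP4/7 in both Sin3 and
    NuRD).  Duplicate (complex, subunit) rows and empty complexes raise.
    """
    defs = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    if not {"complex", "subunit"}.issubset(defs.columns):
        raise DefinitionError("definition table needs columns: complex, subunit")
    defs = defs[["complex", "subunit"]].dropna()
    if defs.empty:
        raise DefinitionError("empty complex-definition table")
    if defs.duplicated().any():
        dupes = defs[defs.duplicated()].to_records(index=False).tolist()
        raise DefinitionError(f"duplicate definition rows: {dupes}")
    return defs.reset_index(drop=True)


def assign_complex_membership(
    protein_ids: Iterable[str], definitions: pd.DataFrame
) -> pd.DataFrame:
    """Membership table: one row per (protein, complex); unannotated marked.

    Proteins in several complexes get one row per complex; proteins in none
    get a single row with complex = "unannotated".
    """
    if definitions.empty:
        raise DefinitionError("empty complex-definition table")
    by_subunit = definitions.groupby("subunit")["complex"].apply(list)
    rows = []
    for pid in protein_ids:
        for cx in by_subunit.get(pid, ["unannotated"]):
            rows.append((pid, cx))
    return pd.DataFrame(rows, columns=["protein_id", "complex"])


def _construct_label(bait_id: str, condition: str) -> str:
    """Human-readable construct name: N tag → Halo-X, C tag → X-Halo."""
    if condition == "N":
        return f"Halo-{bait_id}"
    if condition == "C":
        return f"{bait_id}-Halo"
    return bait_id


def profile_matrix(
    aggregates: pd.DataFrame, scale: float = DEFAULT_SCALE
) -> pd.DataFrame:
    """Proteins × bait-construct matrix of scaled mean dBNSAF.

    Columns are labelled by construct (Halo-HDAC1, HDAC1-Halo, ...); control
    groups are excluded.  Values are ``scale × mean_dbnsaf`` (default 1000×).
    """
    if scale <= 0:
        raise ConfigurationError("scale factor must be positive")
    sub = aggregates[aggregates["condition"] != "control"].copy()
    sub["construct"] = [
        _construct_label(b, c) for b, c in zip(sub["bait_id"], sub["condition"])
    ]
    mat = sub.pivot_table(
        index="protein_id", columns="construct", values="mean_dbnsaf", fill_value=0.0
    )
    return mat * scale


def complex_summary_table(
    aggregates: pd.DataFrame,
    definitions: pd.DataFrame,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Ribbon table: one row per (complex, subunit, bait construct).

    Values and SDs are scaled mean dBNSAF (default 1000×); subunits shared
    between complexes appear once per complex; undetected subunits get 0.
    The layout doubles as a Circos-style link table (complex ↔ bait with the
    scaled value as ribbon width).
    """
    sub = aggregates[aggregates["condition"] != "control"].copy()
    sub["construct"] = [
        _construct_label(b, c) for b, c in zip(sub["bait_id"], sub["condition"])
    ]
    constructs = sorted(sub["construct"].unique())
    means = sub.pivot_table(
        index="protein_id", columns="construct", values="mean_dbnsaf", fill_value=0.0
    )
    sds = sub.pivot_table(
        index="protein_id", columns="construct", values="sd_dbnsaf", fill_value=0.0
    )
    rows = []
    for cx, grp in definitions.groupby("complex", sort=True):
        for subunit in sorted(grp["subunit"]):
            for construct in constructs:
                mean = means.at[subunit, construct] if subunit in means.index else 0.0
                sd = sds.at[subunit, construct] if subunit in sds.index else 0.0
                rows.append((cx, subunit, construct, scale * mean, scale * sd))
    return pd.DataFrame(
        rows, columns=["complex", "subunit", "bait", "value", "sd"]
    )


def cluster_profiles(
    matrix: pd.DataFrame,
    display_epsilon: float = DEFAULT_DISPLAY_EPSILON,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Hierarchically cluster profile rows.

    Runs complete-linkage agglomeration on the Euclidean distances of the
    (already scaled) matrix rows.  Returns the scipy linkage matrix, the
    dendrogram leaf order (row labels) and the display matrix
    ``log2(value + display_epsilon)`` — the display transform is applied
    after clustering, never before.

    To cluster bait profiles instead of proteins, pass ``matrix.T``.
    """
    if matrix.shape[0] < 2:
        raise ConfigurationError("clustering needs at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ConfigurationError("profile matrix contains NaN values")
    z = linkage(pdist(values, metric="euclidean"), method="complete")
    order = [matrix.index[i] for i in leaves_list(z)]
    display = np.log2(matrix + display_epsilon)
    return z, order, display


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        parts = [
            f"{walk(left)}:{max(node.dist - left.dist, 0.0):.10g}",
            f"{walk(right)}:{max(node.dist - right.dist, 0.0):.10g}",
        ]
        return f"({','.join(parts)})"

    return walk(tree) + ";"


def top_level_groups(z: np.ndarray, labels: list[str]) -> tuple[set[str], set[str]]:
    """The two leaf-label sets below the dendrogram root."""
    tree = to_tree(z)
    left = {labels[i] for i in tree.get_left().pre_order()}
    right = {labels[i] for i in tree.get_right().pre_order()}
    return left, right


def write_profile_outputs(
    matrix: pd.DataFrame,
    out_dir: str | Path,
    definitions: pd.DataFrame | None = None,
    aggregates: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write ribbon table, Newick dendrogram and display matrix to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if definitions is not None and aggregates is not None:
        ribbon = complex_summary_table(aggregates, definitions)
        paths["ribbon_table"] = out_dir / "ribbon_table.tsv"
        ribbon.to_csv(paths["ribbon_table"], sep="\t", index=False, float_format="%.17g")
    z, order, display = cluster_profiles(matrix)
    paths["dendrogram"] = out_dir / "dendrogram.nwk"
    paths["dendrogram"].write_text(linkage_to_newick(z, list(matrix.index)) + "\n")
    paths["display_matrix"] = out_dir / "display_matrix.tsv"
    display.loc[order].to_csv(paths["display_matrix"], sep="\t", float_format="%.17g")
    return paths
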