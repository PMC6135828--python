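"""Differential interaction network between N-terminal and C-terminal tagging.

Per condition (N or C), a consensus network is built over preys significant
for at least one of the condition's baits; the prey's weight is the mean of
the per-bait mean dBNSAF over the condition's baits.  The differential
network then keeps every prey whose weight changes by at least ``min_change``
(default 0.2 dBNSAF units, inclusive) between the two conditions, with the
direction of change and an edge width proportional to |Δ|.  Node pie-chart
attributes give each prey's relative distribution of dBNSAF across the four
bait constructs.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

DIRECTION_C = "C-enriched"
DIRECTION_N = "N-enriched"

#: How per-bait means are combined into one condition-level weight.
CONSENSUS_MODES = ("mean", "min", "max")


@dataclass
class ConditionNetwork:
    """Consensus prey weights for one tagging condition."""

    condition: str
    weights: pd.Series  # prey → consensus weight (dBNSAF units)
    per_bait: pd.DataFrame  # preys × baits, per-bait mean dBNSAF
    significant_for: dict[str, set[str]] = field(default_factory=dict)


def build_condition_network(
    aggregates: pd.DataFrame,
    significant: Mapping[tuple[str, str], set[str]],
    condition: str,
    consensus: str = "mean",
) -> ConditionNetwork:
    """Build one condition's consensus network.

    ``aggregates`` is the long per-(bait_id, condition) aggregate table with
    mean_dbnsaf; ``significant`` maps (bait_id, condition) → significant prey
    set.  A prey enters iff significant for ≥ 1 bait of the condition; its
    weight combines the per-bait means of *all* the condition's baits
    (non-significant baits contribute their measured value, absent → 0).
    """
    if consensus not in CONSENSUS_MODES:
        raise ConfigurationError(f"unknown consensus mode {consensus!r}")
    sub = aggregates[aggregates["condition"] == condition]
    baits = sorted(sub["bait_id"].unique())
    if not baits:
        raise ConfigurationError(f"condition {condition!r} has no baits")
    per_bait = sub.pivot_table(
        index="protein_id", columns="bait_id", values="mean_dbnsaf", fill_value=0.0
    ).reindex(columns=baits, fill_value=0.0)
    members: set[str] = set()
    sig_for: dict[str, set[str]] = {}
    for bait in baits:
        s = set(significant.get((bait, condition), set()))
        sig_for[bait] = s
        members |= s
    per_bait = per_bait.reindex(sorted(members), fill_value=0.0)
    if consensus == "mean":
        w = per_bait.mean(axis=1)
    elif consensus == "min":
        w = per_bait.min(axis=1)
    else:
        w = per_bait.max(axis=1)
    w.name = "weight"
    return ConditionNetwork(condition, w, per_bait, sig_for)


def build_differential_network(
    net_n: ConditionNetwork,
    net_c: ConditionNetwork,
    min_change: float = 0.2,
) -> pd.DataFrame:
    """Differential edges between the N- and C-condition networks.

    A prey absent from one condition contributes weight 0.  An edge is
    emitted iff |w_C − w_N| ≥ min_change (inclusive boundary), with
    delta = w_C − w_N, a direction label matching sign(delta), and
    width_value = |delta|.
    """
    if min_change < 0:
        raise ConfigurationError("min_change must be non-negative")
    preys = net_n.weights.index.union(net_c.weights.index)
    wn = net_n.weights.reindex(preys, fill_value=0.0)
    wc = net_c.weights.reindex(preys, fill_value=0.0)
    delta = wc - wn
    keep = delta.abs() >= min_change
    out = pd.DataFrame(
        {
            "prey_id": preys[keep],
            "w_N": wn[keep].to_numpy(),
            "w_C": wc[keep].to_numpy(),
            "delta": delta[keep].to_numpy(),
        }
    )
    out["direction"] = np.where(out["delta"] > 0, DIRECTION_C, DIRECTION_N)
    out["width_value"] = out["delta"].abs()
    return out.sort_values("prey_id", ignore_index=True)


def node_share_attributes(
    per_bait_means: pd.DataFrame, bait_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Relative distribution of dBNSAF across bait constructs, per prey.

    ``per_bait_means``: preys × bait-construct mean dBNSAF (≥ 0).  Shares are
    values / row sum; an all-zero prey keeps all-zero shares and is flagged
    ``undetected``.
    """
    if (per_bait_means.to_numpy() < 0).any():
        raise ConfigurationError("dBNSAF values must be non-negative")
    mat = per_bait_means if bait_order is None else per_bait_means.reindex(
        columns=list(bait_order), fill_value=0.0
    )
    totals = mat.sum(axis=1)
    shares = mat.div(totals.where(totals > 0, 1.0), axis=0)
    shares = shares.add_prefix("share_")
    shares["undetected"] = totals <= 0
    shares.index.name = "prey_id"
    return shares


def to_graph(edges: pd.DataFrame, node_shares: pd.DataFrame | None = None) -> nx.Graph:
    """Differential network as a networkx graph (hub node ↔ preys)."""
    g = nx.Graph()
    hub = "HDAC_baits"
    g.add_node(hub, role="bait_hub")
    for row in edges.itertuples(index=False):
        attrs = {"role": "prey"}
        if node_shares is not None and row.prey_id in node_shares.index:
            for col, val in node_shares.loc[row.prey_id].items():
                attrs[str(col)] = bool(val) if col == "undetected" else float(val)
        g.add_node(row.prey_id, **attrs)
        g.add_edge(
            hub,
            row.prey_id,
            delta=float(row.delta),
            direction=row.direction,
            width_value=float(row.width_value),
        )
    return g


def export_network(
    edges: pd.DataFrame,
    path: str | Path,
    fmt: str,
    node_shares: pd.DataFrame | None = None,
) -> Path:
    """Write the differential network as GraphML, SIF or JSON.

    SIF rows are ``hub <direction> prey`` (one row per edge); GraphML keeps
    full numeric attributes and round-trips through a standard reader.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(to_graph(edges, node_shares), path)
    elif fmt == "sif":
        lines = [
            f"HDAC_baits\t{row.direction}\t{row.prey_id}"
            for row in edges.itertuples(index=False)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "json":
        doc = {
            "nodes": (
                node_shares.reset_index().to_dict(orient="records")
                if node_shares is not None
                else [{"prey_id": p} for p in edges["prey_id"]]
            ),
            "edges": edges.to_dict(orient="records"),
        }
        path.write_text(json.dumps(doc, indent=2, default=float) + "\n")
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")
    return path
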