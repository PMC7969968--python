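"""Mapping differential genes onto the regulatory network.

A differential gene is attributed to every regulator that could directly
account for its change. The default *strict* sign rule composes the usual
reading of regulatory logic with the restriction to regulatory (as opposed
to deregulatory) events: sigma factors and activator TF edges can only
explain increased expression, repressor TF edges only decreased expression,
and dual edges either. Derepression — a gene rising because its repressor
lost activity — is deliberately not modeled. The *permissive* rule lets any
edge explain any direction and exists for sensitivity analysis; every
strict-rule record is also a permissive-rule record.

A gene reached by k qualifying regulators yields k records (it is counted
once per regulator); multiple qualifying edges from the same regulator to
the same gene collapse to one record per direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .diffexpr import DEGSet
from .errors import UsageError
from .formats import NetworkGraph, RegulatoryNetwork

logger = logging.getLogger(__name__)

SIGN_RULES = ("strict", "permissive")


class MappedChange(NamedTuple):
    """One regulator -> gene attribution of an expression change."""

    regulator: str
    reg_class: str
    gene: str
    direction: str  # up | down, from the DEG set
    mode: str  # edge mode in the network


def _edge_qualifies(reg_class: str, mode: str, direction: str, sign_rule: str) -> bool:
    if sign_rule == "permissive":
        return True
    if reg_class == "sigma":
        # sigma edges explain increased expression only
        return direction == "up"
    if mode == "activator":
        return direction == "up"
    if mode == "repressor":
        return direction == "down"
    # dual and unknown map either direction
    return True


def map_degs(
    degs: DEGSet, network: RegulatoryNetwork, sign_rule: str = "strict"
) -> list[MappedChange]:
    """Attribute each differential gene to its sign-consistent regulators.

    Genes absent from the network are reported via the logger, never an
    error — the network cannot explain them but that is a finding, not a
    failure.
    """
    if sign_rule not in SIGN_RULES:
        raise UsageError(f"unknown sign rule {sign_rule!r}; use strict|permissive")
    if network.edges.empty:
        raise UsageError("cannot map onto an empty network")
    n_unknown = int((network.edges["mode"] == "unknown").sum())
    if n_unknown and sign_rule == "strict":
        logger.warning(
            "%d unknown-mode edge(s) treated as dual (map either direction)",
            n_unknown,
        )
    direction_of = {g: "up" for g in degs.up}
    direction_of.update({g: "down" for g in degs.down})
    unmatched = set(direction_of) - network.genes
    if unmatched:
        logger.info(
            "%d differential gene(s) have no regulator in the network", len(unmatched)
        )
    records: set[MappedChange] = set()
    sub = network.edges[network.edges["target"].isin(direction_of)]
    for row in sub.itertuples(index=False):
        direction = direction_of[row.target]
        if _edge_qualifies(row.reg_class, row.mode, direction, sign_rule):
            records.add(
                MappedChange(row.regulator, row.reg_class, row.target, direction, row.mode)
            )
    # one record per (regulator, gene, direction): drop mode multiplicity,
    # preferring a sign-consistent edge's mode so permissive-rule output is
    # a superset of strict-rule output record-for-record
    def preference(rec: MappedChange) -> tuple:
        strict_ok = _edge_qualifies(rec.reg_class, rec.mode, rec.direction, "strict")
        return (not strict_ok, rec.mode)

    dedup: dict[tuple[str, str, str], MappedChange] = {}
    for rec in sorted(records, key=lambda r: (r.regulator, r.gene, r.direction, *preference(r))):
        dedup.setdefault((rec.regulator, rec.gene, rec.direction), rec)
    return list(dedup.values())


@dataclass
class RegulatorActivity:
    """Per-regulator mapped-gene tallies for one contrast.

    ``table`` is indexed by regulator with columns ``reg_class``,
    ``up_count``, ``down_count``, ``mapped_count`` (distinct genes either
    direction) and ``regulon_size`` (distinct targets in the network);
    every network regulator appears, with zeros when nothing mapped.
    ``mapped_genes`` holds the underlying gene sets.
    """

    contrast: str
    table: pd.DataFrame
    mapped_genes: dict[str, frozenset[str]]


def activity_counts(
    mapped: Iterable[MappedChange], network: RegulatoryNetwork, contrast: str
) -> RegulatorActivity:
    """Tally mapped records per regulator (a gene counts once per regulator)."""
    sizes = network.regulon_sizes()
    classes = {
        r: network.edges.loc[network.edges["regulator"] == r, "reg_class"].iloc[0]
        for r in network.regulators
    }
    up: dict[str, set[str]] = {r: set() for r in sizes}
    down: dict[str, set[str]] = {r: set() for r in sizes}
    for rec in mapped:
        if rec.regulator not in sizes:
            raise UsageError(f"mapped record references unknown regulator {rec.regulator!r}")
        (up if rec.direction == "up" else down)[rec.regulator].add(rec.gene)
    regulators = network.regulators
    table = pd.DataFrame(
        {
            "reg_class": [classes[r] for r in regulators],
            "up_count": [len(up[r]) for r in regulators],
            "down_count": [len(down[r]) for r in regulators],
            "mapped_count": [len(up[r] | down[r]) for r in regulators],
            "regulon_size": [sizes[r] for r in regulators],
        },
        index=pd.Index(regulators, name="regulator"),
    )
    mapped_genes = {r: frozenset(up[r] | down[r]) for r in regulators}
    return RegulatorActivity(contrast, table, mapped_genes)


def build_graph(mapped: Iterable[MappedChange]) -> NetworkGraph:
    """Assemble the regulator -> gene change graph (Cytoscape-ready).

    One node per distinct regulator and gene, one directed edge per mapped
    record with an up/down ``direction`` attribute; exact repeats collapse.
    If the same (regulator, gene) pair carries both directions, the edge
    keeps the lexicographically earlier record's direction and a warning is
    logged (SIF/GraphML edges are unique per node pair).
    """
    g = nx.DiGraph()
    for rec in sorted(set(mapped)):
        g.add_node(rec.regulator, kind="regulator")
        g.add_node(rec.gene, kind="gene")
        if g.has_edge(rec.regulator, rec.gene):
            if g[rec.regulator][rec.gene]["direction"] != rec.direction:
                logger.warning(
                    "conflicting directions for edge %s -> %s; keeping the first",
                    rec.regulator,
                    rec.gene,
                )
            continue
        g.add_edge(rec.regulator, rec.gene, direction=rec.direction)
    return NetworkGraph(g)


def write_mapped(mapped: Iterable[MappedChange], path) -> None:
    pd.DataFrame(mapped, columns=MappedChange._fields).to_csv(path, sep="\t", index=False)


def write_activity(activity: RegulatorActivity, path) -> None:
    activity.table.to_csv(path, sep="\t")
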