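"""Core containers and file I/O.

All tables travel as TSV, graphs as SIF or GraphML, and the in-memory
containers are thin, validated wrappers around :class:`pandas.DataFrame`
(tables) and :class:`networkx.DiGraph` (graphs). Every writer/reader pair
round-trips exactly: reading a file a writer produced reconstructs the
original object.

Gene identifiers are opaque strings; matching between count, network and
COG files is exact, case-sensitive string equality. No synonym resolution
is attempted — :func:`unmatched_ids` reports disagreements instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, UsageError

logger = logging.getLogger(__name__)

REGULATOR_CLASSES = ("sigma", "TF")
EDGE_MODES = ("activator", "repressor", "dual", "unknown")

#: EcoCyc-style mode symbols accepted on input and normalized to the
#: canonical vocabulary.
MODE_SYNONYMS = {
    "+": "activator",
    "-": "repressor",
    "−": "repressor",  # unicode minus
    "+/-": "dual",
    "+/−": "dual",
    "": "unknown",
    "activator": "activator",
    "repressor": "repressor",
    "dual": "dual",
    "unknown": "unknown",
}

#: The 26 one-letter COG functional categories.
COG_LEGEND = {
    "J": "Translation, ribosomal structure and biogenesis",
    "A": "RNA processing and modification",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "B": "Chromatin structure and dynamics",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "Y": "Nuclear structure",
    "V": "Defense mechanisms",
    "T": "Signal transduction mechanisms",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "Z": "Cytoskeleton",
    "W": "Extracellular structures",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "C": "Energy production and conversion",
    "G": "Carbohydrate transport and metabolism",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
    "X": "Mobilome: prophages, transposons",
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a sample -> condition design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    design
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``; its index must equal the count columns as a set.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = set(self.counts.columns) - set(self.design.index)
        extra = set(self.design.index) - set(self.counts.columns)
        if missing or extra:
            raise FormatError(
                f"design/sample mismatch: samples without design {sorted(missing)}, "
                f"design rows without sample {sorted(extra)}"
            )
        vals = self.counts.to_numpy()
        if not ((vals == vals.astype(int)) & (vals >= 0)).all():
            bad = (vals != vals.astype(int)) | (vals < 0)
            g, s = [x[0] for x in bad.nonzero()]
            raise FormatError(
                f"non-integer or negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(int)
        # align design row order to sample column order
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        if len(sel) == 0:
            raise UsageError(f"unknown condition label {condition!r}")
        return list(sel)


@dataclass
class RegulatoryNetwork:
    """Directed regulator -> gene edge list typed by class and mode.

    ``edges`` has columns ``regulator``, ``reg_class`` (sigma|TF),
    ``target`` and ``mode`` (activator|repressor|dual|unknown). A regulator
    carries exactly one class across all of its edges and exact duplicate
    rows are forbidden (readers collapse them with a warning before
    constructing the object).
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["regulator", "reg_class", "target", "mode"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise FormatError(f"network table missing column(s) {missing}")
        self.edges = self.edges[required].reset_index(drop=True)
        bad_class = set(self.edges["reg_class"]) - set(REGULATOR_CLASSES)
        if bad_class:
            raise FormatError(f"unknown regulator class(es) {sorted(bad_class)}")
        bad_mode = set(self.edges["mode"]) - set(EDGE_MODES)
        if bad_mode:
            raise FormatError(f"unknown edge mode(s) {sorted(bad_mode)}")
        nclass = self.edges.groupby("regulator")["reg_class"].nunique()
        conflicted = nclass[nclass > 1]
        if len(conflicted):
            raise FormatError(
                f"regulator(s) listed with more than one class: {list(conflicted.index)}"
            )
        if self.edges.duplicated().any():
            row = self.edges[self.edges.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate edge {row['regulator']!r} -> {row['target']!r}"
            )

    @property
    def regulators(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.edges["regulator"]:
            seen.setdefault(r, None)
        return list(seen)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["target"])

    def regulator_class(self, regulator: str) -> str:
        sel = self.edges.loc[self.edges["regulator"] == regulator, "reg_class"]
        if sel.empty:
            raise UsageError(f"unknown regulator {regulator!r}")
        return sel.iloc[0]

    def regulon(self, regulator: str) -> set[str]:
        """Distinct targets of one regulator."""
        return set(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    def regulon_sizes(self) -> dict[str, int]:
        return self.edges.groupby("regulator")["target"].nunique().to_dict()


@dataclass
class COGAnnotation:
    """gene id -> set of one-letter functional category codes.

    Empty sets are allowed (unannotated genes). Codes must appear in the
    legend, which defaults to the 26-code COG alphabet.
    """

    mapping: dict[str, frozenset[str]]
    legend: Mapping[str, str] = field(default_factory=lambda: dict(COG_LEGEND))

    def __post_init__(self) -> None:
        self.mapping = {g: frozenset(cats) for g, cats in self.mapping.items()}
        unknown = set().union(*self.mapping.values(), frozenset()) - set(self.legend)
        if unknown:
            raise FormatError(f"category code(s) not in legend: {sorted(unknown)}")

    def categories(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def genome_counts(self) -> dict[str, int]:
        """Background: number of annotated genes carrying each category."""
        out = {code: 0 for code in self.legend}
        for cats in self.mapping.values():
            for c in cats:
                out[c] += 1
        return out


@dataclass
class NetworkGraph:
    """Bipartite change graph: regulator nodes -> gene nodes, edges signed up/down."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if self.graph.nodes[u].get("kind") != "regulator":
                raise FormatError(f"edge source {u!r} is not a regulator node")
            if self.graph.nodes[v].get("kind") != "gene":
                raise FormatError(f"edge target {v!r} is not a gene node")
            if data.get("direction") not in ("up", "down"):
                raise FormatError(f"edge {u!r}->{v!r} lacks an up/down direction")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and {(u, v): d for u, v, d in self.graph.edges(data=True)}
            == {(u, v): d for u, v, d in other.graph.edges(data=True)}
        )


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------


def read_counts(counts_path, design_path) -> CountMatrix:
    """Read a gene x sample counts TSV plus its companion design TSV.

    The counts file has gene ids in the first column and one column per
    sample; the design file has columns ``sample``, ``condition``,
    ``replicate``. Malformed cells raise :class:`FormatError` naming the
    offending gene and sample — nothing is silently coerced.
    """
    raw = pd.read_csv(counts_path, sep="\t", dtype=str, comment="#")
    if raw.columns[0] != "gene_id":
        raise FormatError(
            f"first counts column must be 'gene_id', found {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round()) | (converted < 0)
        if bad.any():
            gene = raw.index[bad][0]
            raise FormatError(
                f"non-integer or negative count {raw.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    design = pd.read_csv(design_path, sep="\t", dtype=str, comment="#")
    for col in ("sample", "condition", "replicate"):
        if col not in design.columns:
            raise FormatError(f"design table missing column {col!r}")
    if design["sample"].duplicated().any():
        raise FormatError("duplicate sample row in design table")
    design = design.set_index("sample")[["condition", "replicate"]]
    return CountMatrix(numeric.astype(int), design)


def write_counts(matrix: CountMatrix, counts_path, design_path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    matrix.design.rename_axis("sample").to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def read_network(
    path,
    *,
    col_regulator: str = "regulator",
    col_class: str = "class",
    col_target: str = "target",
    col_mode: str = "mode",
    tolerate_unknown_modes: bool = False,
) -> RegulatoryNetwork:
    """Read a regulator->target interaction table (EcoCyc-SmartTables-like).

    The canonical dialect has columns regulator / class / target / mode; the
    ``col_*`` arguments remap arbitrary exports onto it. Mode strings are
    normalized ("+" -> activator, "-" -> repressor, "+/-" -> dual, blank ->
    unknown); with ``tolerate_unknown_modes`` any unrecognized string maps
    to "unknown" instead of raising. Exact duplicate rows are collapsed with
    a logged warning.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in (col_regulator, col_class, col_target, col_mode):
        if col not in raw.columns:
            raise FormatError(f"network table missing column {col!r}")
    table = pd.DataFrame(
        {
            "regulator": raw[col_regulator],
            "reg_class": raw[col_class],
            "target": raw[col_target],
            "mode": raw[col_mode].str.strip(),
        }
    )

    def norm_mode(m: str) -> str:
        if m in MODE_SYNONYMS:
            return MODE_SYNONYMS[m]
        if tolerate_unknown_modes:
            return "unknown"
        raise FormatError(f"unrecognized regulation mode {m!r}")

    table["mode"] = table["mode"].map(norm_mode)
    ndup = int(table.duplicated().sum())
    if ndup:
        logger.warning("collapsed %d duplicated network row(s)", ndup)
        table = table.drop_duplicates()
    return RegulatoryNetwork(table.reset_index(drop=True))


def write_network(network: RegulatoryNetwork, path) -> None:
    out = network.edges.rename(columns={"reg_class": "class"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# COG I/O
# ---------------------------------------------------------------------------


def read_cog(path, legend: Mapping[str, str] | None = None) -> COGAnnotation:
    """Read a gene -> categories TSV (columns ``gene``, ``categories``).

    ``categories`` concatenates one-letter codes (e.g. ``CE``); an empty
    field means the gene is unannotated.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("gene", "categories"):
        if col not in raw.columns:
            raise FormatError(f"COG table missing column {col!r}")
    if raw["gene"].duplicated().any():
        dup = raw["gene"][raw["gene"].duplicated()].iloc[0]
        raise FormatError(f"duplicate gene {dup!r} in COG table")
    mapping = {g: frozenset(c) for g, c in zip(raw["gene"], raw["categories"])}
    if legend is None:
        return COGAnnotation(mapping)
    return COGAnnotation(mapping, dict(legend))


def write_cog(annotation: COGAnnotation, path) -> None:
    rows = [
        {"gene": g, "categories": "".join(sorted(cats))}
        for g, cats in annotation.mapping.items()
    ]
    pd.DataFrame(rows, columns=["gene", "categories"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# graph I/O
# ---------------------------------------------------------------------------


def write_graph(graph: NetworkGraph, path, fmt: str = "SIF") -> None:
    """Write a change graph for Cytoscape import.

    SIF lines are ``regulator<TAB>direction<TAB>gene``; GraphML carries the
    node ``kind`` and edge ``direction`` attributes.
    """
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.graph.edges(data=True)):
                fh.write(f"{u}\t{data['direction']}\t{v}\n")
            # isolated nodes (none in practice, but keep the file lossless)
            for node in sorted(graph.graph.nodes):
                if graph.graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "GraphML":
        nx.write_graphml(graph.graph, path)
    else:
        raise UsageError(f"unknown graph format {fmt!r}; use 'SIF' or 'GraphML'")


def read_graph(path, fmt: str = "SIF") -> NetworkGraph:
    if fmt == "SIF":
        g = nx.DiGraph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    # isolated node; kind is unrecoverable from SIF alone
                    g.add_node(parts[0], kind="regulator")
                elif len(parts) == 3:
                    u, direction, v = parts
                    g.add_node(u, kind="regulator")
                    g.add_node(v, kind="gene")
                    g.add_edge(u, v, direction=direction)
                elif parts != [""]:
                    raise FormatError(f"malformed SIF line {line!r}")
        return NetworkGraph(g)
    if fmt == "GraphML":
        return NetworkGraph(nx.read_graphml(path))
    raise UsageError(f"unknown graph format {fmt!r}; use 'SIF' or 'GraphML'")


# ---------------------------------------------------------------------------
# namespace diagnostics
# ---------------------------------------------------------------------------


def unmatched_ids(reference: Iterable[str], query: Iterable[str]) -> set[str]:
    """Ids present in ``query`` but absent from ``reference`` (exact match)."""
    ref = set(reference)
    missing = {q for q in query if q not in ref}
    if missing:
        logger.warning("%d id(s) not found in reference namespace", len(missing))
    return missing
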