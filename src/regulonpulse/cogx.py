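"""COG functional-category cross-tabulation.

Counting convention: a gene carrying several categories contributes once to
*each* of them, so category counts sum to the total per-gene category
multiplicity, not to the number of genes. Genes with no category go to a
reserved "uncharacterized" bucket that is reported separately — it is not a
category row and is excluded from regulator x category matrices (the
"function unknown" codes R and S remain true categories and are counted
normally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .diffexpr import DEGSet
from .formats import COGAnnotation
from .trnmap import MappedChange

UNCHARACTERIZED = "uncharacterized"


@dataclass
class CogTally:
    """Per-category up/down counts for one gene set, with genome background.

    ``table`` is indexed by category code with columns ``up_count``,
    ``down_count`` and ``genome_count`` (annotated genes carrying the
    category, regardless of differential status); ``uncharacterized_up`` /
    ``_down`` count differential genes with no category at all.
    """

    label: str
    table: pd.DataFrame
    uncharacterized_up: int
    uncharacterized_down: int


def tally_cogs(degs: DEGSet, annotation: COGAnnotation) -> CogTally:
    """Cross-tabulate a DEG set by COG category (multi-counting)."""
    codes = list(annotation.legend)
    up = {c: 0 for c in codes}
    down = {c: 0 for c in codes}
    unchar = {"up": 0, "down": 0}
    for direction, genes in (("up", degs.up), ("down", degs.down)):
        counter = up if direction == "up" else down
        for gene in genes:
            cats = annotation.categories(gene)
            if not cats:
                unchar[direction] += 1
                continue
            for c in cats:
                counter[c] += 1
    genome = annotation.genome_counts()
    table = pd.DataFrame(
        {
            "up_count": [up[c] for c in codes],
            "down_count": [down[c] for c in codes],
            "genome_count": [genome[c] for c in codes],
        },
        index=pd.Index(codes, name="category"),
    )
    return CogTally(degs.contrast, table, unchar["up"], unchar["down"])


def regulator_cog_matrix(
    mapped: Iterable[MappedChange], annotation: COGAnnotation
) -> pd.DataFrame:
    """Long-format regulator x category x direction gene counts.

    Cell value: distinct genes mapped to the regulator in that direction
    carrying the category. Unannotated genes are excluded entirely; a
    multi-category gene counts once per category.
    """
    seen: set[tuple[str, str, str, str]] = set()  # regulator, gene, direction, cat
    for rec in mapped:
        for cat in annotation.categories(rec.gene):
            seen.add((rec.regulator, rec.gene, rec.direction, cat))
    if not seen:
        return pd.DataFrame(columns=["regulator", "category", "direction", "count"])
    frame = pd.DataFrame(sorted(seen), columns=["regulator", "gene", "direction", "category"])
    out = (
        frame.groupby(["regulator", "category", "direction"], sort=True)["gene"]
        .nunique()
        .reset_index(name="count")
    )
    return out


def write_tally(tally: CogTally, path) -> None:
    out = tally.table.copy()
    extra = pd.DataFrame(
        {
            "up_count": [tally.uncharacterized_up],
            "down_count": [tally.uncharacterized_down],
            "genome_count": [pd.NA],
        },
        index=pd.Index([UNCHARACTERIZED], name="category"),
    )
    pd.concat([out, extra]).to_csv(path, sep="\t", na_rep="NA")
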