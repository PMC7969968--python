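"""End-to-end orchestration: simulate/load -> DE -> map -> compare -> crosstab.

One :func:`run_pipeline` call reproduces the whole analysis for a study:
per-contrast differential expression against a reference condition,
unique-to-treatment gene sets (relative to the untreated contrast),
regulator mapping and activity tallies, Fisher comparisons of each treated
population against the untreated one (sigma factors and TFs compared
separately), COG tallies and regulator x COG matrices, Cytoscape-ready
graphs, Venn-style overlap counts, and a machine-readable JSON report.
Identical configuration and seed produce a byte-identical report.

Convention for what feeds what, mirroring how such studies are presented:
activity tallies and Fisher comparisons use the *full* per-contrast DEG
sets (populations are compared on everything that changed), while exported
change graphs, COG tallies of treatment-specific biology, and the
cross-population overlap use the *unique* sets with the untreated
contrast's genes removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import cogx, diffexpr, formats, regstats, synthio, trnmap
from .errors import UsageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either give the four input paths (counts, design, network, COG) or
    leave them None to simulate a study from ``sim`` (written to
    ``outdir`` so every report number is re-derivable from files).
    """

    outdir: str
    counts_path: str | None = None
    design_path: str | None = None
    network_path: str | None = None
    cog_path: str | None = None
    sim: synthio.SimConfig | None = None
    reference_condition: str = "stationary"
    untreated_condition: str = "untreated"
    alpha: float = 0.1
    fold_cutoff: float = 2.0
    sign_rule: str = "strict"
    table_mode: str = "regulon"
    dispersion_mode: str = "trend"
    select_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.counts_path, self.design_path, self.network_path, self.cog_path]
        if any(p is None for p in paths) and not all(p is None for p in paths):
            raise UsageError("give all four input paths, or none (to simulate)")
        if self.counts_path is None and self.sim is None:
            self.sim = synthio.SimConfig(seed=self.seed)


def _slug(contrast: str) -> str:
    return contrast.replace(":", "_vs_")


def _load_or_simulate(config: RunConfig, outdir: Path):
    if config.counts_path is not None:
        matrix = formats.read_counts(config.counts_path, config.design_path)
        network = formats.read_network(config.network_path)
        annotation = formats.read_cog(config.cog_path)
        truth = None
    else:
        network, annotation, matrix, truth = synthio.simulate_study(config.sim)
        formats.write_counts(matrix, outdir / "counts.tsv", outdir / "design.tsv")
        formats.write_network(network, outdir / "network.tsv")
        formats.write_cog(annotation, outdir / "cog.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(_truth_json(truth), fh, indent=1, sort_keys=True)
    return matrix, network, annotation, truth


def _truth_json(truth: synthio.SyntheticTruth) -> dict:
    return {
        "active_regulators": {c: sorted(r) for c, r in truth.active_regulators.items()},
        "de_genes": {
            c: sorted([g, d, f] for g, d, f in triples)
            for c, triples in truth.de_genes.items()
        },
        "gene_baseline_mean": truth.gene_baseline_mean,
        "gene_dispersion": truth.gene_dispersion,
        "sample_libsize_factor": truth.sample_libsize_factor,
    }


def validate_inputs(
    matrix: formats.CountMatrix,
    network: formats.RegulatoryNetwork,
    annotation: formats.COGAnnotation,
    config: RunConfig,
) -> dict:
    """Non-fatal cross-file diagnostics.

    Reports gene ids that do not match across counts/network/COG, replicate
    counts per condition (warning below two), and echoes the thresholds.
    """
    count_genes = set(matrix.gene_ids)
    diag: dict = {
        "network_targets_not_in_counts": sorted(
            formats.unmatched_ids(count_genes, network.genes)
        ),
        "cog_genes_not_in_counts": sorted(
            formats.unmatched_ids(count_genes, annotation.mapping)
        ),
        "count_genes_without_regulator": len(count_genes - network.genes),
        "replicates_per_condition": {},
        "thresholds": {
            "alpha": config.alpha,
            "fold_cutoff": config.fold_cutoff,
            "sign_rule": config.sign_rule,
            "table_mode": config.table_mode,
            "select_alpha": config.select_alpha,
        },
    }
    for cond in matrix.conditions:
        n = len(matrix.samples_for(cond))
        diag["replicates_per_condition"][cond] = n
        if n < 2:
            logger.warning("condition %r has only %d replicate(s)", cond, n)
    return diag


def _subset_activity(
    activity: trnmap.RegulatorActivity, reg_class: str
) -> trnmap.RegulatorActivity:
    mask = activity.table["reg_class"] == reg_class
    table = activity.table[mask]
    return trnmap.RegulatorActivity(
        activity.contrast,
        table,
        {r: activity.mapped_genes[r] for r in table.index},
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the JSON report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, network, annotation, truth = _load_or_simulate(config, outdir)
    diagnostics = validate_inputs(matrix, network, annotation, config)

    reference = config.reference_condition
    if reference not in matrix.conditions:
        raise UsageError(f"reference condition {reference!r} not in design")
    contrast_conditions = [
        c
        for c in matrix.conditions
        if c != reference and len(matrix.samples_for(c)) >= 2
    ]

    report: dict = {
        "seed": config.seed,
        "reference_condition": reference,
        "untreated_condition": config.untreated_condition,
        "diagnostics": diagnostics,
        "contrasts": {},
        "fisher": {},
        "overlap": {},
    }
    if truth is not None:
        report["planted_regulators"] = {
            c: sorted(r) for c, r in truth.active_regulators.items()
        }

    degsets: dict[str, diffexpr.DEGSet] = {}
    unique_sets: dict[str, diffexpr.DEGSet] = {}
    activities: dict[str, trnmap.RegulatorActivity] = {}

    for cond in contrast_conditions:
        result = diffexpr.de_test(
            matrix, reference, cond, dispersion_mode=config.dispersion_mode
        )
        degs = diffexpr.call_degs(result, config.fold_cutoff, config.alpha)
        degsets[cond] = degs
        slug = _slug(degs.contrast)
        diffexpr.write_de_table(result, outdir / f"de_{slug}.tsv")

        mapped_full = trnmap.map_degs(degs, network, config.sign_rule)
        activities[cond] = trnmap.activity_counts(mapped_full, network, degs.contrast)
        trnmap.write_mapped(mapped_full, outdir / f"mapped_{slug}.tsv")
        trnmap.write_activity(activities[cond], outdir / f"activity_{slug}.tsv")

        entry = {
            "n_up": len(degs.up),
            "n_down": len(degs.down),
            "mapped_records": len(mapped_full),
            "activity": {
                r: {
                    "up": int(row["up_count"]),
                    "down": int(row["down_count"]),
                    "regulon_size": int(row["regulon_size"]),
                }
                for r, row in activities[cond].table.iterrows()
            },
        }
        tally = cogx.tally_cogs(degs, annotation)
        cogx.write_tally(tally, outdir / f"cog_tally_{slug}.tsv")
        entry["cog_tally"] = {
            code: {
                "up": int(row["up_count"]),
                "down": int(row["down_count"]),
                "genome": int(row["genome_count"]),
            }
            for code, row in tally.table.iterrows()
        }
        entry["cog_uncharacterized"] = {
            "up": tally.uncharacterized_up,
            "down": tally.uncharacterized_down,
        }
        report["contrasts"][degs.contrast] = entry

    # unique-to-treatment sets, graphs, and regulator x COG matrices
    untreated = config.untreated_condition
    for cond in contrast_conditions:
        degs = degsets[cond]
        if cond != untreated and untreated in degsets:
            uniq = diffexpr.unique_degs(degs, degsets[untreated])
        else:
            uniq = degs
        unique_sets[cond] = uniq
        slug = _slug(degs.contrast)
        mapped_uniq = trnmap.map_degs(uniq, network, config.sign_rule)
        graph = trnmap.build_graph(mapped_uniq)
        formats.write_graph(graph, outdir / f"graph_{slug}.sif", "SIF")
        formats.write_graph(graph, outdir / f"graph_{slug}.graphml", "GraphML")
        matrix_long = cogx.regulator_cog_matrix(mapped_uniq, annotation)
        matrix_long.to_csv(outdir / f"regulator_cog_{slug}.tsv", sep="\t", index=False)
        report["contrasts"][degs.contrast]["unique_up"] = len(uniq.up)
        report["contrasts"][degs.contrast]["unique_down"] = len(uniq.down)

    # Fisher comparisons: each treated-like population vs the untreated one,
    # sigma factors and TFs tested separately
    if untreated in activities:
        for cond in contrast_conditions:
            if cond == untreated:
                continue
            for reg_class in ("sigma", "TF"):
                act_t = _subset_activity(activities[cond], reg_class)
                act_u = _subset_activity(activities[untreated], reg_class)
                if act_t.table.empty:
                    continue
                comps = regstats.compare_regulators(
                    act_t,
                    act_u,
                    table_mode=config.table_mode,
                    select_alpha=config.select_alpha,
                )
                key = f"{cond}|{untreated}|{reg_class}"
                slug = f"{_slug(degsets[cond].contrast)}_{reg_class}"
                regstats.comparisons_frame(comps).to_csv(
                    outdir / f"fisher_{slug}.tsv", sep="\t", index=False
                )
                report["fisher"][key] = {
                    c.regulator: {
                        "table": [list(c.table[0]), list(c.table[1])],
                        "odds_ratio": None
                        if c.odds_ratio != c.odds_ratio
                        else ("inf" if c.odds_ratio == float("inf") else c.odds_ratio),
                        "pvalue": c.pvalue,
                        "padj": c.padj,
                        "selected": c.selected,
                    }
                    for c in comps
                }
                report["fisher"][key]["selected_regulators"] = sorted(
                    c.regulator for c in comps if c.selected
                )

    # cross-population overlap of unique sets (untreated excluded)
    overlap_pool = {
        degsets[c].contrast: unique_sets[c]
        for c in contrast_conditions
        if c != untreated
    }
    if len(overlap_pool) >= 2:
        regions = regstats.overlap_counts(overlap_pool)
        report["overlap"] = {
            direction: {"+".join(combo): n for combo, n in sorted(combos.items())}
            for direction, combos in regions.items()
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def config_from_yaml(path) -> RunConfig:
    """Build a RunConfig (and nested SimConfig) from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise UsageError(f"unknown config key(s): {sorted(unknown)}")
    sim = None
    if sim_raw is not None:
        sim_known = {f.name for f in dataclasses.fields(synthio.SimConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise UsageError(f"unknown sim config key(s): {sorted(bad)}")
        for key in ("regulon_size_range", "mode_probs", "baseline_mean_log10_range",
                    "dispersion_range", "libsize_factor_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "conditions" in sim_raw:
            sim_raw["conditions"] = tuple(sim_raw["conditions"])
        if "active_regulators" in sim_raw:
            sim_raw["active_regulators"] = {
                c: frozenset(v) for c, v in sim_raw["active_regulators"].items()
            }
        sim = synthio.SimConfig(**sim_raw)
    return RunConfig(sim=sim, **raw)
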