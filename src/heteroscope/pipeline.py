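"""End-to-end orchestration: design → heterosis → DEGs → distances →
correlations → gene screen → classification → enrichment, with every table
written as TSV and every threshold recorded.

Outputs are deterministic for a fixed config and seed: tables are written
with a fixed float format and each carries header comment lines naming the
convention and thresholds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import correlate, enrichment, heterosis
from .design import DiallelDesign, read_design
from .distance import pairwise_distances
from .expression import ExpressionMatrix, deg_counts_for_design
from .traits import TraitTable, summary_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    design_path: str
    traits_path: str
    fpkm_path: str
    sample_map_path: str
    outdir: str
    annotation_path: str | None = None
    gene_subsets: dict[str, str] = field(default_factory=dict)  # label -> gene-list file
    convention: str = "difference"
    deg_alpha: float = 0.05
    deg_fc_min: float = 1.0
    deg_pseudo: float = 0.1
    distance_transform: str = "identity"
    distance_tau: float = 0.0
    screen_alpha_fdr: float = 0.01
    screen_basis: str = "MPV"
    enrich_q_max: float = 0.05
    pathway_q_max: float = 0.05
    target_trait: str = "PGW"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_alpha", "screen_alpha_fdr", "enrich_q_max", "pathway_q_max"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise PipelineError(f"{name} must lie in (0, 1), got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)

    def thresholds(self) -> dict:
        skip = {"design_path", "traits_path", "fpkm_path", "sample_map_path",
                "annotation_path", "gene_subsets", "outdir"}
        return {k: v for k, v in dataclasses.asdict(self).items() if k not in skip}


def _write_tsv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w") as handle:
        for key in sorted(header):
            handle.write(f"# {key}: {header[key]}\n")
        df.to_csv(handle, sep="\t", float_format="%.6g",
                  index=isinstance(df.index, pd.Index) and df.index.name is not None)


def load_inputs(config: RunConfig) -> tuple[DiallelDesign, TraitTable, ExpressionMatrix]:
    design = read_design(config.design_path)
    traits = TraitTable.read_wide(config.traits_path)
    expression = ExpressionMatrix.read(config.fpkm_path, config.sample_map_path)
    return design, traits, expression


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns a dict of the in-memory results.  A stage failure aborts with
    the stage name; partial outputs stay on disk next to a FAILED marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = []
    results: dict = {}
    stage = "load"

    def log(key: str, value) -> None:
        run_log.append(f"{key}={value}")

    try:
        design, traits, expression = load_inputs(config)
        log("stage_load.parents", design.n_parents)
        log("stage_load.crosses", len(design.crosses))
        log("stage_load.missing", len(design.missing))
        log("stage_load.genes", len(expression.genes))
        meta = config.thresholds()

        stage = "trait_summary"
        hybrid_codes = [h for h in design.hybrids if h in traits.data.index]
        parent_codes = [p for p in design.parents if p in traits.data.index]
        summaries = summary_table(traits, {"parents": parent_codes, "hybrids": hybrid_codes})
        _write_tsv(summaries, outdir / "trait_summary.tsv", meta)
        results["trait_summary"] = summaries

        stage = "heterosis"
        het = heterosis.compute_heterosis(design, traits, convention=config.convention)
        _write_tsv(het, outdir / "heterosis.tsv", meta)
        results["heterosis"] = het
        log("stage_heterosis.records", len(het))
        parent_means = []
        for trait_name in traits.traits:
            for statistic in ("MPH", "HPH"):
                series = heterosis.parent_mean_heterosis(het, design, trait_name, statistic)
                frame = series.reset_index()
                frame.insert(0, "trait", trait_name)
                frame.insert(1, "statistic", statistic)
                frame.columns = ["trait", "statistic", "parent", "mean_value"]
                parent_means.append(frame)
        parent_means = pd.concat(parent_means, ignore_index=True)
        _write_tsv(parent_means, outdir / "parent_mean_heterosis.tsv", meta)
        results["parent_mean_heterosis"] = parent_means

        stage = "degs"
        deg_counts = deg_counts_for_design(expression, design, alpha=config.deg_alpha,
                                           fc_min=config.deg_fc_min, pseudo=config.deg_pseudo)
        _write_tsv(deg_counts, outdir / "deg_counts.tsv", meta)
        results["deg_counts"] = deg_counts

        stage = "distances"
        profiles = expression.parent_profiles()
        distances = pairwise_distances(profiles, transform=config.distance_transform,
                                       tau=config.distance_tau)
        _write_tsv(distances, outdir / "distances.tsv", meta)
        results["distances"] = distances

        stage = "correlations"
        count_rows, dist_rows = [], []
        for trait_name in traits.traits:
            responses = heterosis.heterosis_responses(het, trait_name)
            if responses.empty:
                log(f"stage_correlations.{trait_name}.skipped", "no heterosis records")
                continue
            count_rows.append(correlate.deg_count_correlation(design, deg_counts,
                                                              responses, trait_name))
            dist_rows.append(correlate.distance_correlation(distances, design,
                                                            responses, trait_name))
        deg_corr = pd.concat(count_rows, ignore_index=True)
        dist_corr = pd.concat(dist_rows, ignore_index=True)
        _write_tsv(deg_corr, outdir / "deg_count_correlations.tsv", meta)
        _write_tsv(dist_corr, outdir / "distance_correlations.tsv", meta)
        results["deg_count_correlations"] = deg_corr
        results["distance_correlations"] = dist_corr

        stage = "screen"
        responses = heterosis.heterosis_responses(het, config.target_trait)
        screen = correlate.gene_correlation_screen(profiles, design, responses,
                                                   alpha_fdr=config.screen_alpha_fdr)
        _write_tsv(screen, outdir / "gene_screen.tsv", meta)
        results["screen"] = screen
        log("stage_screen.constant_genes", screen.attrs["n_constant"])

        stage = "classify"
        sets = correlate.classify_correlated_genes(screen)
        set_counts = pd.DataFrame(sorted((k, len(v)) for k, v in sets.items()),
                                  columns=["set", "n_genes"])
        _write_tsv(set_counts, outdir / "gene_set_counts.tsv", meta)
        results["gene_sets"] = sets
        results["gene_set_counts"] = set_counts

        stage = "pathways"
        if config.gene_subsets:
            table = correlate.pathway_table(screen, basis=config.screen_basis)
            for label, path in sorted(config.gene_subsets.items()):
                subset = [line.strip() for line in Path(path).read_text().splitlines()
                          if line.strip()]
                filtered, extrema = correlate.filter_pathway_records(
                    table, subset, q_max=config.pathway_q_max)
                _write_tsv(filtered, outdir / f"pathway_{label}.tsv", {**meta, **extrema})
                results[f"pathway_{label}"] = (filtered, extrema)

        stage = "enrichment"
        if config.annotation_path:
            annotation = enrichment.AnnotationMap.read(config.annotation_path,
                                                       universe=expression.genes)
            for label in ("both_positive", "both_negative"):
                gene_set = sets.get(label, set())
                if not gene_set:
                    log(f"stage_enrichment.{label}", "empty set, skipped")
                    continue
                enriched = enrichment.enrich(gene_set, annotation, q_max=config.enrich_q_max)
                _write_tsv(enriched, outdir / f"enrichment_{label}.tsv", meta)
                results[f"enrichment_{label}"] = enriched
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage = "finalize"
    for key in sorted(config.thresholds()):
        log(f"config.{key}", config.thresholds()[key])
    (outdir / "run_log.txt").write_text("\n".join(run_log) + "\n")
    hashes = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
              for p in sorted(outdir.glob("*.tsv"))}
    (outdir / "manifest.json").write_text(json.dumps(hashes, indent=2, sort_keys=True) + "\n")
    results["manifest"] = hashes
    return results
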