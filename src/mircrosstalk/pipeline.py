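"""End-to-end pipeline: differential expression -> overlap -> enrichment ->
networks -> drug connectivity -> chemical association -> crosstalk.

Stages are plain functions over in-memory objects so the analysis scripts,
the CLI, and the tests can run any slice; :func:`run_pipeline` composes them
and writes the full report-table set into an output directory.  Given the
same inputs and seed the output directory is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from mircrosstalk import connectivity as conn
from mircrosstalk import crosstalk as xt
from mircrosstalk import diffexpr, enrich, nettopo
from mircrosstalk import overlap as ovl
from mircrosstalk import synthdata
from mircrosstalk.errors import InputError

logger = logging.getLogger(__name__)

CONTEXTS = ("ctx1", "ctx2")
#: extreme-rank fraction defining a drug-miRNA interaction for the molecule
#: dimension of the crosstalk score
DRUG_RANK_QUARTILE = 0.25
REPORT_PRECISION = 6


@dataclass
class PipelineConfig:
    """Resolved run configuration (echoed to the output directory)."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    data_dir: str | None = None  # required for files mode
    p_cut: float = diffexpr.P_CUT
    lfc_cut: float = diffexpr.LFC_CUT
    seed: int = 0
    outdir: str = "results/run"
    top_k: int = 30
    synth: synthdata.SynthConfig | None = None

    def __post_init__(self) -> None:
        if self.p_cut <= 0 or self.lfc_cut <= 0:
            raise InputError("thresholds must be positive")
        if self.mode not in ("synthetic", "files"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.data_dir:
            raise InputError("files mode requires data_dir")
        if self.mode == "synthetic" and self.synth is None:
            self.synth = synthdata.SynthConfig(seed=self.seed)


@dataclass
class PipelineResult:
    de_tables: dict
    overlaps: dict
    enrichment: dict
    metrics: dict
    drug_screen: pd.DataFrame
    chemical_screen: pd.DataFrame
    crosstalk_rows: pd.DataFrame
    crosstalk_network: object
    bridging: list[str]
    outdir: Path | None = None
    log_lines: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_differential(
    bundle: synthdata.StudyBundle, p_cut: float, lfc_cut: float
) -> dict:
    """Moderated DE tables for both assays and both contexts."""
    out: dict = {}
    for assay, study in (("mrna", bundle.mrna), ("mirna", bundle.mirna)):
        out[assay] = {}
        for ctx in CONTEXTS:
            contrast = synthdata.CONTEXT_GROUPS[ctx]
            out[assay][ctx] = diffexpr.fit_contrast(
                study, contrast, p_cut=p_cut, lfc_cut=lfc_cut
            )
    return out


def stage_overlap(de_tables: dict) -> dict:
    """Direction-aware Venn partition per assay."""
    return {
        assay: ovl.concordant_overlap(
            diffexpr.de_features(de_tables[assay]["ctx1"]),
            diffexpr.de_features(de_tables[assay]["ctx2"]),
        )
        for assay in ("mrna", "mirna")
    }


def stage_enrichment(
    overlap_genes, ann: synthdata.AnnotationBundle, universe
) -> dict:
    """ORA of the concordant overlapping DEGs against both collections."""
    return {
        "pathway": enrich.ora(overlap_genes, ann.pathways, universe),
        "bp": enrich.ora(overlap_genes, ann.bps, universe),
    }


def stage_networks(
    de_tables: dict, ann: synthdata.AnnotationBundle, top_k: int
) -> dict:
    """PPI, TF and miRNA-target networks with ranked topology tables."""
    merged = nettopo.merge_targets(ann.validated_targets, ann.predicted_targets)
    out: dict = {"graphs": {}, "tables": {}, "detargets": {}}
    for ctx in CONTEXTS:
        de_genes = diffexpr.de_features(de_tables["mrna"][ctx])
        de_mirnas = diffexpr.de_features(de_tables["mirna"][ctx])
        graphs = {
            "ppi": nettopo.assemble_ppi(de_genes, ann.ppi_edges),
            "tf": nettopo.assemble_tf(de_genes, ann.tf_edges),
            "mirna_target": nettopo.assemble_mirna_target(
                de_mirnas, merged, de_genes
            ),
        }
        out["graphs"][ctx] = graphs
        out["tables"][ctx] = {
            name: nettopo.metrics_report(g, k=top_k)
            if g.number_of_nodes()
            else pd.DataFrame()
            for name, g in graphs.items()
        }
        out["detargets"][ctx] = nettopo.mirna_detargets(
            de_mirnas, merged, de_genes
        )
    out["merged_targets"] = merged
    return out


def _tag_sets(de_mirna_table: pd.DataFrame) -> tuple:
    de = diffexpr.de_features(de_mirna_table)
    up = frozenset(m for m, d in de.items() if d == "up")
    down = frozenset(m for m, d in de.items() if d == "down")
    if not up or not down:
        return None
    return (
        conn.TagSet(features=up, polarity="up"),
        conn.TagSet(features=down, polarity="down"),
    )


def stage_drug_screen(
    de_tables: dict, ann: synthdata.AnnotationBundle
) -> pd.DataFrame:
    """Cross-context connectivity screen of every drug signature."""
    tags = {}
    for ctx in CONTEXTS:
        ts = _tag_sets(de_tables["mirna"][ctx])
        if ts is None:
            logger.warning("context %s lacks up or down DEmiRNAs; empty screen", ctx)
            return pd.DataFrame(columns=["drug", "enrichment_ctx1",
                                         "enrichment_ctx2", "concordance"])
        tags[ctx] = ts
    signatures = [
        conn.RankedSignature(drug_id=d, context_id=c, ordered_features=sig)
        for (d, c), sig in sorted(ann.drug_signatures.items())
    ]
    return conn.screen_drugs(tags, signatures)


def stage_chemical_screen(
    de_tables: dict,
    ann: synthdata.AnnotationBundle,
    merged_targets: Mapping[str, frozenset[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric miRNA-chemical association per context."""
    frames = []
    for ctx in CONTEXTS:
        de_mirnas = diffexpr.de_features(de_tables["mirna"][ctx])
        mirna_targets = {
            m: merged_targets.get(m, frozenset()) for m in sorted(de_mirnas)
        }
        df = enrich.mirna_chemical_assoc(ann.chemical_genes, mirna_targets, universe)
        df.insert(0, "context", ctx)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def build_feature_sets(
    de_tables: dict,
    ann: synthdata.AnnotationBundle,
    networks: dict,
    drug_screen: pd.DataFrame,
    chemical_screen: pd.DataFrame,
    universe,
) -> xt.FeatureSetCollection:
    """Per (DEmiRNA, context) sets across the five crosstalk dimensions.

    targets: DE target genes of the miRNA in that context; molecules: drugs
    with nonzero S in the context whose signature ranks the miRNA in the top
    or bottom quartile; chemicals: association-screen pairs retained at
    p < 0.05; pathways/bps: terms enriched (raw p < 0.05) in the miRNA's DE
    targets.
    """
    nonzero_drugs = {}
    for ctx, col in (("ctx1", "enrichment_ctx1"), ("ctx2", "enrichment_ctx2")):
        if len(drug_screen):
            nonzero_drugs[ctx] = set(drug_screen.loc[drug_screen[col] != 0, "drug"])
        else:
            nonzero_drugs[ctx] = set()
    collection = xt.FeatureSetCollection()
    for ctx in CONTEXTS:
        detargets = networks["detargets"][ctx]
        retained = chemical_screen[
            (chemical_screen["context"] == ctx) & chemical_screen["retained"]
        ] if len(chemical_screen) else pd.DataFrame(columns=["mirna", "chemical"])
        for mirna in sorted(detargets):
            targets = detargets[mirna]
            molecules = set()
            for drug in nonzero_drugs[ctx]:
                sig = ann.drug_signatures.get((drug, ctx))
                if sig is None or mirna not in sig:
                    continue
                rank = sig.index(mirna) + 1
                n = len(sig)
                if rank <= DRUG_RANK_QUARTILE * n or rank > (1 - DRUG_RANK_QUARTILE) * n:
                    molecules.add(drug)
            chems = set(retained.loc[retained["mirna"] == mirna, "chemical"])
            pathways = set()
            bps = set()
            if targets:
                for dim, coll in (("pathway", ann.pathways), ("bp", ann.bps)):
                    res = enrich.ora(targets, coll, universe)
                    terms = set(res.loc[res["significant"], "term_id"])
                    (pathways if dim == "pathway" else bps).update(terms)
            collection.add(
                mirna, ctx,
                targets=targets, molecules=molecules, chemicals=chems,
                pathways=pathways, bps=bps,
            )
    return collection


def stage_crosstalk(collection: xt.FeatureSetCollection) -> tuple:
    rows = xt.score_all_pairs(collection)
    network = xt.build_crosstalk_network(rows)
    bridging = xt.identify_bridging(network)
    return rows, network, bridging


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        synth = config.synth
        if synth.seed != config.seed:
            synth = synthdata.SynthConfig(**{**synth.__dict__, "seed": config.seed})
        bundle, truth = synthdata.generate_study(synth)
        ann = synthdata.generate_annotations(synth, truth)
        return bundle, truth, ann
    data_dir = Path(config.data_dir)
    if not data_dir.exists():
        raise InputError(f"data directory not found: {data_dir}")
    bundle, truth = synthdata.read_study(data_dir)
    ann = synthdata.read_annotations(data_dir)
    return bundle, truth, ann


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage; optionally write the report tables to config.outdir."""
    bundle, truth, ann = _load_inputs(config)
    universe = list(bundle.mrna.matrix.index)
    log: list[str] = [f"mode={config.mode} seed={config.seed}"]

    de_tables = stage_differential(bundle, config.p_cut, config.lfc_cut)
    for assay in ("mrna", "mirna"):
        for ctx in CONTEXTS:
            n_de = len(diffexpr.de_features(de_tables[assay][ctx]))
            log.append(f"de {assay} {ctx}: {n_de} features called")

    overlaps = stage_overlap(de_tables)
    log.append(
        f"overlap genes: {len(overlaps['mrna'].concordant)} concordant, "
        f"{len(overlaps['mrna'].discordant)} discordant"
    )
    log.append(f"overlap mirnas (any direction): {len(overlaps['mirna'].de_both)}")

    enrichment = stage_enrichment(overlaps["mrna"].concordant, ann, universe)
    networks = stage_networks(de_tables, ann, config.top_k)
    drug_screen = stage_drug_screen(de_tables, ann)
    log.append(f"drug screen: {len(drug_screen)} drugs in both contexts")
    chemical_screen = stage_chemical_screen(
        de_tables, ann, networks["merged_targets"], universe
    )
    n_ret = int(chemical_screen["retained"].sum()) if len(chemical_screen) else 0
    log.append(f"chemical screen: {n_ret} retained (miRNA, chemical) pairs")

    collection = build_feature_sets(
        de_tables, ann, networks, drug_screen, chemical_screen, universe
    )
    rows, network, bridging = stage_crosstalk(collection)
    log.append(
        f"crosstalk: {len(rows)} scored pairs, "
        f"{network.number_of_edges()} retained edges, bridging={bridging}"
    )

    result = PipelineResult(
        de_tables=de_tables,
        overlaps=overlaps,
        enrichment=enrichment,
        metrics=networks["tables"],
        drug_screen=drug_screen,
        chemical_screen=chemical_screen,
        crosstalk_rows=rows,
        crosstalk_network=network,
        bridging=bridging,
        log_lines=log,
    )
    if write:
        result.outdir = write_outputs(config, result)
    return result


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{REPORT_PRECISION}g")


def write_outputs(config: PipelineConfig, result: PipelineResult) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ctx in CONTEXTS:
        _fmt(diffexpr.report_table(result.de_tables["mrna"][ctx]),
             outdir / f"de_{ctx}.tsv")
        _fmt(diffexpr.report_table(result.de_tables["mirna"][ctx]),
             outdir / f"de_mirna_{ctx}.tsv")
    venn = []
    for assay in ("mrna", "mirna"):
        s = result.overlaps[assay].summary()
        s.insert(0, "assay", assay)
        venn.append(s)
    _fmt(pd.concat(venn, ignore_index=True), outdir / "venn_summary.tsv")
    for dim, df in result.enrichment.items():
        _fmt(df, outdir / f"enrichment_{dim}.tsv")
    for ctx, tables in result.metrics.items():
        for name, tab in tables.items():
            _fmt(tab, outdir / f"{name}_{ctx}_metrics.tsv")
    _fmt(result.drug_screen, outdir / "drug_screen.tsv")
    retained = result.chemical_screen
    if len(retained):
        retained = retained[retained["retained"]].drop(columns="retained")
    _fmt(retained, outdir / "chemical_edges.tsv")
    xt.format_scores(result.crosstalk_rows, REPORT_PRECISION).to_csv(
        outdir / "crosstalk_scores.tsv", sep="\t", index=False
    )
    with open(outdir / "crosstalk_network.sif", "w") as fh:
        for u, v in sorted(result.crosstalk_network.edges()):
            fh.write(f"{u}\tcrosstalk\t{v}\n")
    (outdir / "bridging_mirnas.txt").write_text(
        "".join(f"{m}\n" for m in result.bridging)
    )
    cfg = {k: v for k, v in config.__dict__.items() if k != "synth"}
    if config.synth is not None:
        cfg["synth"] = config.synth.__dict__
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    (outdir / "run.log").write_text("".join(f"{s}\n" for s in result.log_lines))
    return outdir
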