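"""Synthetic coculture study generator: expression matrices, annotation
tables, and the ground truth needed to test every downstream stage.

The generator emulates the structure of a four-group bulk microarray design
(A: EC monoculture, B: cocultured ECs, C: NSPC monoculture, D: cocultured
NSPCs) with two paired contrasts -- context 1 (B vs A, NSPC-induced EC
alteration) and context 2 (D vs C, EC-induced NSPC alteration):

* log2 intensities with per-feature baselines ~ U(4, 12) and i.i.d. Gaussian
  noise of sd ``noise_sd_log2`` (constant across features, so the planted
  effect-to-noise ratio is exactly the configured one);
* planted differentially expressed genes and miRNAs per context (mean shift
  +/- effect_size_log2 in the experimental group), with configurable
  shared-concordant and shared-discordant gene subsets and shared DEmiRNAs;
* annotation tables (miRNA targets validated/predicted, pathway and GO BP
  collections, PPI and TF edges, chemical gene sets) constructed so the
  planted structure is recoverable: each planted miRNA regulates a disjoint
  module of its own context's exclusive DE genes, shared miRNAs regulate the
  shared DE genes, and background targets are drawn from non-DE genes; and
* per-drug, per-context ranked signatures whose KS response to the planted
  up/down DEmiRNA tag sets has a known sign.

Identical (config, seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mircrosstalk.diffexpr import ExpressionStudy
from mircrosstalk.errors import ConfigError

GROUPS = ("A", "B", "C", "D")
#: experimental group per context (controls are A and C respectively)
CONTEXT_GROUPS = {"ctx1": ("B", "A"), "ctx2": ("D", "C")}

#: Fraction of up-regulated features among planted DEmiRNAs, per context
#: (5 of 18 and 5 of 8 in the emulated design).
MIRNA_UP_FRACTION = {"ctx1": 5 / 18, "ctx2": 5 / 8}
#: Extreme-rank zone (fraction of the signature) where tag miRNAs are planted.
SIGNATURE_ZONE = 0.15


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale parameters; defaults are the package's standing conditions."""

    n_genes: int = 2000
    n_mirnas: int = 300
    n_reps_per_group: int = 3
    n_de_genes_ctx1: int = 150
    n_de_genes_ctx2: int = 220
    n_shared_concordant_genes: int = 20
    n_shared_discordant_genes: int = 6
    n_de_mirnas_ctx1: int = 18
    n_de_mirnas_ctx2: int = 8
    n_shared_mirnas: int = 3
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.25
    n_drugs: int = 20
    n_chemicals: int = 30
    n_pathways: int = 40
    n_bp_terms: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            k: v
            for k, v in asdict(self).items()
            if k.startswith("n_") or k == "seed"
        }
        for name, value in counts.items():
            if name != "seed" and value < 0:
                raise ConfigError(f"{name} must be nonnegative (got {value})")
        if self.noise_sd_log2 <= 0:
            raise ConfigError("noise_sd_log2 must be positive")
        if self.effect_size_log2 < 0:
            raise ConfigError("effect_size_log2 must be nonnegative")
        if self.n_shared_mirnas > min(self.n_de_mirnas_ctx1, self.n_de_mirnas_ctx2):
            raise ConfigError(
                "n_shared_mirnas exceeds min(n_de_mirnas_ctx1, n_de_mirnas_ctx2)"
            )
        shared = self.n_shared_concordant_genes + self.n_shared_discordant_genes
        if shared > min(self.n_de_genes_ctx1, self.n_de_genes_ctx2):
            raise ConfigError(
                "n_shared_concordant_genes + n_shared_discordant_genes exceeds "
                "min(n_de_genes_ctx1, n_de_genes_ctx2)"
            )
        if self.n_reps_per_group < 2:
            raise ConfigError("n_reps_per_group must be >= 2")
        if self.n_de_genes_ctx1 + self.n_de_genes_ctx2 - shared > self.n_genes:
            raise ConfigError("planted DE genes exceed n_genes")
        if (
            self.n_de_mirnas_ctx1 + self.n_de_mirnas_ctx2 - self.n_shared_mirnas
            > self.n_mirnas
        ):
            raise ConfigError("planted DE miRNAs exceed n_mirnas")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure used by recovery tests.

    planted_de_genes/planted_de_mirnas: context -> {feature -> 'up'|'down'};
    planted_drug_sign: drug -> (sign_ctx1, sign_ctx2) with sign the intended
    sign of the integrated connectivity score S.
    """

    planted_de_genes: Mapping[str, Mapping[str, str]]
    planted_de_mirnas: Mapping[str, Mapping[str, str]]
    planted_shared_mirnas: frozenset[str]
    planted_drug_sign: Mapping[str, tuple[int, int]]
    planted_mirna_chemical: frozenset[tuple[str, str]]


@dataclass
class StudyBundle:
    """The two assay matrices sharing one four-group design."""

    mrna: ExpressionStudy
    mirna: ExpressionStudy


@dataclass
class AnnotationBundle:
    """File-shaped annotation inputs for the downstream stages."""

    validated_targets: list[tuple[str, str]]
    predicted_targets: list[tuple[str, str]]
    pathways: dict[str, frozenset[str]]
    bps: dict[str, frozenset[str]]
    ppi_edges: list[tuple[str, str]]
    tf_edges: list[tuple[str, str]]
    chemical_genes: dict[str, frozenset[str]]
    mirna_chemical: list[tuple[str, str]]
    drug_signatures: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=dict
    )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _plant_directions(rng: np.random.Generator, features, up_fraction=None):
    """feature -> 'up'|'down'; up_fraction fixes the split, else fair coin."""
    features = list(features)
    if up_fraction is None:
        dirs = rng.choice(["up", "down"], size=len(features))
        return dict(zip(features, dirs))
    n_up = int(round(up_fraction * len(features)))
    n_up = min(max(n_up, 1 if len(features) > 1 else 0), len(features) - 1) if len(
        features
    ) > 1 else len(features)
    order = rng.permutation(len(features))
    out = {}
    for rank, idx in enumerate(order):
        out[features[idx]] = "up" if rank < n_up else "down"
    return out


def _simulate_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    sample_ids: list[str],
    groups: list[str],
    planted: Mapping[str, Mapping[str, str]],
    effect: float,
    noise_sd: float,
) -> pd.DataFrame:
    n_feat, n_samp = len(feature_ids), len(sample_ids)
    baseline = rng.uniform(4.0, 12.0, size=n_feat)
    noise = rng.standard_normal((n_feat, n_samp)) * noise_sd
    mat = baseline[:, None] + noise
    index = {f: i for i, f in enumerate(feature_ids)}
    for ctx, de_map in planted.items():
        exp_group = CONTEXT_GROUPS[ctx][0]
        cols = [j for j, g in enumerate(groups) if g == exp_group]
        for feat, direction in de_map.items():
            shift = effect if direction == "up" else -effect
            mat[index[feat], cols] += shift
    out = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
    out.index.name = "feature_id"
    return out


def generate_study(config: SynthConfig) -> tuple[StudyBundle, GroundTruth]:
    """Simulate the four-group study and its ground truth (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    genes = _ids("gene", config.n_genes)
    mirnas = _ids("mir", config.n_mirnas)

    # --- plant DE genes -----------------------------------------------------
    nc, nd = config.n_shared_concordant_genes, config.n_shared_discordant_genes
    perm = rng.permutation(config.n_genes)
    shared_conc = [genes[i] for i in perm[:nc]]
    shared_disc = [genes[i] for i in perm[nc : nc + nd]]
    n1_only = config.n_de_genes_ctx1 - nc - nd
    n2_only = config.n_de_genes_ctx2 - nc - nd
    ctx1_only = [genes[i] for i in perm[nc + nd : nc + nd + n1_only]]
    ctx2_only = [genes[i] for i in perm[nc + nd + n1_only : nc + nd + n1_only + n2_only]]
    de_genes = {"ctx1": {}, "ctx2": {}}
    for g in shared_conc:
        d = str(rng.choice(["up", "down"]))
        de_genes["ctx1"][g] = d
        de_genes["ctx2"][g] = d
    for g in shared_disc:
        d = str(rng.choice(["up", "down"]))
        de_genes["ctx1"][g] = d
        de_genes["ctx2"][g] = "down" if d == "up" else "up"
    de_genes["ctx1"].update(_plant_directions(rng, ctx1_only))
    de_genes["ctx2"].update(_plant_directions(rng, ctx2_only))

    # --- plant DE miRNAs ----------------------------------------------------
    mperm = rng.permutation(config.n_mirnas)
    ns = config.n_shared_mirnas
    shared_mirnas = [mirnas[i] for i in mperm[:ns]]
    m1_only = [mirnas[i] for i in mperm[ns : config.n_de_mirnas_ctx1]]
    m2_only = [
        mirnas[i]
        for i in mperm[
            config.n_de_mirnas_ctx1 : config.n_de_mirnas_ctx1
            + config.n_de_mirnas_ctx2
            - ns
        ]
    ]
    de_mirnas = {
        "ctx1": _plant_directions(
            rng, shared_mirnas + m1_only, MIRNA_UP_FRACTION["ctx1"]
        ),
        "ctx2": _plant_directions(
            rng, shared_mirnas + m2_only, MIRNA_UP_FRACTION["ctx2"]
        ),
    }

    # --- matrices -----------------------------------------------------------
    reps = config.n_reps_per_group
    sample_ids = [f"{g}{r}" for g in GROUPS for r in range(1, reps + 1)]
    groups = [g for g in GROUPS for _ in range(reps)]
    design = dict(zip(sample_ids, groups))
    mrna_mat = _simulate_matrix(
        rng, genes, sample_ids, groups, de_genes,
        config.effect_size_log2, config.noise_sd_log2,
    )
    mirna_mat = _simulate_matrix(
        rng, mirnas, sample_ids, groups, de_mirnas,
        config.effect_size_log2, config.noise_sd_log2,
    )

    # --- drug and chemical truth -------------------------------------------
    drugs = _ids("drug", config.n_drugs)
    drug_sign = {
        d: (int(rng.choice([-1, 1])), int(rng.choice([-1, 1]))) for d in drugs
    }
    chemicals = _ids("chem", config.n_chemicals)
    de_mirna_union = sorted(set(de_mirnas["ctx1"]) | set(de_mirnas["ctx2"]))
    pairs = set()
    if chemicals:
        # every shared miRNA gets two chemical partners; other DE miRNAs one
        for i, m in enumerate(sorted(shared_mirnas)):
            pairs.add((m, chemicals[(2 * i) % len(chemicals)]))
            pairs.add((m, chemicals[(2 * i + 1) % len(chemicals)]))
        offset = 2 * len(shared_mirnas)
        for i, m in enumerate(x for x in de_mirna_union if x not in shared_mirnas):
            pairs.add((m, chemicals[(offset + i) % len(chemicals)]))

    truth = GroundTruth(
        planted_de_genes={c: dict(sorted(v.items())) for c, v in de_genes.items()},
        planted_de_mirnas={c: dict(sorted(v.items())) for c, v in de_mirnas.items()},
        planted_shared_mirnas=frozenset(shared_mirnas),
        planted_drug_sign=drug_sign,
        planted_mirna_chemical=frozenset(pairs),
    )
    contrasts = tuple(CONTEXT_GROUPS[c] for c in ("ctx1", "ctx2"))
    bundle = StudyBundle(
        mrna=ExpressionStudy(matrix=mrna_mat, design=design, contrasts=contrasts),
        mirna=ExpressionStudy(matrix=mirna_mat, design=design, contrasts=contrasts),
    )
    return bundle, truth


def _ranked_signature(
    rng: np.random.Generator,
    mirnas: list[str],
    up_tags: list[str],
    down_tags: list[str],
    sign: int,
) -> tuple[str, ...]:
    """Permutation of all miRNA ids whose KS response to the tags has `sign`.

    sign=+1: up tags in the top zone, down tags in the bottom zone (so
    KS_up > 0 > KS_down and S > 0); sign=-1 swaps the zones.
    """
    n = len(mirnas)
    top_tags, bottom_tags = (up_tags, down_tags) if sign > 0 else (down_tags, up_tags)
    z_top = max(len(top_tags), int(SIGNATURE_ZONE * n))
    z_bot = max(len(bottom_tags), int(SIGNATURE_ZONE * n))
    if z_top + z_bot > n:
        raise ConfigError("too many tag miRNAs for the signature length")
    slots = [None] * n
    top_pos = rng.choice(z_top, size=len(top_tags), replace=False)
    for pos, m in zip(sorted(top_pos), top_tags):
        slots[pos] = m
    bot_pos = rng.choice(z_bot, size=len(bottom_tags), replace=False)
    for pos, m in zip(sorted(bot_pos), bottom_tags):
        slots[n - z_bot + pos] = m
    rest = [m for m in mirnas if m not in set(top_tags) | set(bottom_tags)]
    rest = [rest[i] for i in rng.permutation(len(rest))]
    it = iter(rest)
    return tuple(m if m is not None else next(it) for m in slots)


def generate_annotations(
    config: SynthConfig, truth: GroundTruth
) -> AnnotationBundle:
    """Annotation tables consistent with (and recoverable from) the truth.

    Uses an rng derived from seed+1 so study and annotations can be generated
    independently yet reproducibly.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _ids("gene", config.n_genes)
    mirnas = _ids("mir", config.n_mirnas)
    de1 = truth.planted_de_genes["ctx1"]
    de2 = truth.planted_de_genes["ctx2"]
    shared_de_genes = sorted(set(de1) & set(de2))
    de_union = sorted(set(de1) | set(de2))

    # --- miRNA target tables ------------------------------------------------
    # Each planted miRNA regulates a module of DE genes exclusive to its own
    # context (disjoint across miRNAs); shared miRNAs regulate overlapping
    # draws from the shared DE genes.  Background targets come from non-DE
    # genes, so cross-context common DE targets identify planted crosstalk.
    ctx1_excl = sorted(set(de1) - set(de2))
    ctx2_excl = sorted(set(de2) - set(de1))
    non_de = sorted(set(genes) - set(de_union))
    modules: dict[str, set[str]] = {m: set() for m in mirnas}
    for ctx, pool in (("ctx1", ctx1_excl), ("ctx2", ctx2_excl)):
        only = sorted(
            set(truth.planted_de_mirnas[ctx]) - truth.planted_shared_mirnas
        )
        if not only or not pool:
            continue
        pool = [pool[i] for i in rng.permutation(len(pool))]
        size = min(8, len(pool) // len(only)) or 1
        for i, m in enumerate(only):
            modules[m].update(pool[i * size : (i + 1) * size])
    for m in sorted(truth.planted_shared_mirnas):
        take = min(6, len(shared_de_genes))
        if take:
            idx = rng.choice(len(shared_de_genes), size=take, replace=False)
            modules[m].update(shared_de_genes[i] for i in idx)

    validated: list[tuple[str, str]] = []
    predicted: list[tuple[str, str]] = []
    targets_by_mirna: dict[str, set[str]] = {}
    for m in mirnas:
        n_bg = int(rng.integers(15, 30))
        bg_idx = rng.choice(len(non_de), size=min(n_bg, len(non_de)),
                            replace=False)
        background = [non_de[i] for i in bg_idx]
        val = sorted(modules[m] | set(background[: 2 * n_bg // 3]))
        validated.extend((m, g) for g in val)
        # predicted overlaps validated (nonempty intersection) plus extras
        keep = max(1, len(val) // 3)
        kidx = rng.choice(len(val), size=keep, replace=False)
        pred = {val[i] for i in kidx} | set(background[2 * n_bg // 3 :])
        predicted.extend((m, g) for g in sorted(pred))
        targets_by_mirna[m] = set(val) | pred

    # --- gene-set collections ----------------------------------------------
    def _collection(prefix: str, n_terms: int) -> dict[str, frozenset[str]]:
        coll = {}
        for term in _ids(prefix, n_terms):
            size = int(rng.integers(10, 40))
            idx = rng.choice(config.n_genes, size=size, replace=False)
            coll[term] = set(genes[i] for i in idx)
        return coll

    pathways = _collection("path", config.n_pathways)
    bps = _collection("bp", config.n_bp_terms)
    # Each planted miRNA's module acts through a pathway and a BP term:
    # annotate several module genes to a designated term so the module is
    # genuinely over-represented there (and every shared miRNA has targets
    # annotated to at least one pathway).
    planted_mirnas = sorted(
        set(truth.planted_de_mirnas["ctx1"]) | set(truth.planted_de_mirnas["ctx2"])
    )
    for i, m in enumerate(planted_mirnas):
        anchor = sorted(modules[m]) or sorted(targets_by_mirna.get(m, set()))
        if not anchor:
            continue
        for coll in (pathways, bps):
            if coll:
                coll[list(coll)[i % len(coll)]].update(anchor[:4])
    pathways = {t: frozenset(s) for t, s in pathways.items()}
    bps = {t: frozenset(s) for t, s in bps.items()}

    # --- interaction edges ---------------------------------------------------
    ppi: set[tuple[str, str]] = set()
    for g in de_union:
        partners = rng.choice(config.n_genes, size=3, replace=False)
        for i in partners:
            other = genes[i]
            if other != g:
                ppi.add(tuple(sorted((g, other))))
    for _ in range(300):
        i, j = rng.choice(config.n_genes, size=2, replace=False)
        ppi.add(tuple(sorted((genes[i], genes[j]))))
    tf_pool = [genes[i] for i in rng.choice(config.n_genes, size=25, replace=False)]
    tf_edges: set[tuple[str, str]] = set()
    for tf in tf_pool:
        de_take = min(5, len(de_union))
        chosen = {de_union[i] for i in rng.choice(len(de_union), size=de_take,
                                                  replace=False)}
        chosen |= {genes[i] for i in rng.choice(config.n_genes, size=5,
                                                replace=False)}
        tf_edges |= {(tf, g) for g in chosen if g != tf}

    # --- chemical gene sets ---------------------------------------------------
    chemicals = _ids("chem", config.n_chemicals)
    chem_genes: dict[str, set[str]] = {c: set() for c in chemicals}
    for c in chemicals:
        idx = rng.choice(config.n_genes, size=int(rng.integers(5, 15)),
                         replace=False)
        chem_genes[c] = {genes[i] for i in idx}
    for m, c in sorted(truth.planted_mirna_chemical):
        tgt = sorted(targets_by_mirna.get(m, set()))
        take = min(8, len(tgt))
        if take:
            idx = rng.choice(len(tgt), size=take, replace=False)
            chem_genes[c] |= {tgt[i] for i in idx}

    # --- drug signatures ------------------------------------------------------
    signatures: dict[tuple[str, str], tuple[str, ...]] = {}
    for drug in sorted(truth.planted_drug_sign):
        s1, s2 = truth.planted_drug_sign[drug]
        for ctx, sign in (("ctx1", s1), ("ctx2", s2)):
            de_map = truth.planted_de_mirnas[ctx]
            up = sorted(m for m, d in de_map.items() if d == "up")
            down = sorted(m for m, d in de_map.items() if d == "down")
            signatures[(drug, ctx)] = _ranked_signature(rng, mirnas, up, down, sign)

    return AnnotationBundle(
        validated_targets=sorted(validated),
        predicted_targets=sorted(predicted),
        pathways=pathways,
        bps=bps,
        ppi_edges=sorted(ppi),
        tf_edges=sorted(tf_edges),
        chemical_genes={c: frozenset(s) for c, s in chem_genes.items()},
        mirna_chemical=sorted(truth.planted_mirna_chemical),
        drug_signatures=signatures,
    )


# ---------------------------------------------------------------------------
# File output / input (plain TSV, GMT, JSON)
# ---------------------------------------------------------------------------

def write_study(bundle: StudyBundle, truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for assay, study in (("mrna", bundle.mrna), ("mirna", bundle.mirna)):
        mat = study.matrix.rename_axis("feature_id")
        mat.to_csv(outdir / f"expression_{assay}.tsv", sep="\t",
                   float_format="%.17g")
    rows = []
    for assay, study in (("mRNA", bundle.mrna), ("miRNA", bundle.mirna)):
        for sample, group in study.design.items():
            rows.append((sample, group, assay))
    pd.DataFrame(rows, columns=["sample_id", "group", "assay"]).to_csv(
        outdir / "design.tsv", sep="\t", index=False
    )
    payload = {
        "planted_de_genes": {c: dict(v) for c, v in truth.planted_de_genes.items()},
        "planted_de_mirnas": {c: dict(v) for c, v in truth.planted_de_mirnas.items()},
        "planted_shared_mirnas": sorted(truth.planted_shared_mirnas),
        "planted_drug_sign": {d: list(s) for d, s in truth.planted_drug_sign.items()},
        "planted_mirna_chemical": sorted(map(list, truth.planted_mirna_chemical)),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _write_edges(path: Path, edges, evidence: str) -> None:
    pd.DataFrame(edges, columns=["source", "target"]).assign(
        evidence=evidence
    ).to_csv(path, sep="\t", index=False)


def _write_gmt(path: Path, collection: Mapping[str, frozenset[str]]) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection):
            members = "\t".join(sorted(collection[term]))
            fh.write(f"{term}\tsynthetic\t{members}\n")


def write_annotations(ann: AnnotationBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_edges(outdir / "targets_validated.tsv", ann.validated_targets, "validated")
    _write_edges(outdir / "targets_predicted.tsv", ann.predicted_targets, "predicted")
    _write_gmt(outdir / "pathways.gmt", ann.pathways)
    _write_gmt(outdir / "bp.gmt", ann.bps)
    _write_edges(outdir / "ppi_edges.tsv", ann.ppi_edges, "ppi")
    _write_edges(outdir / "tf_edges.tsv", ann.tf_edges, "tf")
    chem_rows = [
        (c, g) for c in sorted(ann.chemical_genes)
        for g in sorted(ann.chemical_genes[c])
    ]
    _write_edges(outdir / "chemical_genes.tsv", chem_rows, "ctd")
    _write_edges(outdir / "mirna_chemical.tsv", ann.mirna_chemical, "ctd")
    rows = []
    for (drug, ctx) in sorted(ann.drug_signatures):
        for rank, feat in enumerate(ann.drug_signatures[(drug, ctx)], start=1):
            rows.append((drug, ctx, rank, feat))
    pd.DataFrame(rows, columns=["drug_id", "context", "rank", "feature_id"]).to_csv(
        outdir / "drug_signatures.tsv", sep="\t", index=False
    )


def read_study(indir: str | Path) -> tuple[StudyBundle, GroundTruth]:
    indir = Path(indir)
    design_df = pd.read_csv(indir / "design.tsv", sep="\t")
    contrasts = tuple(CONTEXT_GROUPS[c] for c in ("ctx1", "ctx2"))
    studies = {}
    for assay, label in (("mrna", "mRNA"), ("mirna", "miRNA")):
        mat = pd.read_csv(indir / f"expression_{assay}.tsv", sep="\t",
                          index_col="feature_id")
        rows = design_df[design_df["assay"] == label]
        design = dict(zip(rows["sample_id"], rows["group"]))
        studies[assay] = ExpressionStudy(matrix=mat, design=design,
                                         contrasts=contrasts)
    payload = json.loads((indir / "truth.json").read_text())
    truth = GroundTruth(
        planted_de_genes=payload["planted_de_genes"],
        planted_de_mirnas=payload["planted_de_mirnas"],
        planted_shared_mirnas=frozenset(payload["planted_shared_mirnas"]),
        planted_drug_sign={
            d: tuple(s) for d, s in payload["planted_drug_sign"].items()
        },
        planted_mirna_chemical=frozenset(
            (m, c) for m, c in payload["planted_mirna_chemical"]
        ),
    )
    return StudyBundle(mrna=studies["mrna"], mirna=studies["mirna"]), truth


def _read_gmt(path: Path) -> dict[str, frozenset[str]]:
    out = {}
    for line in path.read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 2:
            out[parts[0]] = frozenset(p for p in parts[2:] if p)
    return out


def read_annotations(indir: str | Path) -> AnnotationBundle:
    indir = Path(indir)

    def _edges(name):
        df = pd.read_csv(indir / name, sep="\t")
        return list(zip(df["source"], df["target"]))

    chem_df = pd.read_csv(indir / "chemical_genes.tsv", sep="\t")
    chem_genes: dict[str, set[str]] = {}
    for c, g in zip(chem_df["source"], chem_df["target"]):
        chem_genes.setdefault(c, set()).add(g)
    sig_df = pd.read_csv(indir / "drug_signatures.tsv", sep="\t")
    signatures: dict[tuple[str, str], tuple[str, ...]] = {}
    for (drug, ctx), grp in sig_df.groupby(["drug_id", "context"]):
        ordered = grp.sort_values("rank")["feature_id"]
        signatures[(drug, ctx)] = tuple(ordered)
    return AnnotationBundle(
        validated_targets=_edges("targets_validated.tsv"),
        predicted_targets=_edges("targets_predicted.tsv"),
        pathways=_read_gmt(indir / "pathways.gmt"),
        bps=_read_gmt(indir / "bp.gmt"),
        ppi_edges=_edges("ppi_edges.tsv"),
        tf_edges=_edges("tf_edges.tsv"),
        chemical_genes={c: frozenset(s) for c, s in chem_genes.items()},
        mirna_chemical=_edges("mirna_chemical.tsv"),
        drug_signatures=signatures,
    )
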