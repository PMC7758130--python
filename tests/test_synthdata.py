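"""Synthetic study generator: determinism, invariants, truth containment,
and recoverability of the planted structure."""

import numpy as np
import pandas as pd
import pytest

from mircrosstalk import diffexpr, synthdata
from mircrosstalk.connectivity import RankedSignature, TagSet, ks_statistic
from mircrosstalk.errors import ConfigError
from mircrosstalk.synthdata import SynthConfig, generate_annotations, generate_study


def test_seeded_determinism_bit_identical():
    cfg = SynthConfig(n_genes=120, n_mirnas=40, seed=42,
                      n_de_genes_ctx1=15, n_de_genes_ctx2=20,
                      n_shared_concordant_genes=4, n_shared_discordant_genes=1,
                      n_de_mirnas_ctx1=6, n_de_mirnas_ctx2=5, n_shared_mirnas=2)
    b1, t1 = generate_study(cfg)
    b2, t2 = generate_study(cfg)
    pd.testing.assert_frame_equal(b1.mrna.matrix, b2.mrna.matrix)
    pd.testing.assert_frame_equal(b1.mirna.matrix, b2.mirna.matrix)
    assert t1 == t2
    a1 = generate_annotations(cfg, t1)
    a2 = generate_annotations(cfg, t2)
    assert a1 == a2


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_shared_mirnas=10, n_de_mirnas_ctx1=4, n_de_mirnas_ctx2=6),
     dict(n_shared_concordant_genes=90, n_shared_discordant_genes=20,
          n_de_genes_ctx1=100, n_de_genes_ctx2=100),
     dict(noise_sd_log2=0.0),
     dict(n_genes=-5),
     dict(n_reps_per_group=1)],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SynthConfig(**kwargs)


def test_default_config_plants_three_shared_mirnas():
    _, truth = generate_study(SynthConfig(seed=0))
    assert len(truth.planted_shared_mirnas) == 3
    for ctx in ("ctx1", "ctx2"):
        assert truth.planted_shared_mirnas <= set(truth.planted_de_mirnas[ctx])


def test_planted_counts_and_shapes():
    cfg = SynthConfig(seed=2)
    bundle, truth = generate_study(cfg)
    assert bundle.mrna.matrix.shape == (cfg.n_genes, 4 * cfg.n_reps_per_group)
    assert bundle.mirna.matrix.shape == (cfg.n_mirnas, 4 * cfg.n_reps_per_group)
    assert len(truth.planted_de_genes["ctx1"]) == cfg.n_de_genes_ctx1
    assert len(truth.planted_de_genes["ctx2"]) == cfg.n_de_genes_ctx2
    assert len(truth.planted_de_mirnas["ctx1"]) == cfg.n_de_mirnas_ctx1
    assert len(truth.planted_de_mirnas["ctx2"]) == cfg.n_de_mirnas_ctx2
    # every planted feature exists in the generated matrices
    for ctx in ("ctx1", "ctx2"):
        assert set(truth.planted_de_genes[ctx]) <= set(bundle.mrna.matrix.index)
        assert set(truth.planted_de_mirnas[ctx]) <= set(bundle.mirna.matrix.index)


def test_planted_shift_has_configured_size_and_direction():
    cfg = SynthConfig(seed=4, noise_sd_log2=0.05)
    bundle, truth = generate_study(cfg)
    mat = bundle.mrna.matrix
    b_cols = [s for s, g in bundle.mrna.design.items() if g == "B"]
    a_cols = [s for s, g in bundle.mrna.design.items() if g == "A"]
    fc = mat[b_cols].mean(axis=1) - mat[a_cols].mean(axis=1)
    for gene, direction in truth.planted_de_genes["ctx1"].items():
        expected = 1.0 if direction == "up" else -1.0
        assert fc[gene] == pytest.approx(expected, abs=0.25)


def test_shared_discordant_genes_shift_opposite_ways():
    cfg = SynthConfig(seed=6)
    _, truth = generate_study(cfg)
    d1, d2 = truth.planted_de_genes["ctx1"], truth.planted_de_genes["ctx2"]
    shared = set(d1) & set(d2)
    n_disc = sum(d1[g] != d2[g] for g in shared)
    assert n_disc == cfg.n_shared_discordant_genes
    assert len(shared) == (cfg.n_shared_concordant_genes
                           + cfg.n_shared_discordant_genes)


def test_null_effect_gives_chance_level_calls():
    hits = total = called = 0
    for seed in range(1, 6):
        cfg = SynthConfig(effect_size_log2=0.0, seed=seed)
        bundle, _ = generate_study(cfg)
        tab = diffexpr.fit_contrast(bundle.mrna, ("B", "A"))
        hits += int((tab["P"] < 0.05).sum())
        called += int((tab["direction"] != "none").sum())
        total += len(tab)
    assert abs(hits / total - 0.05) < 2 * np.sqrt(0.05 * 0.95 / total)
    # with the fold-change gate on top, DE calls are no more than chance level
    assert called / total < 0.05


def test_effect_recovery_at_default_settings():
    """>=90% of planted features pass the P/logFC thresholds (20 seeds)."""
    hits = total = 0
    for seed in range(1, 21):
        cfg = SynthConfig(n_genes=400, n_mirnas=100, n_de_genes_ctx1=40,
                          n_de_genes_ctx2=50, n_shared_concordant_genes=8,
                          n_shared_discordant_genes=2, seed=seed)
        bundle, truth = generate_study(cfg)
        tab = diffexpr.fit_contrast(bundle.mrna, ("B", "A"))
        called = diffexpr.de_features(tab)
        for gene, direction in truth.planted_de_genes["ctx1"].items():
            total += 1
            hits += called.get(gene) == direction
    assert hits / total >= 0.90


def test_annotations_contain_planted_chemical_pairs(small_study_truth):
    _, _, truth, ann = small_study_truth
    emitted = set(ann.mirna_chemical)
    assert truth.planted_mirna_chemical <= emitted
    for mirna, chem in truth.planted_mirna_chemical:
        # the chemical's gene set overlaps the miRNA's targets by construction
        targets = {g for m, g in ann.validated_targets if m == mirna}
        targets |= {g for m, g in ann.predicted_targets if m == mirna}
        assert ann.chemical_genes[chem] & targets


def test_validated_and_predicted_targets_overlap(small_study_truth):
    _, _, _, ann = small_study_truth
    val = {}
    for m, g in ann.validated_targets:
        val.setdefault(m, set()).add(g)
    pred = {}
    for m, g in ann.predicted_targets:
        pred.setdefault(m, set()).add(g)
    for m in val:
        assert val[m] & pred.get(m, set())


def test_shared_mirnas_have_pathway_annotated_targets(small_study_truth):
    _, _, truth, ann = small_study_truth
    targets = {}
    for m, g in ann.validated_targets + ann.predicted_targets:
        targets.setdefault(m, set()).add(g)
    annotated = set().union(*ann.pathways.values())
    for m in truth.planted_shared_mirnas:
        assert targets[m] & annotated


def test_drug_signatures_respond_with_planted_sign(small_study_truth):
    """A (+,+) drug places up-tags near the top in both contexts (KS_up > 0)."""
    _, _, truth, ann = small_study_truth
    for drug, signs in truth.planted_drug_sign.items():
        for ctx, sign in zip(("ctx1", "ctx2"), signs):
            de = truth.planted_de_mirnas[ctx]
            up = frozenset(m for m, d in de.items() if d == "up")
            sig = RankedSignature(drug, ctx, ann.drug_signatures[(drug, ctx)])
            ks_up = ks_statistic(TagSet(up, "up"), sig).KS
            assert (ks_up > 0) == (sign > 0)


def test_file_roundtrip_preserves_study(tmp_path, small_study_truth):
    cfg, bundle, truth, ann = small_study_truth
    synthdata.write_study(bundle, truth, tmp_path)
    synthdata.write_annotations(ann, tmp_path)
    bundle2, truth2 = synthdata.read_study(tmp_path)
    ann2 = synthdata.read_annotations(tmp_path)
    pd.testing.assert_frame_equal(bundle.mrna.matrix, bundle2.mrna.matrix)
    assert truth2.planted_shared_mirnas == truth.planted_shared_mirnas
    assert dict(truth2.planted_de_genes["ctx1"]) == dict(
        truth.planted_de_genes["ctx1"])
    assert sorted(ann2.validated_targets) == sorted(ann.validated_targets)
    assert ann2.pathways == ann.pathways
    assert ann2.drug_signatures == ann.drug_signatures
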