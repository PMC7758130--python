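"""KS connectivity scoring against ranked signatures and the drug screen."""

from itertools import combinations

import pytest

from mircrosstalk import synthdata
from mircrosstalk.connectivity import (
    ConnectivityResult,
    RankedSignature,
    TagSet,
    classify_concordance,
    connectivity_score,
    integrate_s,
    ks_statistic,
    screen_drugs,
)
from mircrosstalk.errors import InputError
from oracles import bf_ks


def _sig(features, drug="d", ctx="ctx1"):
    return RankedSignature(drug, ctx, tuple(features))


def test_top_clustered_tags_hand_value():
    res = ks_statistic(TagSet(frozenset({"g1", "g2"})), _sig(["g1", "g2", "g3", "g4"]))
    assert res.tag_positions == (1, 2)
    assert res.a == pytest.approx(0.5)
    assert res.b == pytest.approx(0.25)
    assert res.KS == pytest.approx(0.5)


def test_bottom_clustered_tags_hand_value():
    res = ks_statistic(TagSet(frozenset({"g3", "g4"})), _sig(["g1", "g2", "g3", "g4"]))
    assert res.a == pytest.approx(0.0)
    assert res.b == pytest.approx(0.75)
    assert res.KS == pytest.approx(-0.75)


def test_tag_errors():
    sig = _sig(["g1", "g2", "g3"])
    with pytest.raises(InputError):
        ks_statistic(TagSet(frozenset({"gX"})), sig)
    with pytest.raises(InputError):
        TagSet(frozenset())


def test_single_tag_closed_form():
    """For t=1 the statistic reduces to a closed form in V(1)."""
    feats = [f"g{i}" for i in range(1, 11)]
    sig = _sig(feats)
    n = 10
    for v in range(1, n + 1):
        res = ks_statistic(TagSet(frozenset({feats[v - 1]})), sig)
        a = 1 - v / n
        b = v / n
        expected = a if a > b else (-b if b > a else a)
        assert res.KS == pytest.approx(expected)


def test_exhaustive_oracle_all_subsets_up_to_n8():
    """ks_statistic equals the literal max-scan oracle for every tag subset."""
    for n in range(2, 9):
        feats = [f"g{i}" for i in range(n)]
        sig = _sig(feats)
        for t in range(1, n + 1):
            for combo in combinations(range(1, n + 1), t):
                res = ks_statistic(
                    TagSet(frozenset(feats[i - 1] for i in combo)), sig
                )
                a, b, ks = bf_ks(list(combo), n)
                assert res.a == pytest.approx(a)
                assert res.b == pytest.approx(b)
                assert res.KS == pytest.approx(ks)
                assert -1.0 <= res.KS <= 1.0


def test_integrated_s_branch_rules():
    assert integrate_s(0.5, -0.75) == pytest.approx(1.25)
    assert integrate_s(0.5, 0.3) == 0.0
    assert integrate_s(-0.2, -0.6) == 0.0
    assert integrate_s(0.0, -0.4) == pytest.approx(0.4)


def test_connectivity_score_combines_hand_values():
    sig = _sig(["g1", "g2", "g3", "g4"])
    res = connectivity_score(TagSet(frozenset({"g1", "g2"}), "up"),
                             TagSet(frozenset({"g3", "g4"}), "down"), sig)
    assert res.S == pytest.approx(1.25)
    assert res.S_norm == pytest.approx(0.625)


def test_overlapping_tag_sets_rejected():
    sig = _sig(["g1", "g2", "g3", "g4"])
    with pytest.raises(InputError):
        connectivity_score(TagSet(frozenset({"g1"}), "up"),
                           TagSet(frozenset({"g1", "g4"}), "down"), sig)


def test_shift_sanity_top_positive_bottom_negative():
    feats = [f"g{i}" for i in range(50)]
    sig = _sig(feats)
    top = ks_statistic(TagSet(frozenset(feats[:5])), sig)
    bottom = ks_statistic(TagSet(frozenset(feats[-5:])), sig)
    assert top.KS > 0 > bottom.KS


@pytest.mark.parametrize(
    "s1,s2,expected",
    [(-0.677, -0.672, "concordant"), (0.633, 0.776, "concordant"),
     (0.748, -0.693, "discordant"), (0.0, 0.5, "null")],
)
def test_concordance_classification(s1, s2, expected):
    assert classify_concordance(s1, s2) == expected


def test_screen_excludes_drug_missing_a_context():
    feats = [f"g{i}" for i in range(8)]
    tags = {
        "ctx1": (TagSet(frozenset(feats[:2]), "up"),
                 TagSet(frozenset(feats[-2:]), "down")),
        "ctx2": (TagSet(frozenset(feats[:2]), "up"),
                 TagSet(frozenset(feats[-2:]), "down")),
    }
    sigs = [_sig(feats, "d1", "ctx1"), _sig(feats, "d1", "ctx2"),
            _sig(feats, "d2", "ctx1")]
    out = screen_drugs(tags, sigs)
    assert list(out["drug"]) == ["d1"]
    assert out["concordance"].iloc[0] == "concordant"


def test_planted_drug_sign_recovery():
    """On synthetic drugs, sign(S_norm) matches the planted sign in >=95% of
    (drug, context) pairs across seeds."""
    good = total = 0
    for seed in range(1, 21):
        cfg = synthdata.SynthConfig(n_genes=200, n_mirnas=120, n_drugs=8,
                                    n_de_genes_ctx1=30, n_de_genes_ctx2=40,
                                    n_shared_concordant_genes=8,
                                    n_shared_discordant_genes=2, seed=seed)
        _, truth = synthdata.generate_study(cfg)
        ann = synthdata.generate_annotations(cfg, truth)
        for ctx in ("ctx1", "ctx2"):
            de = truth.planted_de_mirnas[ctx]
            up = TagSet(frozenset(m for m, d in de.items() if d == "up"), "up")
            down = TagSet(frozenset(m for m, d in de.items() if d == "down"),
                          "down")
            for drug, signs in truth.planted_drug_sign.items():
                sign = signs[0] if ctx == "ctx1" else signs[1]
                sig = RankedSignature(drug, ctx, ann.drug_signatures[(drug, ctx)])
                res = connectivity_score(up, down, sig)
                total += 1
                good += (res.S_norm > 0) == (sign > 0) and res.S_norm != 0
    assert good / total >= 0.95
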