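"""EVcomplex transforms, residue/protein models, calibration, restraints."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from evpair.errors import TrainingError
from evpair.evscores import (
    INTERACTION_FEATURES,
    LogisticModel,
    build_residue_features,
    calibrate_threshold,
    diagonal_artifact_check,
    evcomplex_transform,
    export_restraints,
    intra_enrichment,
    relative_rank,
    relative_ranks,
    score_protein_interaction,
    train_interaction_model,
    train_residue_model,
)
from evpair.plm import build_ec_table
from evpair.synth import bayes_auc, make_feature_fixture, make_logistic_fixture


def toy_table(L1=8, L2=8, n_eff=64.0, seed=0):
    rng = np.random.default_rng(seed)
    L = L1 + L2
    S = rng.normal(size=(L, L))
    S = (S + S.T) / 2
    return build_ec_table(S, L1, L2, n_eff=n_eff)


# ---------------------------------------------------------------------------
# EVcomplex transform
# ---------------------------------------------------------------------------

def test_minimum_inter_ec_maps_to_minus_one():
    table = evcomplex_transform(toy_table())
    inter = table[table["is_inter"]]
    assert inter["evcomplex_raw"].min() == pytest.approx(-1.0)


def test_evcomplex_scale_invariance():
    table = toy_table()
    doubled = table.copy()
    attrs = dict(table.attrs)
    doubled["cn"] = 2 * doubled["cn"]
    doubled.attrs.update(attrs)
    a = evcomplex_transform(table)["evcomplex_raw"]
    b = evcomplex_transform(doubled)["evcomplex_raw"]
    assert np.allclose(a, b)


def test_evcomplex_hand_values():
    # 4 inter rows with cn -2, -1, 1, 3 -> raw -1, -0.5, 0.5, 1.5
    table = build_ec_table(np.zeros((4, 4)), 2, 2, n_eff=4.0)
    inter_idx = table.index[table["is_inter"]]
    table.loc[inter_idx, "cn"] = [-2.0, -1.0, 1.0, 3.0]
    out = evcomplex_transform(table)
    raw = out.loc[inter_idx, "evcomplex_raw"].tolist()
    assert raw == pytest.approx([-1.0, -0.5, 0.5, 1.5])
    # N_eff/L = 1 here, so score equals raw
    assert out.loc[inter_idx, "evcomplex_score"].tolist() == pytest.approx(raw)


def test_evcomplex_shallow_alignment_shrunk():
    table = toy_table(n_eff=4.0)  # N_eff/L = 0.25 -> g = 0.5
    out = evcomplex_transform(table)
    assert np.allclose(out["evcomplex_score"], out["evcomplex_raw"] * 0.5)


# ---------------------------------------------------------------------------
# Enrichment and relative rank
# ---------------------------------------------------------------------------

def test_enrichment_uniform_regular_graph():
    # ring of intra pairs in segment A with equal cn: every touched residue
    # has the same summed score -> enrichment exactly 1
    L1 = L2 = 12
    S = np.zeros((24, 24))
    ring = [(i, (i + 6) % 12) for i in range(12)]
    for i, j in ring:
        a, b = min(i, j), max(i, j)
        S[a, b] = S[b, a] = 1.0
    table = build_ec_table(S, L1, L2, n_eff=24.0)
    enr = intra_enrichment(table, top_n=6)  # the six ring pairs
    touched = enr > 0
    assert touched.sum() == 12
    assert np.allclose(enr[touched], 1.0)


def test_enrichment_hub_residue_maximal():
    L1, L2 = 10, 10
    S = np.zeros((20, 20))
    for j in range(6, 10):  # residue 0 in every strong intra pair
        S[0, j] = S[j, 0] = 5.0
    S[2, 8] = S[8, 2] = 1.0
    table = build_ec_table(S, L1, L2, n_eff=20.0)
    enr = intra_enrichment(table)
    assert enr.argmax() == 0


def brute_enrichment(table, top_n):
    L = table.attrs["L1"] + table.attrs["L2"]
    intra = table[~table["is_inter"]].sort_values("rank").head(top_n)
    sums = {}
    for _, r in intra.iterrows():
        for p in (int(r["i"]) - 1, int(r["j"]) - 1):
            sums[p] = sums.get(p, 0.0) + r["cn"]
    mean = np.mean(list(sums.values()))
    out = np.zeros(L)
    for p, s in sums.items():
        out[p] = s / mean
    return out


def test_enrichment_matches_brute_force():
    table = toy_table(seed=3)
    assert np.allclose(intra_enrichment(table, top_n=20), brute_enrichment(table, 20))


def test_relative_rank_extremes_and_middle():
    table = toy_table(seed=4)
    rel = relative_ranks(table)
    n = len(table)
    top = table["cn"].to_numpy().argmax()
    assert rel[top] == pytest.approx(1 / n)
    bottom = table["cn"].to_numpy().argmin()
    assert rel[bottom] == pytest.approx(1.0)
    # brute-force count for an arbitrary middle row
    k = 17
    cn = table["cn"].to_numpy()
    expected = (np.sum(cn > cn[k]) + 1) / n
    assert relative_rank(table, k) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Residue features
# ---------------------------------------------------------------------------

def test_residue_feature_construction():
    table = toy_table(L1=10, L2=10, seed=5)
    L = 20
    cons = np.linspace(0, 1, L)
    enr = np.linspace(2, 0, L)
    labels = {}
    inter = table[table["is_inter"]].nsmallest(10, "rank")
    for k, (_, r) in enumerate(inter.iterrows()):
        labels[(int(r["i"]), int(r["j"]))] = None if k == 3 else (k % 2 == 0)
    rows = build_residue_features(table, cons, enr, labels=labels)
    assert len(rows) == 10
    assert (rows["padded"] == 0).all()
    # ordered by cn descending
    assert (rows["cn"].diff().dropna() <= 1e-12).all()
    for _, r in rows.iterrows():
        i, j = int(r["i"]), int(r["j"])
        assert r["conservation_max"] == pytest.approx(max(cons[i - 1], cons[j - 1]))
        assert r["enrichment_max"] == pytest.approx(max(enr[i - 1], enr[j - 1]))
    # unknown-distance row keeps a missing label
    assert rows["label"].isna().sum() == 1
    # structure-free mode leaves structure features missing
    assert rows["rsa_min"].isna().all()


def test_residue_feature_padding():
    S = np.zeros((6, 6))
    S[1, 5] = S[5, 1] = -1.0  # a negative minimum inter EC for the transform
    table = build_ec_table(S, 4, 2, n_eff=6.0)
    n_inter = int(table["is_inter"].sum())
    assert n_inter < 10
    rows = build_residue_features(table, np.zeros(6), np.zeros(6))
    assert len(rows) == 10
    assert rows["padded"].sum() == 10 - n_inter


# ---------------------------------------------------------------------------
# Residue model
# ---------------------------------------------------------------------------

def test_separable_features_fit():
    rng = np.random.default_rng(0)
    n = 200
    df = pd.DataFrame(
        {
            "evcomplex_score": np.concatenate([rng.uniform(1, 2, n), rng.uniform(-2, -1, n)]),
            "conservation_max": rng.uniform(0, 1, 2 * n),
            "inter_relative_rank": rng.uniform(0, 1, 2 * n),
            "enrichment_max": rng.uniform(0, 2, 2 * n),
            "label": [1.0] * n + [0.0] * n,
        }
    )
    model = train_residue_model(df, seed=1)
    acc = ((model.predict_proba(df) > 0.5) == df["label"]).mean()
    assert acc >= 0.99


def test_planted_weight_recovery():
    w_true = np.array([1.0, -0.7, 0.5, 0.0])
    df = make_logistic_fixture(5000, w_true, bias=0.3, seed=2)
    model = train_residue_model(
        df, features=[f"f{k}" for k in range(4)], penalty="l2", reg_weight=1.0, seed=0
    )
    assert np.all(np.abs(model.weights - w_true) <= 0.15)


def test_permuted_labels_near_chance():
    rng = np.random.default_rng(3)
    w_true = np.array([1.0, -0.7, 0.5, 0.0])
    df = make_logistic_fixture(1000, w_true, seed=4)
    df["label"] = rng.permutation(df["label"].to_numpy())
    model = train_residue_model(df, features=[f"f{k}" for k in range(4)], seed=0)
    probs = model.predict_proba(df)
    auc = roc_auc_score(df["label"], probs)
    assert 0.4 < auc < 0.6


def test_single_class_raises():
    df = make_logistic_fixture(50, [1.0], seed=0)
    df["label"] = 1.0
    with pytest.raises(TrainingError):
        train_residue_model(df, features=["f0"])


def test_training_reproducible():
    df = make_logistic_fixture(500, [0.8, -0.4], seed=5)
    m1 = train_residue_model(df, features=["f0", "f1"], seed=7)
    m2 = train_residue_model(df, features=["f0", "f1"], seed=7)
    assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias


def test_model_json_roundtrip(tmp_path):
    df = make_logistic_fixture(300, [0.5, 0.5], seed=6)
    model = train_residue_model(df, features=["f0", "f1"], seed=0)
    p = tmp_path / "model.json"
    model.save(p)
    loaded = LogisticModel.load(p)
    assert loaded.feature_names == model.feature_names
    assert np.allclose(loaded.weights, model.weights)
    x = df[["f0", "f1"]].to_numpy()
    assert np.allclose(loaded.predict_proba(x), model.predict_proba(x))


# ---------------------------------------------------------------------------
# Interaction model
# ---------------------------------------------------------------------------

def test_interaction_monotone_in_residue_probs():
    w = np.concatenate([np.full(10, 0.5), [-1.0]])
    model = LogisticModel(INTERACTION_FEATURES, w, bias=-2.0, penalty="l2", reg_weight=1.0)
    low = score_protein_interaction(np.zeros(10), 1.0, model)
    mid = score_protein_interaction(np.full(10, 0.5), 0.5, model)
    high = score_protein_interaction(np.ones(10), 1e-3, model)
    assert low.probability < mid.probability < high.probability
    assert low.probability < 0.2 and high.probability > 0.8


def test_interaction_l1_selection_drops_noise():
    rng = np.random.default_rng(0)
    n = 322  # class size of the training protocol
    pos = pd.DataFrame(rng.normal(0, 1, (n, 11)), columns=INTERACTION_FEATURES)
    neg = pd.DataFrame(rng.normal(0, 1, (n, 11)), columns=INTERACTION_FEATURES)
    pos["residue_prob_1"] += 2.5  # the single informative feature
    model = train_interaction_model(pos, neg, seed=0)
    assert "residue_prob_1" in model.feature_names
    assert len(model.feature_names) <= 4, "noise features should be pruned by L1"


def test_interaction_duplicate_features_no_crash():
    rng = np.random.default_rng(1)
    n = 300
    base = rng.normal(0, 1, n)
    cols = {f: base.copy() for f in INTERACTION_FEATURES}
    pos = pd.DataFrame(cols)
    pos += rng.normal(0, 0.01, pos.shape)
    neg = pos - 1.5
    model = train_interaction_model(pos, neg, seed=0)
    assert len(model.feature_names) >= 1


def test_interaction_heldout_auc_near_bayes():
    sep = 1.5
    feats = [f"f{k}" for k in range(5)]
    train = make_feature_fixture(800, 800, sep, seed=10)
    test = make_feature_fixture(1500, 1500, sep, seed=11)
    model = train_interaction_model(
        train[train["label"] == 1], train[train["label"] == 0], features=feats, seed=0
    )
    probs = model.predict_proba(test)
    auc = roc_auc_score(test["label"], probs)
    assert abs(auc - bayes_auc(sep)) <= 0.05


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def brute_force_calibration(scores, labels, mode, target):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    feasible = []
    for t in np.unique(s):
        pred = s >= t
        tp = (pred & y).sum()
        fp = (pred & ~y).sum()
        if mode == "precision":
            ok = tp + fp > 0 and tp / (tp + fp) >= target
        else:
            ok = fp / (~y).sum() <= target
        if ok:
            feasible.append(t)
    return min(feasible) if feasible else None


def test_separated_classes_midpoint():
    scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
    labels = [0, 0, 0, 1, 1, 1]
    res = calibrate_threshold(scores, labels, "precision", 1.0)
    assert res.attained and res.threshold == pytest.approx(0.5)


def test_hand_precision_set():
    scores = [0.9, 0.85, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
    labels = [1, 1, 0, 1, 1, 0, 0, 1, 0, 0]
    res = calibrate_threshold(scores, labels, "precision", 0.8)
    cut = brute_force_calibration(scores, labels, "precision", 0.8)
    # chosen cut is 0.6 (4 of 5 above are true); returned midpoint to 0.5
    assert cut == pytest.approx(0.6)
    assert res.threshold == pytest.approx(0.55)
    assert res.achieved == pytest.approx(0.8)


@pytest.mark.parametrize("mode,target", [("precision", 0.75), ("fpr", 0.2)])
def test_calibration_matches_enumeration(mode, target):
    rng = np.random.default_rng(12)
    scores = rng.normal(size=500)
    labels = rng.random(500) < 1 / (1 + np.exp(-scores))
    res = calibrate_threshold(scores, labels, mode, target)
    cut = brute_force_calibration(scores, labels, mode, target)
    if cut is None:
        assert not res.attained
    else:
        below = scores[scores < cut]
        expected = (cut + below.max()) / 2 if len(below) else cut
        assert res.threshold == pytest.approx(expected)


def test_fpr_zero_unattainable_with_overlap():
    scores = [0.9, 0.8, 0.7, 0.6]
    labels = [0, 1, 0, 1]  # the top score is a negative
    res = calibrate_threshold(scores, labels, "fpr", 0.0)
    assert not res.attained
    assert res.achieved > 0


# ---------------------------------------------------------------------------
# Diagonal artifact and restraints
# ---------------------------------------------------------------------------

def _table_with_inter_cn(L1, L2, pairs_cn):
    """pairs_cn: {(pos_a, pos_b 1-based segment-local): cn}."""
    S = np.zeros((L1 + L2, L1 + L2))
    for (a, b), v in pairs_cn.items():
        i, j = a - 1, L1 + b - 1
        S[i, j] = S[j, i] = v
    return build_ec_table(S, L1, L2, n_eff=float(L1 + L2))


def test_diagonal_artifact_detected():
    pairs = {(k, k): 10.0 - 0.1 * k for k in range(1, 11)}
    table = _table_with_inter_cn(20, 20, pairs)
    assert diagonal_artifact_check(table)


def test_diagonal_boundary_five_of_ten():
    pairs = {(k, k): 10.0 for k in range(1, 6)}
    pairs.update({(k, k + 10): 9.0 for k in range(1, 6)})
    table = _table_with_inter_cn(20, 20, pairs)
    assert diagonal_artifact_check(table)
    # 4 of 10 on the diagonal is below the flag fraction
    pairs = {(k, k): 10.0 for k in range(1, 5)}
    pairs.update({(k, k + 10): 9.0 for k in range(1, 7)})
    table = _table_with_inter_cn(20, 20, pairs)
    assert not diagonal_artifact_check(table)


def test_diagonal_false_flag_rate_on_random_tables():
    flags = 0
    trials = 200
    rng = np.random.default_rng(0)
    for _ in range(trials):
        pos = rng.choice(100, size=10, replace=False) + 1
        pos2 = rng.choice(100, size=10, replace=False) + 1
        pairs = {(int(a), int(b)): float(10 + rng.random()) for a, b in zip(pos, pos2)}
        table = _table_with_inter_cn(100, 100, pairs)
        flags += diagonal_artifact_check(table)
    assert flags / trials < 0.01


def _residue_map(L1, L2, gly_positions=()):
    out = {}
    for p in range(1, L1 + 1):
        out[p] = ("A", 100 + p, "G" if p in gly_positions else "L")
    for p in range(L1 + 1, L1 + L2 + 1):
        out[p] = ("B", 200 + p, "G" if p in gly_positions else "K")
    return out


def test_restraints_union_and_atoms():
    pairs = {(k, k + 2): 10.0 - k for k in range(1, 9)}
    table = _table_with_inter_cn(12, 12, pairs)
    inter = table[table["is_inter"]].nsmallest(len(table), "rank")
    cn = inter["cn"].to_numpy()
    rmap = _residue_map(12, 12, gly_positions={1})
    # identical top-5 under both modes -> exactly 5 lines
    text, skipped = export_restraints(table, {"m1": cn, "m2": cn}, rmap)
    lines = [l for l in text.splitlines() if l]
    assert len(lines) == 5 and skipped == 0
    # glycine residue gets CA, others CB
    gly_lines = [l for l in lines if "resid 101" in l]
    assert gly_lines and "name CA" in gly_lines[0]
    assert all("name CB" in l.split("resid 101")[-1] for l in gly_lines)
    # disjoint top-5 sets -> 10 lines
    text2, _ = export_restraints(table, {"m1": cn, "m2": -cn}, rmap)
    assert len([l for l in text2.splitlines() if l]) == 10
    assert all(l.startswith("assign (segid") for l in lines)
    assert all(l.endswith("5.0 2.0 2.0") for l in lines)


def test_restraints_unmappable_skipped():
    pairs = {(k, k + 2): 10.0 - k for k in range(1, 7)}
    table = _table_with_inter_cn(12, 12, pairs)
    inter = table[table["is_inter"]].nsmallest(len(table), "rank")
    rmap = _residue_map(12, 12)
    del rmap[1]  # first pair's A-side residue unmappable
    text, skipped = export_restraints(table, {"m": inter["cn"].to_numpy()}, rmap)
    assert skipped == 1
    assert len([l for l in text.splitlines() if l]) == 4
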