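"""Interaction scoring on top of ranked evolutionary couplings.

Raw corrected-norm (CN) couplings are turned into comparable scores in
two steps: the EVcomplex normalization (divide every inter-protein EC by
the magnitude of the most negative inter-protein EC, then shrink scores
from shallow alignments by a function of N_eff/L), and logistic models
that combine the coupling score with residue-level features.

Two residue-contact models are supported: a structure-free model
(EVcomplex score, conservation of the more conserved residue, relative
rank of the inter EC, maximum intra-EC enrichment of the two residues)
and a structure-aware model adding the minimum relative solvent
accessibility of the pair and the precision of higher-ranked ECs.  A
protein-level model consumes the ten residue-contact probabilities of the
top inter ECs plus the relative rank of the best inter EC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .errors import ConfigurationError, DegenerateInputError, ParameterError, TrainingError

STRUCTURE_FREE_FEATURES = [
    "evcomplex_score",
    "conservation_max",
    "inter_relative_rank",
    "enrichment_max",
]
STRUCTURE_AWARE_FEATURES = STRUCTURE_FREE_FEATURES + ["rsa_min", "precision_above"]

#: number of top inter-protein ECs fed to the residue and protein models
N_TOP_INTER = 10
#: number of top restraint pairs exported per scoring mode
N_TOP_RESTRAINTS = 5


def neff_normalization(neff_over_l: float) -> float:
    """Diversity shrink g(x) = min(1, sqrt(x)) applied to EVcomplex raw
    scores: deep alignments (N_eff/L >= 1) keep their raw score, shallow
    ones are shrunk toward zero."""
    return float(min(1.0, np.sqrt(max(neff_over_l, 0.0))))


def evcomplex_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``evcomplex_raw`` and ``evcomplex_score`` columns.

    raw = cn / |min inter cn| (the most negative inter EC maps to -1);
    score = raw * g(N_eff / L).  A zero minimum leaves the columns NaN
    (division degenerate).
    """
    if "n_eff" not in table.attrs:
        raise ParameterError("EC table lacks n_eff metadata")
    inter = table[table["is_inter"]]
    if len(inter) == 0:
        raise DegenerateInputError("no inter-protein ECs")
    attrs = dict(table.attrs)
    out = table.copy()
    mmin = float(inter["cn"].min())
    if mmin == 0.0:
        out["evcomplex_raw"] = np.nan
        out["evcomplex_score"] = np.nan
        out.attrs.update(attrs, division_degenerate=True)
        return out
    L = attrs["L1"] + attrs["L2"]
    g = neff_normalization(attrs["n_eff"] / L)
    out["evcomplex_raw"] = out["cn"] / abs(mmin)
    out["evcomplex_score"] = out["evcomplex_raw"] * g
    out.attrs.update(attrs, neff_correction=g)
    return out


def intra_enrichment(table: pd.DataFrame, top_n: int | None = None) -> np.ndarray:
    """Per-residue intra-protein coupling enrichment.

    Sum of CN over the ``top_n`` highest-ranked intra rows touching each
    residue, normalized by the mean of that sum over the residues that
    appear in those rows; untouched residues get 0.  ``top_n`` defaults to
    the total concatenated length.
    """
    L = table.attrs["L1"] + table.attrs["L2"]
    if top_n is None:
        top_n = L
    intra = table[~table["is_inter"]].nsmallest(top_n, "rank")
    if len(intra) == 0:
        raise ParameterError("no intra-protein ECs")
    sums = np.zeros(L)
    np.add.at(sums, intra["i"].to_numpy() - 1, intra["cn"].to_numpy())
    np.add.at(sums, intra["j"].to_numpy() - 1, intra["cn"].to_numpy())
    touched = np.zeros(L, dtype=bool)
    touched[intra["i"].to_numpy() - 1] = True
    touched[intra["j"].to_numpy() - 1] = True
    mean = sums[touched].mean()
    if mean == 0:
        return np.zeros(L)
    enrich = np.where(touched, sums / mean, 0.0)
    return enrich


def relative_ranks(table: pd.DataFrame) -> np.ndarray:
    """(strictly-better count + 1) / total rows, for every row, against
    the pooled intra+inter score distribution."""
    cn = table["cn"].to_numpy()
    order = np.sort(cn)[::-1]
    greater = np.searchsorted(-order, -cn, side="left")
    return (greater + 1) / len(cn)


def relative_rank(table: pd.DataFrame, row_position: int) -> float:
    """Relative rank of one row (positional index into the table)."""
    return float(relative_ranks(table)[row_position])


def build_residue_features(
    table: pd.DataFrame,
    conservation: np.ndarray,
    enrichment: np.ndarray | None = None,
    rsa: np.ndarray | None = None,
    intra_contact_status: dict[tuple[int, int], bool] | None = None,
    labels: dict[tuple[int, int], bool | None] | None = None,
    n_top: int = N_TOP_INTER,
) -> pd.DataFrame:
    """Feature rows for the ``n_top`` highest-scoring inter-protein ECs.

    ``conservation``/``enrichment``/``rsa`` are per-position arrays over
    the concatenated coordinate (0-based); ``intra_contact_status`` maps
    intra pairs (1-based (i, j)) to contact truth for the precision-above
    feature; ``labels`` maps inter pairs to contact truth (None = residue
    unresolved in every structure).  When fewer than ``n_top`` inter rows
    exist, the table is padded with zero rows flagged ``padded = 1``.
    """
    if "evcomplex_score" not in table.columns:
        table = evcomplex_transform(table)
    inter = table[table["is_inter"]]
    if len(inter) == 0:
        raise DegenerateInputError("no inter-protein ECs to featurize")
    rel = relative_ranks(table)
    top = inter.nsmallest(n_top, "rank")

    # running precision of higher-ranked intra ECs with known contact truth
    rows = []
    for pos_idx, row in top.iterrows():
        i, j = int(row["i"]), int(row["j"])
        rec = {
            "i": i,
            "j": j,
            "cn": row["cn"],
            "evcomplex_raw": row["evcomplex_raw"],
            "evcomplex_score": row["evcomplex_score"],
            "conservation_max": float(np.nanmax([conservation[i - 1], conservation[j - 1]])),
            "inter_relative_rank": float(rel[table.index.get_loc(pos_idx)]),
            "enrichment_max": (
                float(max(enrichment[i - 1], enrichment[j - 1]))
                if enrichment is not None
                else np.nan
            ),
            "rsa_min": (
                float(np.fmin(rsa[i - 1], rsa[j - 1])) if rsa is not None else np.nan
            ),
            "padded": 0,
        }
        if intra_contact_status is not None:
            above = table[(table["rank"] < row["rank"]) & (~table["is_inter"])]
            known = [
                intra_contact_status[(int(a), int(b))]
                for a, b in zip(above["i"], above["j"])
                if (int(a), int(b)) in intra_contact_status
            ]
            rec["precision_above"] = float(np.mean(known)) if known else np.nan
        else:
            rec["precision_above"] = np.nan
        if labels is not None:
            lab = labels.get((i, j))
            rec["label"] = np.nan if lab is None else float(lab)
        else:
            rec["label"] = np.nan
        rows.append(rec)

    while len(rows) < n_top:
        rows.append(
            {
                "i": 0, "j": 0, "cn": 0.0, "evcomplex_raw": 0.0, "evcomplex_score": 0.0,
                "conservation_max": 0.0, "inter_relative_rank": 1.0, "enrichment_max": 0.0,
                "rsa_min": np.nan, "precision_above": np.nan, "padded": 1, "label": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic models
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """A serializable penalized logistic regression."""

    feature_names: list[str]
    weights: np.ndarray
    bias: float
    penalty: str
    reg_weight: float
    seed: int | None = None
    folds: int | None = None
    cv_precision: float | None = None
    cv_recall: float | None = None
    residue_threshold: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = X @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "weights": [float(w) for w in self.weights],
                "bias": float(self.bias),
                "penalty": self.penalty,
                "reg_weight": self.reg_weight,
                "seed": self.seed,
                "folds": self.folds,
                "cv_precision": self.cv_precision,
                "cv_recall": self.cv_recall,
                "residue_threshold": self.residue_threshold,
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")


def train_residue_model(
    rows: pd.DataFrame,
    features: list[str] | None = None,
    penalty: str = "l1",
    reg_weight: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> LogisticModel:
    """Fit the residue-contact logistic model.

    ``reg_weight`` is scikit-learn's C (liblinear solver).  Rows with an
    unknown label are excluded; cross-validated precision/recall are
    recorded on the model.
    """
    features = features or STRUCTURE_FREE_FEATURES
    data = rows.dropna(subset=[label_col] + features)
    X = data[features].to_numpy(dtype=float)
    y = data[label_col].to_numpy(dtype=float).astype(int)
    _check_two_classes(y)

    clf = LogisticRegression(
        C=reg_weight, solver="liblinear", l1_ratio=1.0 if penalty == "l1" else 0.0,
        random_state=seed, max_iter=2000,
    )
    n_folds = min(folds, int(np.bincount(y).min()))
    cv_prec = cv_rec = None
    if n_folds >= 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(clf, X, y, cv=cv)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        cv_prec = tp / (tp + fp) if tp + fp else float("nan")
        cv_rec = tp / (tp + fn) if tp + fn else float("nan")
    clf.fit(X, y)
    return LogisticModel(
        feature_names=list(features),
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        penalty=penalty,
        reg_weight=reg_weight,
        seed=seed,
        folds=n_folds,
        cv_precision=cv_prec,
        cv_recall=cv_rec,
    )


INTERACTION_FEATURES = [f"residue_prob_{k}" for k in range(1, N_TOP_INTER + 1)] + ["top_rank"]


def interaction_feature_vector(residue_probs, top_rank: float) -> np.ndarray:
    """Pad/truncate the residue probabilities to ten and append the
    relative rank of the best inter EC (11 features)."""
    probs = list(np.asarray(residue_probs, dtype=float)[:N_TOP_INTER])
    probs += [0.0] * (N_TOP_INTER - len(probs))
    return np.array(probs + [float(top_rank)])


@dataclass
class InteractionScore:
    pair_id: str
    residue_probs: np.ndarray
    top_rank: float
    probability: float
    n_calls: int | None = None


def score_protein_interaction(
    residue_probs, top_rank: float, model: LogisticModel, pair_id: str = ""
) -> InteractionScore:
    """Protein-level interaction probability from the per-residue contact
    probabilities of the top inter ECs and the best inter EC's relative
    rank.  ``n_calls`` counts residue probabilities above the model's
    stored residue threshold, when one was calibrated."""
    if model is None:
        raise ConfigurationError("no interaction model supplied")
    x = interaction_feature_vector(residue_probs, top_rank)
    prob = float(model.predict_proba(x[None, :])[0])
    n_calls = None
    if model.residue_threshold is not None:
        n_calls = int(np.sum(np.asarray(residue_probs, dtype=float) >= model.residue_threshold))
    return InteractionScore(
        pair_id=pair_id,
        residue_probs=np.asarray(residue_probs, dtype=float),
        top_rank=float(top_rank),
        probability=prob,
        n_calls=n_calls,
    )


def train_interaction_model(
    pos: pd.DataFrame,
    neg: pd.DataFrame,
    features: list[str] | None = None,
    select_reg_weight: float = 0.1,
    final_reg_weight: float = 1.0,
    seed: int = 0,
) -> LogisticModel:
    """Two-stage fit of the protein-interaction model.

    Classes are balanced by sampling the larger set down without
    replacement under ``seed``.  Stage 1 fits an L1 model (C =
    ``select_reg_weight``) and drops zero-weight features; stage 2 refits
    the survivors with L2.
    """
    features = features or INTERACTION_FEATURES
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))
    if n < 1:
        raise TrainingError("both classes must be nonempty")
    pos_idx = rng.choice(len(pos), size=n, replace=False) if len(pos) > n else np.arange(n)
    neg_idx = rng.choice(len(neg), size=n, replace=False) if len(neg) > n else np.arange(n)
    X = np.vstack(
        [pos.iloc[pos_idx][features].to_numpy(float), neg.iloc[neg_idx][features].to_numpy(float)]
    )
    y = np.concatenate([np.ones(n), np.zeros(n)]).astype(int)

    l1 = LogisticRegression(
        C=select_reg_weight, solver="liblinear", l1_ratio=1.0, random_state=seed, max_iter=2000
    ).fit(X, y)
    survivors = [f for f, w in zip(features, l1.coef_.ravel()) if w != 0.0]
    if not survivors:
        raise TrainingError("L1 selection eliminated every feature")
    cols = [features.index(f) for f in survivors]
    l2 = LogisticRegression(
        C=final_reg_weight, solver="liblinear", l1_ratio=0.0, random_state=seed, max_iter=2000
    ).fit(X[:, cols], y)
    return LogisticModel(
        feature_names=survivors,
        weights=l2.coef_.ravel().copy(),
        bias=float(l2.intercept_[0]),
        penalty="l2",
        reg_weight=final_reg_weight,
        seed=seed,
        metadata={"l1_select_reg_weight": select_reg_weight, "n_per_class": int(n)},
    )


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    threshold: float
    achieved: float
    attained: bool
    mode: str
    target: float


def calibrate_threshold(
    scores, labels, mode: str = "precision", target: float = 0.8
) -> ThresholdResult:
    """Find the smallest decision threshold meeting a precision or FPR
    target (classify positive when score >= threshold).

    Candidate cuts are the observed score values; the returned threshold
    is the midpoint between the chosen cut and the next score below it,
    so perfectly separated classes yield the gap midpoint.  An
    unattainable target returns the best achievable value flagged
    ``attained = False``.
    """
    if mode not in {"precision", "fpr"}:
        raise ParameterError(f"unknown calibration mode {mode!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (y.any() and (~y).any()):
        raise TrainingError("both classes required for calibration")

    uniq = np.unique(s)[::-1]  # descending
    n_neg = int((~y).sum())
    best_cut = None
    best_val = None
    achieved_best = -np.inf if mode == "precision" else np.inf
    for t in uniq:
        pred = s >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        if mode == "precision":
            val = tp / (tp + fp) if tp + fp else np.nan
            ok = val >= target
            if not np.isnan(val) and val > achieved_best:
                achieved_best = val
        else:
            val = fp / n_neg
            ok = val <= target
            if val < achieved_best:
                achieved_best = val
        if ok:
            best_cut, best_val = t, val  # keep scanning: later t are smaller
    if best_cut is None:
        return ThresholdResult(
            threshold=float("nan"), achieved=float(achieved_best),
            attained=False, mode=mode, target=target,
        )
    below = uniq[uniq < best_cut]
    threshold = float((best_cut + below.max()) / 2.0) if len(below) else float(best_cut)
    return ThresholdResult(
        threshold=threshold, achieved=float(best_val), attained=True, mode=mode, target=target
    )


# ---------------------------------------------------------------------------
# QC artifact check and restraints
# ---------------------------------------------------------------------------

def diagonal_artifact_check(
    table: pd.DataFrame, band: int = 2, n_top: int = N_TOP_INTER, min_fraction: float = 0.5
) -> bool:
    """Flag concatenations whose strongest inter couplings track the
    diagonal (position i in A coupled to position ~i in B) — the
    signature of homologous rather than interacting proteins.  True iff
    at least ``min_fraction`` of the top ``n_top`` inter rows have
    segment-local offset |pos_A - pos_B| <= ``band``."""
    inter = table[table["is_inter"]]
    if len(inter) == 0:
        raise ParameterError("no inter-protein ECs")
    top = inter.nsmallest(n_top, "rank")
    offsets = (top["pos_i"] - top["pos_j"]).abs()
    return bool((offsets <= band).sum() >= min_fraction * len(top))


def export_restraints(
    table: pd.DataFrame,
    model_scores: dict[str, np.ndarray | pd.Series],
    residue_map: dict[int, tuple[str, int, str]],
    n_top: int = N_TOP_RESTRAINTS,
    distance: float = 5.0,
    bound: float = 2.0,
) -> tuple[str, int]:
    """Docking restraints from the top-scoring inter ECs.

    ``model_scores`` maps each scoring mode (e.g. ``structure-free``,
    ``structure-aware``) to per-row scores aligned with the inter rows of
    the table (rank order); the union of each mode's top ``n_top`` pairs
    is exported.  ``residue_map`` sends 1-based concatenated positions to
    (chain, residue number, one-letter aa); the restraint is placed on CB
    (CA for glycine) at ``distance`` with symmetric ``bound``.  Returns
    (restraint text, number of pairs skipped for unmappable residues).
    """
    inter = table[table["is_inter"]].nsmallest(len(table), "rank").reset_index(drop=True)
    selected: list[tuple[int, int]] = []
    for mode, scores in model_scores.items():
        s = np.asarray(scores, dtype=float)
        order = np.argsort(-s, kind="mergesort")[: min(n_top, len(s))]
        for k in order:
            pair = (int(inter.loc[k, "i"]), int(inter.loc[k, "j"]))
            if pair not in selected:
                selected.append(pair)
    selected.sort()

    lines = []
    skipped = 0
    for i, j in selected:
        if i not in residue_map or j not in residue_map:
            skipped += 1
            continue
        sel = []
        for pos in (i, j):
            chain, resnum, aa = residue_map[pos]
            atom = "CA" if aa.upper() == "G" else "CB"
            sel.append(f"(segid {chain} and resid {resnum} and name {atom})")
        lines.append(f"assign {sel[0]} {sel[1]} {distance:.1f} {bound:.1f} {bound:.1f}")
    return "\n".join(lines) + ("\n" if lines else ""), skipped
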