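"""SVM-ensemble kinase-substrate prediction with Pareto ranking.

Per-kinase classifiers are ensembles of RBF-kernel support vector
machines trained on literature-curated positive substrates against
independently subsampled negative sites (5:1 negative:positive per
member).  Features combine the three information channels of the study:
the scaled 9-point temporal profile plus its kinetic summaries (AUC,
order-2 polynomial coefficients, mean log2 ratio), the inhibitor-screen
responses, and per-kinase PSSM motif scores.  Ensemble decision values
are min-max normalized to [0, 1] over the scored cohort; a delta score
(score minus the best competing kinase's score) measures assignment
specificity, and candidates are prioritized by Pareto non-dominated
sorting over (score, delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from phosphodyn import motif as motif_mod
from phosphodyn import temporal
from phosphodyn.temporal import TIMEPOINTS_MIN


@dataclass
class SVMConfig:
    """Ensemble hyperparameters (the defaults are package choices)."""

    n_members: int = 25
    negative_ratio: float = 5.0
    C: float = 1.0
    gamma: str | float = "auto"  # 1 / n_features
    kernel: str = "rbf"

    @classmethod
    def from_dict(cls, d: dict) -> "SVMConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown svm config key(s): {sorted(unknown)}")
        return cls(**d)


SCALED_FEATURES = [f"scaled_{t:g}" for t in TIMEPOINTS_MIN]
KINETIC_FEATURES = ["auc", "poly_quad", "poly_lin", "poly_const", "mean_log2"]
INHIBITOR_FEATURES = ["ins_log2", "mk_log2", "ly_log2"]


def feature_columns(kinases) -> list[str]:
    """Documented feature layout: 9 scaled timepoints, AUC, 3 polynomial
    coefficients, mean log2 ratio, 3 inhibitor medians, K PSSM scores."""
    return (
        SCALED_FEATURES
        + KINETIC_FEATURES
        + INHIBITOR_FEATURES
        + [f"pssm_{k}" for k in kinases]
    )


def assemble_features(
    records,
    pssms: dict[str, motif_mod.PSSM],
    max_missing_timepoints: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Feature table (rows = site ids) plus exclusion counts.

    Sites missing a time course, more than ``max_missing_timepoints`` of
    the 9 timepoints, or an entire inhibitor arm are excluded and
    counted rather than imputed.
    """
    rows = {}
    excluded = {"no_timecourse": 0, "sparse_timecourse": 0, "no_inhibitor": 0}
    for r in records:
        tc = r.timecourse_quant
        if tc is None:
            excluded["no_timecourse"] += 1
            continue
        med = tc.log2_ratios
        if np.isnan(med).sum() > max_missing_timepoints or np.isfinite(med).sum() < 2:
            excluded["sparse_timecourse"] += 1
            continue
        q = r.inhibitor_quant
        if q is None or not all(q.arm_quantified(a) for a in ("ins", "mk", "ly")):
            excluded["no_inhibitor"] += 1
            continue
        interp = temporal.interpolate_missing(med)
        scaled, _ = temporal.scale_profile(med)
        poly = temporal.fit_poly2(scaled)
        feats = dict(zip(SCALED_FEATURES, scaled))
        feats["auc"] = temporal.compute_auc(scaled)
        feats["poly_quad"], feats["poly_lin"], feats["poly_const"] = poly
        feats["mean_log2"] = float(interp.mean())
        feats["ins_log2"] = q.ins_median
        feats["mk_log2"] = q.mk_median
        feats["ly_log2"] = q.ly_median
        for k, pssm in pssms.items():
            feats[f"pssm_{k}"] = motif_mod.score_window(pssm, r.sequence_window)
        rows[r.site_id] = feats
    cols = feature_columns(list(pssms))
    df = pd.DataFrame.from_dict(rows, orient="index")
    if len(df):
        df = df[cols]
    else:
        df = pd.DataFrame(columns=cols)
    df.index.name = "site_id"
    return df, excluded


def select_negative_pool(
    records, positive_ids: set[str], exclusion_window: int = 13
) -> list[str]:
    """Candidate negatives: sites not in any positive set and not within
    ``exclusion_window`` residues of a positive on the same protein
    (avoids sequence-window overlap leakage)."""
    positives = [
        (r.protein_id, r.position) for r in records if r.site_id in positive_ids
    ]
    by_protein: dict[str, list[int]] = {}
    for prot, pos in positives:
        by_protein.setdefault(prot, []).append(pos)
    pool = []
    for r in records:
        if r.site_id in positive_ids:
            continue
        near = any(
            abs(r.position - p) <= exclusion_window
            for p in by_protein.get(r.protein_id, ())
        )
        if not near:
            pool.append(r.site_id)
    return pool


@dataclass
class KinaseClassifier:
    """Trained ensemble for one kinase."""

    kinase: str
    members: list[Pipeline]
    feature_columns: list[str]
    config: SVMConfig
    seed: int | None = None
    score_min: float = field(default=np.nan)
    score_max: float = field(default=np.nan)


def train_ensemble(
    kinase: str,
    positive_ids,
    features: pd.DataFrame,
    config: SVMConfig | None = None,
    seed: int | None = None,
    negative_pool=None,
) -> KinaseClassifier:
    """Fit an ensemble of SVMs: all positives vs fresh negative subsamples.

    Each member standardizes its own training data and fits an SVC; the
    negative subsample (``negative_ratio`` x positives, without
    replacement) is drawn independently per member.  Deterministic for a
    fixed seed.
    """
    config = config or SVMConfig()
    positive_ids = list(dict.fromkeys(positive_ids))
    missing = [p for p in positive_ids if p not in features.index]
    if missing:
        raise ValueError(
            f"positive site(s) absent from the feature table: {missing[:10]}"
        )
    if len(positive_ids) < 10:
        raise ValueError("train_ensemble requires at least 10 positives")
    if negative_pool is None:
        negative_pool = [i for i in features.index if i not in set(positive_ids)]
    else:
        negative_pool = [i for i in negative_pool if i in features.index]
    if len(negative_pool) < 10 * len(positive_ids):
        raise ValueError(
            "negative pool must be at least 10x the positive set "
            f"({len(negative_pool)} vs {len(positive_ids)} positives)"
        )
    rng = np.random.default_rng(seed)
    x_pos = features.loc[positive_ids].to_numpy()
    pool = np.asarray(negative_pool)
    n_neg = min(len(pool), int(round(config.negative_ratio * len(positive_ids))))
    members: list[Pipeline] = []
    for _ in range(config.n_members):
        neg_ids = rng.choice(pool, size=n_neg, replace=False)
        x = np.vstack([x_pos, features.loc[neg_ids].to_numpy()])
        y = np.concatenate([np.ones(len(x_pos)), np.zeros(n_neg)])
        clf = make_pipeline(
            StandardScaler(),
            SVC(kernel=config.kernel, C=config.C, gamma=config.gamma),
        )
        clf.fit(x, y)
        members.append(clf)
    return KinaseClassifier(
        kinase=kinase,
        members=members,
        feature_columns=list(features.columns),
        config=config,
        seed=seed,
    )


def ensemble_decision_values(
    classifier: KinaseClassifier, features: pd.DataFrame
) -> np.ndarray:
    """Mean SVM decision value over ensemble members (unnormalized)."""
    if list(features.columns) != classifier.feature_columns:
        raise ValueError(
            "feature layout does not match the classifier's training layout"
        )
    x = features.to_numpy()
    return np.mean([m.decision_function(x) for m in classifier.members], axis=0)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; a degenerate (constant or single-value)
    cohort maps to 0.5 with a warning."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        warnings.warn(
            "degenerate score normalization (constant scores); returning 0.5",
            stacklevel=2,
        )
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def predict_scores(
    classifier: KinaseClassifier, features: pd.DataFrame
) -> pd.Series:
    """Normalized [0, 1] prediction scores over the scored cohort."""
    raw = ensemble_decision_values(classifier, features)
    classifier.score_min = float(raw.min())
    classifier.score_max = float(raw.max())
    return pd.Series(minmax_normalize(raw), index=features.index, name=classifier.kinase)


def delta_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """delta[s, K] = score[s, K] - max over other kinases' scores of s."""
    if scores.shape[1] < 2:
        raise ValueError("delta scores require at least 2 kinases")
    arr = scores.to_numpy()
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        others = np.delete(arr, j, axis=1)
        out[:, j] = arr[:, j] - others.max(axis=1)
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)


def pareto_rank(
    scores: np.ndarray, deltas: np.ndarray, site_ids
) -> pd.DataFrame:
    """Non-dominated sorting maximizing (score, delta).

    Front 1 holds the points dominated by no other (dominance: >= on
    both coordinates, > on at least one); later fronts are defined
    recursively on the remainder.  Within a front, ranks are assigned by
    descending score, ties broken stably by site id; the overall rank
    orders by (front, -score, site_id).

    Implemented as a sorted sweep: after ordering by descending score
    (then descending delta, then id), a point is dominated within a
    front iff the front's best delta so far strictly exceeds its delta,
    or equals it via a point with strictly larger score.
    """
    scores = np.asarray(scores, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    site_ids = list(site_ids)
    n = len(site_ids)
    if not (len(scores) == len(deltas) == n):
        raise ValueError("scores, deltas and site_ids must have equal length")
    if n == 0:
        return pd.DataFrame(columns=["site_id", "score", "delta", "pareto_front", "rank"])
    if not (np.isfinite(scores).all() and np.isfinite(deltas).all()):
        raise ValueError("pareto_rank requires finite points")

    order = sorted(range(n), key=lambda i: (-scores[i], -deltas[i], site_ids[i]))
    fronts = np.zeros(n, dtype=int)
    # per existing front: (max delta seen, max score among points at that delta)
    front_state: list[tuple[float, float]] = []
    for i in order:
        placed = False
        for f, (best_delta, score_at_best) in enumerate(front_state):
            dominated = best_delta > deltas[i] or (
                best_delta == deltas[i] and score_at_best > scores[i]
            )
            if not dominated:
                fronts[i] = f + 1
                if deltas[i] > best_delta:
                    front_state[f] = (deltas[i], scores[i])
                placed = True
                break
        if not placed:
            front_state.append((deltas[i], scores[i]))
            fronts[i] = len(front_state)

    df = pd.DataFrame(
        {
            "site_id": site_ids,
            "score": scores,
            "delta": deltas,
            "pareto_front": fronts,
        }
    )
    df = df.sort_values(
        ["pareto_front", "score", "site_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, n + 1)
    return df


def rank_predictions(
    scores: pd.DataFrame,
    positives: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Full prediction table: per kinase, delta scores + Pareto ranks.

    ``positives`` flags known substrates in the output without removing
    them from the ranking.
    """
    deltas = delta_scores(scores)
    positives = positives or {}
    tables = []
    for kin in scores.columns:
        t = pareto_rank(
            scores[kin].to_numpy(), deltas[kin].to_numpy(), scores.index
        )
        t.insert(1, "kinase", kin)
        known = positives.get(kin, set())
        t["known_positive"] = t["site_id"].isin(known)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def evaluate_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int = 5,
    seed: int | None = None,
    config: SVMConfig | None = None,
) -> dict:
    """Stratified k-fold sensitivity/specificity/AUROC of the ensemble.

    Metrics use the 0.5 normalized-score operating point, with scores
    normalized within each held-out fold; confidence intervals are
    normal approximations over the folds.
    """
    config = config or SVMConfig()
    y = np.asarray(labels).astype(int)
    if (np.bincount(y, minlength=2)[1] // folds) < 2:
        raise ValueError("each fold must contain at least 2 positives")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sens, spec, aucs = [], [], []
    ids = np.asarray(features.index)
    for k, (tr, te) in enumerate(skf.split(features, y)):
        pos_tr = ids[tr][y[tr] == 1]
        clf = train_ensemble(
            "cv",
            pos_tr,
            features.iloc[tr],
            config=config,
            seed=None if seed is None else seed + k,
            negative_pool=ids[tr][y[tr] == 0],
        )
        raw = ensemble_decision_values(clf, features.iloc[te])
        norm = minmax_normalize(raw)
        pred = norm >= 0.5
        truth = y[te] == 1
        tp = int((pred & truth).sum())
        fn = int((~pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        fp = int((pred & ~truth).sum())
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        aucs.append(roc_auc_score(truth, raw))

    def ci(vals):
        v = np.asarray(vals, dtype=float)
        m = float(np.nanmean(v))
        half = 1.96 * float(np.nanstd(v, ddof=1)) / np.sqrt(len(v))
        return m, (m - half, m + half)

    s, s_ci = ci(sens)
    p, p_ci = ci(spec)
    a, a_ci = ci(aucs)
    return {
        "sensitivity": s,
        "sensitivity_ci": s_ci,
        "specificity": p,
        "specificity_ci": p_ci,
        "auroc": a,
        "auroc_ci": a_ci,
        "fold_auroc": aucs,
    }
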