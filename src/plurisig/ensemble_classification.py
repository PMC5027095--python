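"""Step 3: resampled ensemble classification and per-gene prediction rates.

For every balanced resample, a logistic model on the signature features
is assessed by stratified 10-fold cross-validation: each training gene
receives an out-of-fold probability (avoiding resubstitution optimism)
and the resample's ROC AUC is computed from those probabilities.  A
model refit on the whole resample then scores every gene outside the
training set.  Per gene, the prediction rate is the fraction of
resamples whose applicable probability exceeds the classification
threshold; non-positive genes with rate >= 90% are called candidate
pluripotency genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .peak_io import FeatureMatrix
from .signature_selection import ResamplePlan, _derive_seed, _stratified_folds

logger = logging.getLogger(__name__)

DEFAULT_N_FOLDS = 10
DEFAULT_PROB_THRESHOLD = 0.5
DEFAULT_CALL_THRESHOLD = 0.9

#: Effectively-unpenalized ridge weight for the per-resample refits; a
#: tiny L2 term keeps separable resamples numerically finite without
#: affecting the probability ranking.
_REFIT_C = 1e6


@dataclass
class ModelRun:
    """One resample's cross-validated model."""

    resample_index: int
    auc: float
    oof_probability: dict[str, float]     # training genes, out-of-fold
    global_probability: dict[str, float]  # all other genes, full-model


@dataclass
class EnsembleResult:
    """Aggregated ensemble over all resamples for one scope."""

    scope: str
    per_resample_auc: list[float]
    mean_auc: float
    sd_auc: float
    prediction_rate: dict[str, float]
    candidates: set[str]
    n_resamples: int


def compute_roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC via the Mann-Whitney rank statistic (ties 1/2).

    Returns ``(roc_points, auc)`` where ``roc_points`` is the (FPR, TPR)
    polyline from threshold +inf down to -inf.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and the same length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(s)  # average ranks for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # ROC polyline over descending unique thresholds
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each run of equal scores
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in last
    ]
    return points, float(auc)


def _fit_probability_model(X: np.ndarray, y: np.ndarray,
                           seed: int) -> LogisticRegression:
    clf = LogisticRegression(C=_REFIT_C, solver="lbfgs", max_iter=2000,
                             random_state=seed)
    with warnings.catch_warnings():
        # separable resamples legitimately stop at the iteration cap with
        # saturated probabilities; the ranking is already converged
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def run_ensemble(
    matrix: FeatureMatrix,
    plan: ResamplePlan,
    scope: str = "combined",
    n_folds: int = DEFAULT_N_FOLDS,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
    keep_runs: bool = False,
) -> EnsembleResult | tuple[EnsembleResult, list[ModelRun]]:
    """Run the resampled cross-validated ensemble on the given matrix.

    ``matrix`` must already be restricted to the signature's columns
    (and Z-scored) but cover the full gene universe.  Per resample the
    training genes get out-of-fold probabilities (their AUC is the
    resample AUC) and all remaining genes are scored by the full-resample
    model.  A gene counts as "predicted pluripotent" in a resample when
    its applicable probability is strictly greater than
    ``prob_threshold``; candidates are non-positive genes with
    prediction rate >= ``call_threshold``.
    """
    if matrix.n_columns == 0:
        raise ValueError("no features selected: cannot run the ensemble")
    if not matrix.normalized:
        raise ValueError("matrix must be Z-score normalized")
    n_genes = matrix.n_genes
    all_idx = np.arange(n_genes)
    pos_idx = matrix.gene_indices(sorted(plan.positives))
    hits = np.zeros(n_genes, dtype=int)
    aucs: list[float] = []
    runs: list[ModelRun] = []
    X_all = matrix.values

    for r, negatives in enumerate(plan.negative_sets):
        neg_idx = matrix.gene_indices(sorted(negatives))
        train_idx = np.concatenate([pos_idx, neg_idx])
        y_train = np.r_[np.ones(len(pos_idx)), np.zeros(len(neg_idx))]
        # fold seed from the negative-set content: prediction rates are
        # then invariant to the order resamples are listed in
        seed = _derive_seed(plan.master_seed,
                            "folds:" + ",".join(sorted(negatives)))
        rng = np.random.default_rng(seed)
        oof = np.empty(len(train_idx))
        local = np.arange(len(train_idx))
        for held_out in _stratified_folds(y_train, n_folds, rng):
            fit_rows = np.setdiff1d(local, held_out)
            clf = _fit_probability_model(
                X_all[train_idx[fit_rows]], y_train[fit_rows], seed
            )
            oof[held_out] = clf.predict_proba(X_all[train_idx[held_out]])[:, 1]
        _, auc = compute_roc_auc(y_train.astype(int), oof)
        aucs.append(auc)
        full = _fit_probability_model(X_all[train_idx], y_train, seed)
        rest_idx = np.setdiff1d(all_idx, train_idx)
        rest_prob = (full.predict_proba(X_all[rest_idx])[:, 1]
                     if len(rest_idx) else np.empty(0))
        hits[train_idx[oof > prob_threshold]] += 1
        hits[rest_idx[rest_prob > prob_threshold]] += 1
        if keep_runs:
            runs.append(
                ModelRun(
                    resample_index=r,
                    auc=auc,
                    oof_probability={matrix.gene_ids[i]: float(p)
                                     for i, p in zip(train_idx, oof)},
                    global_probability={matrix.gene_ids[i]: float(p)
                                        for i, p in zip(rest_idx, rest_prob)},
                )
            )

    rate = hits / plan.n_resamples
    prediction_rate = {g: float(rate[i]) for i, g in enumerate(matrix.gene_ids)}
    candidates = call_candidates(prediction_rate, set(plan.positives),
                                 call_threshold)
    result = EnsembleResult(
        scope=scope,
        per_resample_auc=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs)),
        prediction_rate=prediction_rate,
        candidates=candidates,
        n_resamples=plan.n_resamples,
    )
    return (result, runs) if keep_runs else result


def call_candidates(prediction_rate: dict[str, float], positives: set[str],
                    call_threshold: float = DEFAULT_CALL_THRESHOLD) -> set[str]:
    """Non-positive genes predicted pluripotent in >= ``call_threshold`` of
    resamples (e.g. 450/500 -> rate 0.9 -> candidate; 449/500 -> not)."""
    return {
        g for g, v in prediction_rate.items()
        if v >= call_threshold and g not in positives
    }


def compare_scopes(results: dict[str, EnsembleResult]) -> pd.DataFrame:
    """Rank scopes by mean AUC (ties broken by scope name, stable)."""
    if len(results) < 2:
        raise ValueError("need at least two scopes to compare")
    rows = [
        {"scope": scope, "mean_auc": res.mean_auc, "sd_auc": res.sd_auc,
         "n_resamples": res.n_resamples}
        for scope, res in sorted(results.items())
    ]
    df = pd.DataFrame(rows)
    return (df.sort_values(["mean_auc", "scope"], ascending=[False, True])
              .reset_index(drop=True))


def write_ensemble_outputs(result: EnsembleResult, out_dir,
                           positives: set[str]) -> dict[str, str]:
    """Write per-resample AUCs and per-gene prediction rates as TSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    auc_path = out_dir / f"auc_{result.scope}.tsv"
    with open(auc_path, "w") as fh:
        fh.write("resample\tauc\n")
        for i, a in enumerate(result.per_resample_auc):
            fh.write(f"{i}\t{a:.6g}\n")
    rate_path = out_dir / f"prediction_rate_{result.scope}.tsv"
    with open(rate_path, "w") as fh:
        fh.write("gene_id\tprediction_rate\tis_positive\tis_candidate\n")
        for g in sorted(result.prediction_rate):
            fh.write(
                f"{g}\t{result.prediction_rate[g]:.6g}"
                f"\t{int(g in positives)}\t{int(g in result.candidates)}\n"
            )
    return {"auc": str(auc_path), "prediction_rate": str(rate_path)}
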