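"""Experiment harness: splits, cross-validation, metrics and the full
simulation-study protocol.

The protocol for one dataset: a stratified 70/30 screening/replication
split; on the screening set QC, top-500 chi-square selection and LD
block construction; stratified balanced 10-fold CV of the hierarchical
model, standard NB and the majority reference (feature selection and
block schema are, deliberately, learned once on the whole screening set
— the optimistic bias this induces in CV is part of the protocol being
reproduced, and a nested-selection flag removes it); finally a fit on
the whole screening set scored on the untouched replication set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from . import naive_bayes as nbm
from .dataset import CASE, GenotypeDataset
from .hnb import Hyperparams, fit_hnb, predict_log_posterior
from .ld import build_ld_blocks, select_top_k, snp_qc

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def stratified_split(dataset: GenotypeDataset, fraction: float = 0.70, seed: int = 0):
    """Stratified screening/replication split preserving class ratios.

    Returns (screening, replication) datasets covering all samples,
    disjoint, reproducible by seed.
    """
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes for a stratified split")
    if (counts < 2).any():
        raise ValueError("each class needs >= 2 samples")
    idx = np.arange(dataset.n_samples)
    screen_idx, repl_idx = train_test_split(
        idx, train_size=fraction, stratify=labels, random_state=seed
    )
    return dataset.subset_samples(np.sort(screen_idx)), dataset.subset_samples(
        np.sort(repl_idx)
    )


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list:
    """k disjoint folds, each with identical per-class sizes.

    Samples beyond the largest per-class multiple of k are dropped (and
    logged) so every fold has equal size and a cases/controls ratio
    matching the trimmed data exactly.  Returns a list of index arrays.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    per_class_folds = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer than k={k} samples")
        idx = rng.permutation(idx)
        keep = (len(idx) // k) * k
        if keep < len(idx):
            logger.info("dropping %d sample(s) of class %s to equalize folds",
                        len(idx) - keep, c)
        per_class_folds.append(idx[:keep].reshape(k, -1))
    return [np.sort(np.concatenate([f[i] for f in per_class_folds]))
            for i in range(k)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_accuracy(labels, predictions) -> float:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions differ in length")
    if len(labels) == 0:
        raise ValueError("empty input")
    return float((labels == predictions).mean())


def auc(labels, scores, positive=CASE) -> float:
    """Mann-Whitney AUC of case-class scores; ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def wilcoxon_signed_rank_one_tailed(x, y) -> tuple:
    """One-tailed Wilcoxon signed-rank test of H1: median(x - y) > 0.

    Zero differences are dropped; tied absolute differences get averaged
    ranks.  For n <= 25 the p-value is exact over the 2^n equiprobable
    sign assignments (computed by convolution over the rank-sum
    distribution, which handles tied ranks); larger n uses the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (W, p) with W the positive-rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples differ in length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(int)  # averaged ranks -> half-integers
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        w2 = int(np.rint(2 * w))
        p = dist[w2:].sum() / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(r2_ := np.rint(2 * ranks).astype(int),
                                  return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w - mean - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    return w, min(1.0, float(p))


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

MODELS = ("hnb", "nb", "majority")


@dataclass
class ExperimentResult:
    """CV and replication metrics for one dataset at each LD threshold.

    ``cv`` maps (r2_threshold, model) -> {"ca": [...], "auc": [...]}
    with one entry per fold; ``test`` maps the same key to the
    replication-set {"ca": ..., "auc": ...}.
    """

    cv: dict
    test: dict
    n_blocks: dict
    n_covariates: dict
    seed: int
    selection_k: int
    config: dict = field(default_factory=dict)

    def median_cv(self, threshold, model, metric) -> float:
        return float(np.median(self.cv[(threshold, model)][metric]))

    def summary_table(self) -> pd.DataFrame:
        """Table shaped like the simulation-study report: per threshold
        and model, median [min-max] CV metrics and replication metrics."""
        rows = []
        for (thr, model), m in self.cv.items():
            ca, au = np.array(m["ca"]), np.array(m["auc"])
            t = self.test[(thr, model)]
            rows.append(
                {
                    "ld_threshold": thr,
                    "model": model.upper(),
                    "cv_ca": f"{np.median(ca):.2f} [{ca.min():.2f}-{ca.max():.2f}]",
                    "cv_auc": f"{np.median(au):.2f} [{au.min():.2f}-{au.max():.2f}]",
                    "test_ca": f"{t['ca']:.2f}",
                    "test_auc": f"{t['auc']:.2f}",
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cv": {f"{t}|{m}": v for (t, m), v in self.cv.items()},
                "test": {f"{t}|{m}": v for (t, m), v in self.test.items()},
                "n_blocks": {str(t): v for t, v in self.n_blocks.items()},
                "n_covariates": {str(t): v for t, v in self.n_covariates.items()},
                "seed": self.seed,
                "selection_k": self.selection_k,
                "config": self.config,
            }
        )


def _scores_and_preds(model_name, train, test, schema, hyper, top_ids):
    """Fit one model on `train`, return (predicted labels, case scores)."""
    if model_name == "hnb":
        m = fit_hnb(train, schema, hyper)
        log_post = predict_log_posterior(m, test)
        classes = m.classes
    elif model_name == "nb":
        m = nbm.fit_nb(train, top_ids)
        log_post = nbm.predict_nb(m, test)
        classes = m.classes
    elif model_name == "majority":
        m = nbm.majority_classifier(train)
        log_post = nbm.predict_majority(m, test)
        classes = m.classes
    else:  # pragma: no cover
        raise ValueError(model_name)
    preds = np.array([classes[i] for i in np.argmax(log_post, axis=1)])
    case_scores = log_post[:, classes.index(CASE)]
    return preds, case_scores


def run_experiment(
    dataset: GenotypeDataset,
    r2_thresholds=(0.6, 0.8),
    hyper: Hyperparams | None = None,
    selection_k: int = 500,
    seed: int = 0,
    k_folds: int = 10,
    do_qc: bool = True,
    qc_params: dict | None = None,
    nested_selection: bool = False,
    disable_blocks: bool = False,
    models=MODELS,
) -> ExperimentResult:
    """Run the full protocol on one case-control dataset.

    With ``nested_selection`` the QC/selection/schema steps are redone
    inside every CV fold on its training part only (no selection leak);
    ``disable_blocks`` forces an empty block set so the hierarchical
    model degenerates to plain NB over the selected SNPs.
    """
    hyper = hyper or Hyperparams()
    screen, repl = stratified_split(dataset, 0.70, seed=seed)

    def _select_and_schema(train_ds, thr):
        ds = train_ds
        if do_qc:
            ds, _ = snp_qc(ds, **(qc_params or {}))
        top = select_top_k(ds, k=selection_k)
        schema = build_ld_blocks(ds, top, thr, selection_k=selection_k)
        if disable_blocks:
            schema.covariates = list(schema.minor_alleles.keys())
            schema.blocks = []
        return top, schema

    folds = stratified_kfold(screen.labels, k=k_folds, seed=seed)
    all_fold = np.concatenate(folds)

    cv = {}
    test = {}
    n_blocks, n_cov = {}, {}
    for thr in r2_thresholds:
        top, schema = _select_and_schema(screen, thr)
        n_blocks[thr] = len(schema.blocks)
        n_cov[thr] = len(schema.covariates)
        for model in models:
            cv[(thr, model)] = {"ca": [], "auc": []}
        for i, fold in enumerate(folds):
            train_idx = np.setdiff1d(all_fold, fold)
            tr = screen.subset_samples(train_idx)
            te = screen.subset_samples(fold)
            if nested_selection:
                f_top, f_schema = _select_and_schema(tr, thr)
            else:
                f_top, f_schema = top, schema
            for model in models:
                preds, scores = _scores_and_preds(model, tr, te, f_schema, hyper, f_top)
                cv[(thr, model)]["ca"].append(
                    classification_accuracy(te.labels, preds)
                )
                cv[(thr, model)]["auc"].append(auc(te.labels, scores))
        for model in models:
            preds, scores = _scores_and_preds(model, screen, repl, schema, hyper, top)
            test[(thr, model)] = {
                "ca": classification_accuracy(repl.labels, preds),
                "auc": auc(repl.labels, scores),
            }
    return ExperimentResult(
        cv=cv,
        test=test,
        n_blocks=n_blocks,
        n_covariates=n_cov,
        seed=seed,
        selection_k=selection_k,
        config={
            "r2_thresholds": list(r2_thresholds),
            "alpha": hyper.alpha,
            "beta": hyper.beta,
            "estimator": hyper.estimator,
            "nested_selection": nested_selection,
            "disable_blocks": disable_blocks,
            "k_folds": k_folds,
        },
    )
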