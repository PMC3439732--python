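"""Standard Naive Bayes over individual SNPs, plus the majority classifier.

Serves two roles: the comparison baseline against the hierarchical model,
and the covariate sub-model for SNPs that fall outside LD blocks.  Each
SNP is a categorical attribute with states aa/aA/AA (minor-allele dosage
0/1/2); conditional probability tables are smoothed with the Laplace or
m-estimate rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dataset import MISSING, GenotypeDataset

N_STATES = 3


def cpt_from_counts(counts: np.ndarray, m: float, prior: np.ndarray) -> np.ndarray:
    """Smoothed CPT rows from a (..., S) state-count array.

    P(s) = (count_s + m * prior_s) / (n_observed + m); the m-estimate,
    with Laplace as the special case m = S, prior uniform.
    """
    counts = np.asarray(counts, dtype=float)
    n_obs = counts.sum(axis=-1, keepdims=True)
    return (counts + m * prior) / (n_obs + m)


def _resolve_smoothing(smoothing, m, prior, n_states=N_STATES):
    if smoothing == "laplace":
        return float(n_states), np.full(n_states, 1.0 / n_states)
    if smoothing == "m_estimate":
        if m is None or m < 0:
            raise ValueError("m_estimate smoothing requires m >= 0")
        prior = (
            np.full(n_states, 1.0 / n_states) if prior is None else np.asarray(prior, float)
        )
        if prior.shape != (n_states,) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("smoothing prior must be a length-S probability vector")
        return float(m), prior
    raise ValueError(f"unknown smoothing {smoothing!r}")


@dataclass
class NBModel:
    """Per-SNP categorical CPTs and class priors."""

    classes: list
    log_prior: np.ndarray
    snp_ids: list
    counted_allele: np.ndarray  # allele whose dosage the CPT states count
    cpt: np.ndarray  # (n_classes, n_snps, S) probabilities
    smoothing: str = "laplace"
    m: float = N_STATES

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_type": "nb",
                "classes": [int(c) for c in self.classes],
                "log_prior": self.log_prior.tolist(),
                "snp_ids": list(self.snp_ids),
                "counted_allele": list(self.counted_allele),
                "cpt": self.cpt.tolist(),
                "smoothing": self.smoothing,
                "m": self.m,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NBModel":
        d = json.loads(text)
        if d.get("model_type") != "nb":
            raise ValueError(f"not an NB model: {d.get('model_type')}")
        return cls(
            classes=d["classes"],
            log_prior=np.array(d["log_prior"]),
            snp_ids=d["snp_ids"],
            counted_allele=np.array(d["counted_allele"], dtype=object),
            cpt=np.array(d["cpt"]),
            smoothing=d["smoothing"],
            m=d["m"],
        )


def class_log_prior(labels: np.ndarray, classes) -> np.ndarray:
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    if (counts == 0).any():
        absent = [c for c, n in zip(classes, counts) if n == 0]
        raise ValueError(f"class(es) absent from training data: {absent}")
    return np.log(counts / counts.sum())


def fit_nb(
    train: GenotypeDataset,
    snp_ids,
    smoothing: str = "laplace",
    m: float | None = None,
    prior=None,
) -> NBModel:
    """Fit per-SNP CPTs and empirical class priors.

    Missing genotypes are excluded from the per-SNP counts (the CPT
    denominator is the number of *observed* genotypes in the class).
    """
    m_val, prior_vec = _resolve_smoothing(smoothing, m, prior)
    cols = train.snp_index(snp_ids)
    classes = sorted(np.unique(train.labels).tolist())
    if len(classes) < 1:
        raise ValueError("empty training set")
    log_prior = class_log_prior(train.labels, classes)
    cpt = np.empty((len(classes), len(cols), N_STATES))
    for k, c in enumerate(classes):
        counts = train.genotype_counts(mask=train.labels == c)[cols]
        cpt[k] = cpt_from_counts(counts, m_val, prior_vec)
    return NBModel(
        classes=classes,
        log_prior=log_prior,
        snp_ids=list(snp_ids),
        counted_allele=train.counted_allele[cols].copy(),
        cpt=cpt,
        smoothing=smoothing,
        m=m_val,
    )


def _aligned_dosage(model_snp_ids, model_counted, dataset: GenotypeDataset):
    """Dosage columns for the model's SNPs, flipped where the dataset
    counts the opposite allele."""
    cols = dataset.snp_index(model_snp_ids)
    d = dataset.dosage[:, cols].astype(np.int8)
    flip = dataset.counted_allele[cols] != model_counted
    if flip.any():
        dd = d[:, flip]
        d[:, flip] = np.where(dd == MISSING, MISSING, 2 - dd)
    return d


def log_likelihood_nb(model: NBModel, data: GenotypeDataset) -> np.ndarray:
    """(n, K) sums of per-SNP log CPT terms; missing genotypes skipped."""
    d = _aligned_dosage(model.snp_ids, model.counted_allele, data)
    log_cpt = np.log(model.cpt)  # (K, M, S)
    n, m = d.shape
    obs = d != MISSING
    state = np.where(obs, d, 0)
    out = np.zeros((n, len(model.classes)))
    for k in range(len(model.classes)):
        ll = log_cpt[k][np.arange(m)[None, :], state]  # (n, m)
        out[:, k] = np.where(obs, ll, 0.0).sum(axis=1)
    return out


def predict_nb(model: NBModel, data: GenotypeDataset) -> np.ndarray:
    """Normalized per-class log posteriors, one row per individual.

    Missing genotypes contribute nothing to the product.
    """
    scores = model.log_prior[None, :] + log_likelihood_nb(model, data)
    return scores - logsumexp(scores, axis=1, keepdims=True)


@dataclass
class MajorityModel:
    """Predicts the most frequent training class with a constant score."""

    classes: list
    log_prior: np.ndarray
    majority_class: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_type": "majority",
                "classes": [int(c) for c in self.classes],
                "log_prior": self.log_prior.tolist(),
                "majority_class": int(self.majority_class),
            }
        )


def majority_classifier(train: GenotypeDataset) -> MajorityModel:
    """Majority-class reference model.

    Ties in the training class frequencies resolve to the first label, so
    a balanced design predicts the first class for everyone; the constant
    posterior gives AUC 0.5 under the ties-as-half convention.
    """
    if train.n_samples == 0:
        raise ValueError("empty training set")
    classes = sorted(np.unique(train.labels).tolist())
    log_prior = class_log_prior(train.labels, classes)
    majority = classes[int(np.argmax(log_prior))]  # argmax -> first on ties
    return MajorityModel(classes=classes, log_prior=log_prior, majority_class=majority)


def predict_majority(model: MajorityModel, data: GenotypeDataset) -> np.ndarray:
    """Constant log-posterior rows equal to the training class prior."""
    return np.tile(model.log_prior, (data.n_samples, 1))
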