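"""Hierarchical Naive Bayes with Dirichlet-multinomial LD-block variables.

The model treats the SNPs of one linkage-disequilibrium block as
replicates of a single latent block variable.  For individual ``i`` the
vector of genotype-state counts over the block,
``x_i = (x_aa, x_aA, x_AA)`` with ``nrep_i = sum_j x_ij`` observed
(non-missing) SNPs, is multinomial with an individual-level parameter
``theta_i``; the ``theta_i`` of one class share a Dirichlet prior
``Dirichlet(alpha * xi)`` around the class-level population vector
``xi``.  ``theta`` is integrated out analytically, so classification
only needs the closed-form Dirichlet-multinomial marginal likelihood

    P(x | xi) = nrep! * G(a) / G(nrep + a)
                * prod_j G(x_j + a_j) / (x_j! * G(a_j)),

with ``a_j = alpha * xi_j`` and ``a = sum_j a_j``.  Learning collapses
the hierarchy: each individual's counts are down-weighted by
``tau_i = (1 + alpha) / (nrep_i + alpha)`` before the (ML or Bayesian)
estimate of ``xi`` is formed, so many replicates of one individual never
dominate the population estimate.

``alpha`` interpolates between complete pooling of all replicates
(``alpha -> inf``: the marginal likelihood tends to a plain multinomial
in ``xi``) and full per-individual heterogeneity (small ``alpha``).

SNPs outside any block enter the Naive Bayes product as independent
categorical covariates with smoothed CPTs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from . import naive_bayes as nb
from .dataset import MISSING, GenotypeDataset
from .ld import BlockSchema, apply_schema

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "HNBModel",
    "collapse_weight",
    "estimate_xi",
    "log_marginal_likelihood",
    "fit_hnb",
    "predict_log_posterior",
    "classify",
]


@dataclass(frozen=True)
class Hyperparams:
    """Hyperparameters of the hierarchical block model.

    alpha : Dirichlet concentration tying individuals of a class
        together (design parameter of the algorithm; default 1.0).
    beta, gamma : concentration and base measure of the Dirichlet
        hyperprior on ``xi``; ``beta = 1`` with uniform ``gamma`` is
        close to the Laplace estimate, other settings mimic m-estimates
        with ``beta`` in the role of m.  ``gamma = None`` means uniform.
    estimator : "bayes" (posterior-mean ``xi``) or "ml"; ml is exactly
        bayes with ``beta = 0``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: tuple | None = None
    estimator: str = "bayes"

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.estimator not in ("ml", "bayes"):
            raise ValueError("estimator must be 'ml' or 'bayes'")
        if self.gamma is not None:
            g = np.asarray(self.gamma, dtype=float)
            if (g < 0).any() or not np.isclose(g.sum(), 1.0):
                raise ValueError("gamma must be a probability vector")
            object.__setattr__(self, "gamma", tuple(g))

    def gamma_vector(self, n_states: int) -> np.ndarray:
        if self.gamma is None:
            return np.full(n_states, 1.0 / n_states)
        g = np.asarray(self.gamma, dtype=float)
        if g.shape != (n_states,):
            raise ValueError(f"gamma has length {len(g)}, expected {n_states}")
        return g


def collapse_weight(nrep, alpha: float):
    """Collapsing weight tau = (1 + alpha) / (nrep + alpha).

    Strictly decreasing in the number of replicates and equal to 1 when
    nrep = 1, so blocks of size one are weighted like plain NB counts.
    """
    nrep = np.asarray(nrep)
    if (nrep < 0).any():
        raise ValueError("nrep must be >= 0")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    return (1.0 + alpha) / (nrep + alpha)


def estimate_xi(counts, hyper: Hyperparams) -> np.ndarray:
    """Collapsed estimate of a block's class population vector ``xi``.

    Parameters
    ----------
    counts : (N, S) array of per-individual genotype-state counts
        (rows may sum to different nrep when genotypes are missing;
        all-missing rows contribute nothing).

    Returns the ML estimate ``sum tau_i x_ij / sum tau_i nrep_i`` or,
    with the Bayesian estimator, the Dirichlet posterior mean
    ``(sum tau_i x_ij + beta gamma_j) / (sum tau_i nrep_i + beta)``.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"counts must be 2-D (N, S), got shape {x.shape}")
    n_states = x.shape[1]
    if n_states < 2:
        raise ValueError("need at least 2 states")
    nrep = x.sum(axis=1)
    tau = collapse_weight(np.maximum(nrep, 0), hyper.alpha)
    tau = np.where(nrep > 0, tau, 0.0)  # all-missing individuals drop out
    num = (tau[:, None] * x).sum(axis=0) if len(x) else np.zeros(n_states)
    den = (tau * nrep).sum()
    if hyper.estimator == "bayes" and hyper.beta > 0:
        g = hyper.gamma_vector(n_states)
        return (num + hyper.beta * g) / (den + hyper.beta)
    if den == 0:
        raise ValueError("ML estimate undefined: no observed replicates")
    return num / den


def log_marginal_likelihood(
    x, xi, alpha: float, include_count_coefficient: bool = False
):
    """Log Dirichlet-multinomial marginal likelihood of block counts.

    Computed entirely with log-gamma.  ``x`` may be (S,) or (..., S) and
    broadcasts against ``xi``.  With the coefficient off, the
    class-constant ``nrep!`` and ``x_j!`` terms are dropped (they cancel
    when posteriors are normalized across classes).  A state observed
    with ``xi_j = 0`` yields -inf; ``nrep = 0`` yields 0 (log 1).
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    a = alpha * xi
    a_sum = np.broadcast_to(a, np.broadcast_shapes(x.shape, a.shape)).sum(axis=-1)
    nrep = x.sum(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = gammaln(x + a) - gammaln(a)
    # xi_j = 0: no contribution when x_j = 0, impossible when x_j > 0
    zero_a = np.broadcast_to(a == 0, terms.shape)
    xb = np.broadcast_to(x, terms.shape)
    terms = np.where(zero_a & (xb == 0), 0.0, terms)
    terms = np.where(zero_a & (xb > 0), -np.inf, terms)

    out = gammaln(a_sum) - gammaln(nrep + a_sum) + terms.sum(axis=-1)
    if include_count_coefficient:
        out = out + gammaln(nrep + 1) - gammaln(x + 1).sum(axis=-1)
    return out if out.ndim else float(out)


@dataclass
class HNBModel:
    """Fitted hierarchical Naive Bayes model.

    Per class: a log prior, one population vector ``xi`` per LD block,
    and one smoothed CPT per covariate SNP.
    """

    classes: list
    log_prior: np.ndarray  # (K,)
    block_ids: list
    block_xi: np.ndarray  # (K, n_blocks, S)
    block_n_train: np.ndarray  # (K, n_blocks) individuals with nrep > 0
    covariate_model: nb.NBModel | None
    hyper: Hyperparams
    schema: BlockSchema

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_type": "hnb",
                "classes": [int(c) for c in self.classes],
                "log_prior": self.log_prior.tolist(),
                "block_ids": list(self.block_ids),
                "block_xi": self.block_xi.tolist(),
                "block_n_train": self.block_n_train.tolist(),
                "covariate_model": (
                    json.loads(self.covariate_model.to_json())
                    if self.covariate_model is not None
                    else None
                ),
                "hyper": {
                    "alpha": self.hyper.alpha,
                    "beta": self.hyper.beta,
                    "gamma": list(self.hyper.gamma) if self.hyper.gamma else None,
                    "estimator": self.hyper.estimator,
                },
                "schema": json.loads(self.schema.to_json()),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HNBModel":
        d = json.loads(text)
        if d.get("model_type") != "hnb":
            raise ValueError(f"not an HNB model: {d.get('model_type')}")
        cov = d["covariate_model"]
        return cls(
            classes=d["classes"],
            log_prior=np.array(d["log_prior"]),
            block_ids=d["block_ids"],
            block_xi=np.array(d["block_xi"]),
            block_n_train=np.array(d["block_n_train"]),
            covariate_model=(
                nb.NBModel.from_json(json.dumps(cov)) if cov is not None else None
            ),
            hyper=Hyperparams(
                alpha=d["hyper"]["alpha"],
                beta=d["hyper"]["beta"],
                gamma=tuple(d["hyper"]["gamma"]) if d["hyper"]["gamma"] else None,
                estimator=d["hyper"]["estimator"],
            ),
            schema=BlockSchema.from_json(json.dumps(d["schema"])),
        )


def fit_hnb(
    train: GenotypeDataset,
    schema: BlockSchema,
    hyper: Hyperparams | None = None,
    covariate_smoothing: str = "laplace",
    covariate_m: float | None = None,
) -> HNBModel:
    """Fit class priors, per-block ``xi`` vectors and covariate CPTs."""
    hyper = hyper or Hyperparams()
    classes = sorted(np.unique(train.labels).tolist())
    log_prior = nb.class_log_prior(train.labels, classes)
    block_data = apply_schema(schema, train)

    n_blocks = len(schema.blocks)
    n_states = 3
    block_xi = np.zeros((len(classes), n_blocks, n_states))
    block_n = np.zeros((len(classes), n_blocks), dtype=int)
    for k, c in enumerate(classes):
        mask = train.labels == c
        for b in range(n_blocks):
            counts = block_data.block_counts[mask, b, :]
            block_xi[k, b] = estimate_xi(counts, hyper)
            block_n[k, b] = int((counts.sum(axis=1) > 0).sum())

    cov_model = None
    if schema.covariates:
        cov_model = nb.fit_nb(
            train, schema.covariates, smoothing=covariate_smoothing, m=covariate_m
        )
    return HNBModel(
        classes=classes,
        log_prior=log_prior,
        block_ids=[b.id for b in schema.blocks],
        block_xi=block_xi,
        block_n_train=block_n,
        covariate_model=cov_model,
        hyper=hyper,
        schema=schema,
    )


def predict_log_posterior(model: HNBModel, data: GenotypeDataset) -> np.ndarray:
    """Normalized per-class log posteriors, one row per individual.

    Per class: log prior + sum over blocks of the Dirichlet-multinomial
    marginal log likelihood + sum over covariates of the log CPT entry.
    Missing covariates contribute 0; an all-missing individual gets the
    prior back.
    """
    block_data = apply_schema(model.schema, data)
    n = data.n_samples
    scores = np.tile(model.log_prior, (n, 1))
    if len(model.block_ids):
        x = block_data.block_counts.astype(float)  # (n, B, 3)
        for k in range(len(model.classes)):
            scores[:, k] += log_marginal_likelihood(
                x, model.block_xi[k], model.hyper.alpha
            ).sum(axis=1)
    if model.covariate_model is not None:
        if model.covariate_model.classes != model.classes:
            raise ValueError("covariate model classes do not match")
        scores += nb.log_likelihood_nb(model.covariate_model, data)
    return scores - logsumexp(scores, axis=1, keepdims=True)


def classify(model: HNBModel, data: GenotypeDataset):
    """Arg-max classification.

    Returns (labels, posterior) with posterior rows summing to 1.  Exact
    ties resolve to the first class in ``model.classes`` and are logged.
    """
    log_post = predict_log_posterior(model, data)
    post = np.exp(log_post)
    best = np.argmax(log_post, axis=1)  # argmax -> first index on ties
    ties = (log_post == log_post[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("classification ties for %d individual(s); first class used",
                    int(ties.sum()))
    labels = np.array([model.classes[b] for b in best])
    return labels, post
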