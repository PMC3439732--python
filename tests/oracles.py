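"""Independent oracles used by the tests.

Each function recomputes a quantity by a route deliberately different
from the package implementation: numerical integration over the
probability simplex, brute-force enumeration, or closed-form
combinatorics.
"""

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


def dirichlet_multinomial_by_quadrature(x, xi, alpha):
    """Marginal P(x) = integral over the simplex of Multinomial(x | theta)
    times Dirichlet(theta | alpha * xi), for S = 3, by adaptive 2-D
    quadrature (theta3 = 1 - theta1 - theta2)."""
    x = np.asarray(x, dtype=float)
    a = alpha * np.asarray(xi, dtype=float)
    log_coef = gammaln(x.sum() + 1) - gammaln(x + 1).sum()
    log_dir_norm = gammaln(a.sum()) - gammaln(a).sum()

    def integrand(t2, t1):
        t3 = 1.0 - t1 - t2
        if t3 <= 0 or t1 <= 0 or t2 <= 0:
            return 0.0
        log_f = (
            (x[0] + a[0] - 1) * math.log(t1)
            + (x[1] + a[1] - 1) * math.log(t2)
            + (x[2] + a[2] - 1) * math.log(t3)
        )
        return math.exp(log_coef + log_dir_norm + log_f)

    val, _ = integrate.dblquad(
        integrand, 0.0, 1.0, lambda t1: 0.0, lambda t1: 1.0 - t1,
        epsabs=1e-13, epsrel=1e-10,
    )
    return val


def compositions(n, k):
    """All count vectors of length k summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in compositions(n - first, k - 1):
            yield (first,) + rest


def wilcoxon_exact_by_enumeration(x, y):
    """One-tailed signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return w_obs, count / 2.0**n


def auc_by_pair_enumeration(labels, scores, positive=2):
    """AUC as the fraction of (case, control) pairs where the case
    scores higher, ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def hwe_exact_by_enumeration(n_het, n_hom1, n_hom2):
    """Exact HWE p-value from the closed-form conditional probability of
    each heterozygote count given the allele counts (direct log-factorial
    evaluation, no recurrence)."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n_common = 2 * n - n_rare

    def log_prob(h):
        hr = (n_rare - h) // 2
        hc = (n_common - h) // 2
        return (
            gammaln(n + 1) - gammaln(hr + 1) - gammaln(hc + 1) - gammaln(h + 1)
            + h * math.log(2)
            + gammaln(n_rare + 1) + gammaln(n_common + 1) - gammaln(2 * n + 1)
        )

    hs = [h for h in range(n_rare % 2, min(n_rare, n_common) + 1, 2)]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hs.index(n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())
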