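"""Independent reference implementations used to validate the package:
Monte-Carlo KL estimates and a loop-based enrichment-score computation."""

import numpy as np


def mc_kl_divergence(mu_q, lv_q, mu_p, lv_p, n_samples, seed=0):
    """Monte-Carlo estimate of KL(q || p) for diagonal Gaussians.

    Samples z ~ q and averages log q(z) - log p(z).
    """
    mu_q, lv_q = np.asarray(mu_q, float), np.asarray(lv_q, float)
    mu_p, lv_p = np.asarray(mu_p, float), np.asarray(lv_p, float)
    rng = np.random.default_rng(seed)
    sd_q, sd_p = np.exp(0.5 * lv_q), np.exp(0.5 * lv_p)
    z = mu_q + sd_q * rng.standard_normal((n_samples, mu_q.shape[0]))
    log_q = -0.5 * (((z - mu_q) / sd_q) ** 2 + lv_q + np.log(2 * np.pi))
    log_p = -0.5 * (((z - mu_p) / sd_p) ** 2 + lv_p + np.log(2 * np.pi))
    return float(np.mean((log_q - log_p).sum(axis=1)))


def brute_force_enrichment(gene_ids, delta, set_ids):
    """Loop-based enrichment score: rank genes by delta descending (ties by
    list position), then scan every set-gene prefix explicitly."""
    delta = np.asarray(delta, float)
    order = sorted(range(len(gene_ids)), key=lambda i: (-delta[i], i))
    rank = {gene_ids[i]: pos + 1 for pos, i in enumerate(order)}
    v = sorted(rank[g] for g in set_ids)
    n, t = len(gene_ids), len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b
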