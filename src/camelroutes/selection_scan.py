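"""FST-outlier detection between groups with Bayesian FDR control.

The model follows the logistic decomposition of locus-by-population
FST used by Bayesian outlier scanners:

    logit(F_ij) = alpha_i + beta_j

with a locus effect ``alpha_i`` (zero for neutral loci) and a population
effect ``beta_j``.  Group allele counts at locus i in group j are
beta-binomial around an ancestral frequency ``p_i`` with dispersion set
by ``F_ij``.  A reversible-jump MCMC switches each ``alpha_i`` in and out
of the model with configurable prior odds for neutrality; a locus's
q-value is the mean posterior neutrality probability among all loci with
inclusion probability at least as high, and outliers are declared at a
q-value threshold (default FDR 0.05).

Positive ``alpha`` marks diversifying selection (differentiation above
the genome-wide background), negative ``alpha`` homogenizing selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from camelroutes.genotype_io import MISSING, GenotypeMatrix


@dataclass
class ChainParams:
    """MCMC schedule.  The defaults are desk-scale; ``full()`` mirrors the
    classical tool's schedule (20 pilot-equivalent adaptation sweeps are
    folded into the burn-in here)."""

    burn_in: int = 2000
    n_samples: int = 2000
    thin: int = 5

    @classmethod
    def full(cls) -> "ChainParams":
        return cls(burn_in=50_000, n_samples=5_000, thin=10)

    @classmethod
    def fast(cls) -> "ChainParams":
        return cls(burn_in=500, n_samples=500, thin=2)


@dataclass
class OutlierScanResult:
    """Per-SNP posterior summaries of the outlier scan."""

    snp_ids: list[str]
    alpha_mean: np.ndarray  # posterior mean locus effect (0 when excluded)
    inclusion_prob: np.ndarray
    q_value: np.ndarray
    fst: np.ndarray  # posterior mean of the locus's mean F_ij
    outlier: np.ndarray  # bool at the requested FDR
    fdr: float
    beta_mean: np.ndarray
    diagnostics: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "alpha": self.alpha_mean,
                "inclusion_prob": self.inclusion_prob,
                "q_value": self.q_value,
                "fst": self.fst,
                "outlier": self.outlier,
            }
        )


def allele_counts_by_group(G: GenotypeMatrix, groups: dict[str, list[str]]):
    """Per-group alternate-allele and total allele counts per SNP.

    Returns ``(alt, total)`` integer arrays of shape (n_groups, n_snps);
    counts cover non-missing calls only.  Empty groups are rejected.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    alt = np.zeros((len(groups), G.n_snps), dtype=np.int64)
    total = np.zeros_like(alt)
    idx = {s: i for i, s in enumerate(G.samples)}
    for gi, (name, ids) in enumerate(groups.items()):
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        rows = [idx[s] for s in ids]
        sub = G.calls[rows]
        obs = sub != MISSING
        alt[gi] = np.where(obs, sub, 0).sum(axis=0)
        total[gi] = 2 * obs.sum(axis=0)
    return alt, total


def _loglik(alt, total, p, alpha, beta):
    """Beta-binomial log-likelihood per (group, locus), summed over groups.

    theta_ij = (1 - F_ij)/F_ij with logit(F_ij) = alpha_i + beta_j.
    """
    F = expit(alpha[None, :] + beta[:, None])
    F = np.clip(F, 1e-9, 1 - 1e-9)
    theta = (1.0 - F) / F
    a = theta * p[None, :]
    b = theta * (1.0 - p[None, :])
    ll = (
        gammaln(alt + a)
        + gammaln(total - alt + b)
        - gammaln(total + a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )
    return ll.sum(axis=0)  # per locus


def bayescan_fit(
    alt: np.ndarray,
    total: np.ndarray,
    snp_ids: list[str] | None = None,
    prior_odds: float = 10.0,
    chain: ChainParams | None = None,
    seed: int = 0,
    fdr: float = 0.05,
    alpha_prior_sd: float = 3.0,
    beta_prior_mean: float = -1.0,
    beta_prior_sd: float = 1.8,
) -> OutlierScanResult:
    """Reversible-jump MCMC over locus effects; declares outliers at the
    given Bayesian FDR.

    Each sweep updates the ancestral frequencies ``p_i`` (random walk on
    the logit scale, uniform prior on p), the included locus effects
    ``alpha_i``, the group effects ``beta_j``, and proposes an
    include/exclude jump per locus using the alpha prior as the proposal
    density (so the jump acceptance is the likelihood ratio divided or
    multiplied by the prior odds).
    """
    if chain is None:
        chain = ChainParams()
    alt = np.asarray(alt, dtype=float)
    total = np.asarray(total, dtype=float)
    J, m = alt.shape
    if J < 2:
        raise ValueError("need at least two groups")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    rng = np.random.default_rng(seed)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total.sum(axis=0) > 0, alt.sum(axis=0) / total.sum(axis=0), 0.5)
    p = np.clip(p, 0.01, 0.99)
    alpha = np.zeros(m)
    included = np.zeros(m, dtype=bool)
    beta = np.full(J, beta_prior_mean)

    ll = _loglik(alt, total, p, alpha, beta)  # per locus
    scale_p, scale_a, scale_b = 0.4, 0.6, 0.15

    n_iter = chain.burn_in + chain.n_samples * chain.thin
    sum_alpha = np.zeros(m)
    sum_incl = np.zeros(m)
    sum_fst = np.zeros(m)
    sum_beta = np.zeros(J)
    n_kept = 0
    acc_b = prop_b = 0

    for it in range(n_iter):
        # ancestral frequencies: logit RW, uniform prior on p => Jacobian p(1-p)
        lp = np.log(p / (1 - p))
        lp_new = lp + scale_p * rng.standard_normal(m)
        p_new = expit(lp_new)
        ll_new = _loglik(alt, total, p_new, alpha, beta)
        log_acc = (ll_new - ll) + np.log(p_new * (1 - p_new)) - np.log(p * (1 - p))
        take = np.log(rng.random(m)) < log_acc
        p = np.where(take, p_new, p)
        ll = np.where(take, ll_new, ll)

        # locus effects for included loci: Gaussian RW
        if included.any():
            a_new = np.where(
                included, alpha + scale_a * rng.standard_normal(m), alpha
            )
            ll_new = _loglik(alt, total, p, a_new, beta)
            log_acc = (
                (ll_new - ll)
                + (alpha**2 - a_new**2) / (2 * alpha_prior_sd**2)
            )
            take = included & (np.log(rng.random(m)) < log_acc)
            alpha = np.where(take, a_new, alpha)
            ll = np.where(take, ll_new, ll)

        # reversible jump: propose toggling every locus, proposal = prior
        a_prop = np.where(
            included, 0.0, alpha_prior_sd * rng.standard_normal(m)
        )
        ll_new = _loglik(alt, total, p, a_prop, beta)
        log_po = np.log(prior_odds)
        log_acc = np.where(
            included,
            (ll_new - ll) + log_po,  # death: remove alpha
            (ll_new - ll) - log_po,  # birth: add alpha
        )
        take = np.log(rng.random(m)) < log_acc
        alpha = np.where(take, a_prop, alpha)
        included = np.where(take, ~included, included)
        ll = np.where(take, ll_new, ll)

        # group effects: one-at-a-time RW using the full likelihood
        for j in range(J):
            b_new = beta.copy()
            b_new[j] += scale_b * rng.standard_normal()
            ll_new = _loglik(alt, total, p, alpha, b_new)
            log_acc = (
                (ll_new.sum() - ll.sum())
                + ((beta[j] - beta_prior_mean) ** 2 - (b_new[j] - beta_prior_mean) ** 2)
                / (2 * beta_prior_sd**2)
            )
            prop_b += 1
            if np.log(rng.random()) < log_acc:
                beta = b_new
                ll = ll_new
                acc_b += 1

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            sum_alpha += alpha
            sum_incl += included
            F = expit(alpha[None, :] + beta[:, None]).mean(axis=0)
            sum_fst += F
            sum_beta += beta
            n_kept += 1

    incl_prob = sum_incl / n_kept
    alpha_mean = sum_alpha / n_kept
    fst_mean = sum_fst / n_kept
    beta_mean = sum_beta / n_kept

    # Bayesian q-value: mean neutrality probability over loci ranked at or
    # above each locus's inclusion probability
    order = np.argsort(-incl_prob, kind="stable")
    neutral = 1.0 - incl_prob
    cum_mean = np.cumsum(neutral[order]) / np.arange(1, m + 1)
    qval = np.empty(m)
    # loci tied on inclusion probability share the q-value of the last tie
    sorted_incl = incl_prob[order]
    for rank, li in enumerate(order):
        last_tie = np.searchsorted(-sorted_incl, -sorted_incl[rank], side="right") - 1
        qval[li] = cum_mean[last_tie]
    outlier = qval <= fdr

    if incl_prob.max() < 1.5 / (1.0 + prior_odds) and incl_prob.min() > 0:
        mixing = "inclusion probabilities all near the prior; chain may not mix"
    else:
        mixing = "ok"
    diagnostics = {
        "beta_acceptance": acc_b / max(prop_b, 1),
        "n_kept": n_kept,
        "mixing": mixing,
    }
    if mixing != "ok":
        warnings.warn(mixing)
    return OutlierScanResult(
        snp_ids=list(snp_ids),
        alpha_mean=alpha_mean,
        inclusion_prob=incl_prob,
        q_value=qval,
        fst=fst_mean,
        outlier=outlier,
        fdr=fdr,
        beta_mean=beta_mean,
        diagnostics=diagnostics,
    )


def scan_outliers(
    G: GenotypeMatrix,
    groups: dict[str, list[str]],
    snp_ids: list[str] | None = None,
    **kwargs,
) -> OutlierScanResult:
    """Convenience wrapper: allele counts from a genotype matrix, then
    :func:`bayescan_fit`."""
    alt, total = allele_counts_by_group(G, groups)
    return bayescan_fit(alt, total, snp_ids=snp_ids or list(G.snp_ids), **kwargs)


# ---------------------------------------------------------------------------
# Gene-window annotation
# ---------------------------------------------------------------------------

def annotate_windows(
    outlier_snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 200_000,
) -> pd.DataFrame:
    """Annotate outlier SNPs with genes in a +/- ``flank`` bp window.

    ``outlier_snps`` needs columns snp, scaffold, pos; ``genes`` needs
    scaffold, start, end, name (1-based inclusive).  A gene is reported
    when its interval overlaps the closed window
    ``[max(1, pos - flank), pos + flank]`` by at least one base; genes on
    other scaffolds are never reported.  SNPs without a position are
    skipped with a warning.
    """
    records = []
    for _, snp in outlier_snps.iterrows():
        if pd.isna(snp.get("pos")) or pd.isna(snp.get("scaffold")):
            warnings.warn(f"SNP {snp.get('snp')} lacks a position; skipped")
            continue
        pos = int(snp["pos"])
        lo = max(1, pos - flank)
        hi = pos + flank
        hits = genes[
            (genes["scaffold"] == snp["scaffold"])
            & (genes["start"] <= hi)
            & (genes["end"] >= lo)
        ]
        records.append(
            {
                "snp": snp["snp"],
                "scaffold": snp["scaffold"],
                "pos": pos,
                "window_start": lo,
                "window_end": hi,
                "genes": ",".join(hits["name"].tolist()),
                "n_genes": len(hits),
            }
        )
    return pd.DataFrame(
        records,
        columns=["snp", "scaffold", "pos", "window_start", "window_end", "genes", "n_genes"],
    )
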