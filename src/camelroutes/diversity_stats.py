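"""Diversity and differentiation statistics for diploid biallelic SNPs.

Implements the summary statistics of a classical population-genomic
survey: observed and unbiased expected heterozygosity, inbreeding
coefficients, rarefaction-standardized allelic richness, Welch's t test
for group contrasts, pairwise FST (Weir & Cockerham's 1984 theta as the
multi-locus ratio of sums, with an AMOVA-based phi as a secondary
estimator) with permutation significance, and a three-level hierarchical
AMOVA (among populations / among individuals within populations / within
individuals).

Missing data are handled per SNP with pairwise-complete counts.  Negative
variance components and FST estimates are reported as computed, not
truncated (a ``truncate`` flag is available where relevant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from camelroutes.genotype_io import MISSING, GenotypeMatrix


def _masked(G: GenotypeMatrix) -> np.ma.MaskedArray:
    return np.ma.masked_equal(G.calls.astype(float), float(MISSING))


# ---------------------------------------------------------------------------
# Heterozygosity and FIS
# ---------------------------------------------------------------------------

def per_locus_heterozygosity(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP expected and observed heterozygosity over one group.

    Ho is the heterozygote fraction among non-missing calls; He is the
    unbiased gene diversity ``(2n/(2n-1)) * (1 - p^2 - q^2)`` with n the
    number of non-missing diploids.  SNPs with fewer than 2 calls yield
    NaN in both.

    Returns ``(He, Ho)`` arrays of length n_snps.
    """
    calls = _masked(G)
    n = calls.count(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = calls.mean(axis=0).filled(np.nan) / 2.0
        ho = (calls == 1).sum(axis=0) / n
    he = (2 * n / (2 * n - 1)) * (1 - p**2 - (1 - p) ** 2)
    he = np.where(n >= 2, he, np.nan)
    ho = np.where(n >= 2, np.asarray(ho, dtype=float), np.nan)
    return np.asarray(he, dtype=float), ho


def inbreeding_coefficient(he: np.ndarray, ho: np.ndarray) -> np.ndarray:
    """Per-SNP FIS = 1 - Ho/He; undefined (NaN) where He is 0 or missing."""
    he = np.asarray(he, dtype=float)
    ho = np.asarray(ho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = 1.0 - ho / he
    return np.where((he > 0) & np.isfinite(he) & np.isfinite(ho), fis, np.nan)


# ---------------------------------------------------------------------------
# Allelic richness (Hurlbert rarefaction)
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def allelic_richness(G: GenotypeMatrix, groups: dict[str, list[str]],
                     g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per group.

    Hurlbert rarefaction: the expected number of distinct alleles in a
    draw of ``g`` allele copies, ``AR = sum_a [1 - C(N - N_a, g)/C(N, g)]``
    where ``N`` is the group's non-missing allele count at a SNP and
    ``N_a`` the count of allele a.  The rarefaction size defaults to the
    smallest non-missing allele count over all groups and SNPs and must
    be >= 2.  Both AR (in [1, 2]) and AR - 1 are reported, averaged over
    SNPs.
    """
    subsets = {name: G.take_samples(ids) for name, ids in groups.items()}
    counts = {}
    for name, sub in subsets.items():
        calls = _masked(sub)
        n_alleles = 2 * calls.count(axis=0)
        alt = np.asarray(calls.sum(axis=0).filled(0.0))
        counts[name] = (np.asarray(n_alleles, dtype=float), alt)
    if g is None:
        g = int(min(c[0].min() for c in counts.values()))
    if g < 2:
        raise ValueError(f"rarefaction size must be >= 2, got {g}")
    rows = []
    for name, (N, alt) in counts.items():
        ref = N - alt
        with np.errstate(invalid="ignore"):
            ar = np.full(len(N), np.nan)
            ok = N >= g
            terms = np.zeros(len(N))
            for Na in (alt, ref):
                keep = np.exp(
                    np.where(N - Na >= g, _log_comb(N - Na, g) - _log_comb(N, g), -np.inf)
                )
                terms += np.where(Na > 0, 1.0 - np.where(N - Na >= g, keep, 0.0), 0.0)
            ar[ok] = terms[ok]
        rows.append(
            {
                "group": name,
                "rarefaction_size": g,
                "AR": float(np.nanmean(ar)),
                "AR_minus_1": float(np.nanmean(ar) - 1.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom.  NaNs are dropped; requires >= 2 values per side and a
    positive variance on at least one side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(calls: np.ndarray, membership: list[np.ndarray]):
    """Per-SNP Weir-Cockerham (1984) variance components a, b, c.

    ``membership`` lists index arrays, one per population.  SNPs where any
    population has < 1 call or the average sample size is <= 1 are NaN.
    """
    r = len(membership)
    m = calls.shape[1]
    n_i = np.empty((r, m))
    p_i = np.empty((r, m))
    h_i = np.empty((r, m))
    for k, idx in enumerate(membership):
        sub = np.ma.masked_equal(calls[idx].astype(float), float(MISSING))
        n_i[k] = sub.count(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_i[k] = sub.mean(axis=0).filled(np.nan) / 2.0
            h_i[k] = np.asarray((sub == 1).sum(axis=0) / n_i[k])
    valid = (n_i >= 1).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_i.sum(axis=0) / r
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    valid &= nbar > 1
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def weir_cockerham_fst(G: GenotypeMatrix, groups: dict[str, list[str]]) -> float:
    """Multi-locus Weir-Cockerham theta, as the ratio of summed variance
    components over loci (monomorphic loci contribute to the denominator)."""
    idx = {s: i for i, s in enumerate(G.samples)}
    membership = [np.array([idx[s] for s in ids]) for ids in groups.values()]
    a, b, c = _wc_components(G.calls, membership)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0:
        raise ValueError("no polymorphism: theta undefined")
    return float(num / den)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA variance decomposition."""

    components: dict[str, float]  # among_populations / among_individuals / within_individuals
    percentages: dict[str, float]
    phi_st: float
    p_values: dict[str, float]
    n_permutations: int


def _amova_components(calls: np.ndarray, membership: list[np.ndarray]):
    """Summed-over-SNPs variance components of the three-level AMOVA.

    Per SNP, haplotype allele indicators are decomposed into sums of
    squares within individuals, among individuals within populations and
    among populations, converted to variance components by the standard
    moment equations, and summed over SNPs.
    """
    sig_ap = sig_ai = sig_wi = 0.0
    m = calls.shape[1]
    for j in range(m):
        g_pop = []
        for idx in membership:
            g = calls[idx, j].astype(float)
            g = g[g != MISSING]
            if len(g) >= 1:
                g_pop.append(g)
        P = len(g_pop)
        N = sum(len(g) for g in g_pop)
        if P < 2 or N <= P:
            continue
        tot_mean = sum(g.sum() for g in g_pop) / (2.0 * N)
        ss_wi = ss_ai = ss_ap = 0.0
        for g in g_pop:
            pop_mean = g.mean() / 2.0
            ss_wi += 0.5 * np.sum(g == 1)
            ss_ai += np.sum(2.0 * (g / 2.0 - pop_mean) ** 2)
            ss_ap += 2.0 * len(g) * (pop_mean - tot_mean) ** 2
        ms_wi = ss_wi / N
        ms_ai = ss_ai / (N - P)
        ms_ap = ss_ap / (P - 1)
        n_hap = np.array([2.0 * len(g) for g in g_pop])
        nc = (n_hap.sum() - (n_hap**2).sum() / n_hap.sum()) / (P - 1)
        sig_wi += ms_wi
        sig_ai += (ms_ai - ms_wi) / 2.0
        sig_ap += (ms_ap - ms_ai) / nc
    return sig_ap, sig_ai, sig_wi


def amova(
    G: GenotypeMatrix,
    groups: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    truncate: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA with permutation p-values.

    Levels: among populations / among individuals within populations /
    within individuals.  P-values: the among-population component is
    tested by permuting individuals among populations; the among-
    individual component by permuting genotype rows within populations
    against a re-pairing of alleles is not attempted — instead it is
    tested by permuting individuals within the pooled sample, the
    standard genotype-level approximation.  ``p = (1 + #{perm >= obs}) /
    (1 + n_perm)``.
    """
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    idx = {s: i for i, s in enumerate(G.samples)}
    membership = [np.array([idx[s] for s in ids]) for ids in groups.values()]
    sig_ap, sig_ai, sig_wi = _amova_components(G.calls, membership)
    total = sig_ap + sig_ai + sig_wi
    if total == 0:
        raise ValueError("total variance is zero (no segregating variation)")
    comps = {
        "among_populations": sig_ap,
        "among_individuals": sig_ai,
        "within_individuals": sig_wi,
    }
    if truncate:
        comps = {k: max(v, 0.0) for k, v in comps.items()}
        total = sum(comps.values()) or total
    pct = {k: 100.0 * v / total for k, v in comps.items()}

    rng = np.random.default_rng(seed)
    all_idx = np.concatenate(membership)
    sizes = [len(mi) for mi in membership]
    hits_ap = hits_ai = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        pm, start = [], 0
        for s in sizes:
            pm.append(perm[start : start + s])
            start += s
        p_ap, p_ai, _ = _amova_components(G.calls, pm)
        if p_ap >= sig_ap:
            hits_ap += 1
        if p_ai >= sig_ai:
            hits_ai += 1
    p_values = {
        "among_populations": (1 + hits_ap) / (1 + n_perm),
        "among_individuals": (1 + hits_ai) / (1 + n_perm),
    }
    phi = sig_ap / total if total else np.nan
    return AmovaResult(
        components=comps,
        percentages=pct,
        phi_st=float(phi),
        p_values=p_values,
        n_permutations=n_perm,
    )


def amova_fst(G: GenotypeMatrix, groups: dict[str, list[str]]) -> float:
    """AMOVA-based (phi-style) FST: among-population share of total
    variance; the secondary differentiation estimator."""
    idx = {s: i for i, s in enumerate(G.samples)}
    membership = [np.array([idx[s] for s in ids]) for ids in groups.values()]
    sig_ap, sig_ai, sig_wi = _amova_components(G.calls, membership)
    total = sig_ap + sig_ai + sig_wi
    if total == 0:
        raise ValueError("total variance is zero")
    return float(sig_ap / total)


# ---------------------------------------------------------------------------
# Pairwise FST with permutation significance
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    group_a: str
    group_b: str
    estimator: str
    estimate: float
    p_value: float
    n_permutations: int


def pairwise_fst(
    G: GenotypeMatrix,
    groups: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    estimator: str = "wc",
    min_group_size: int = 3,
) -> list[FstResult]:
    """All pairwise FST values with permutation p-values.

    Pairs where either group has fewer than ``min_group_size`` members
    are skipped (reported as NaN with a warning).  Significance permutes
    individuals between the two groups; ``p = (1 + #{perm >= obs}) /
    (1 + n_perm)``.
    """
    est_fun = {"wc": weir_cockerham_fst, "amova": amova_fst}[estimator]
    rng = np.random.default_rng(seed)
    names = list(groups)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ids_a, ids_b = list(groups[a]), list(groups[b])
            if len(ids_a) < min_group_size or len(ids_b) < min_group_size:
                warnings.warn(
                    f"pair ({a}, {b}) skipped: fewer than {min_group_size} "
                    "individuals in a group"
                )
                results.append(FstResult(a, b, estimator, np.nan, np.nan, 0))
                continue
            sub = G.take_samples(ids_a + ids_b)
            obs = est_fun(sub, {a: ids_a, b: ids_b})
            pooled = np.array(ids_a + ids_b)
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                pg = {a: list(perm[: len(ids_a)]), b: list(perm[len(ids_a) :])}
                if est_fun(sub, pg) >= obs:
                    hits += 1
            p = (1 + hits) / (1 + n_perm)
            results.append(FstResult(a, b, estimator, obs, p, n_perm))
    return results


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def diversity_summary(G: GenotypeMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Mean +/- SD of He, Ho and FIS over SNPs, per group."""
    rows = []
    for name, ids in groups.items():
        sub = G.take_samples(list(ids))
        he, ho = per_locus_heterozygosity(sub)
        fis = inbreeding_coefficient(he, ho)
        rows.append(
            {
                "group": name,
                "n_ind": len(ids),
                "He_mean": np.nanmean(he),
                "He_sd": np.nanstd(he, ddof=1),
                "Ho_mean": np.nanmean(ho),
                "Ho_sd": np.nanstd(ho, ddof=1),
                "FIS_mean": np.nanmean(fis),
                "FIS_sd": np.nanstd(fis, ddof=1),
            }
        )
    return pd.DataFrame(rows)


def groups_from_metadata(meta: pd.DataFrame, samples: list[str],
                         group_by: str) -> dict[str, list[str]]:
    """Build group -> sample-id lists from a metadata column, restricted
    to the given samples and preserving their order."""
    sub = meta[meta["sample"].isin(samples)]
    lookup = dict(zip(sub["sample"], sub[group_by]))
    groups: dict[str, list[str]] = {}
    for s in samples:
        if s in lookup:
            groups.setdefault(str(lookup[s]), []).append(s)
    return groups
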