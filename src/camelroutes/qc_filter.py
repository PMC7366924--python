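"""PLINK-style QC filter cascade with identity-by-state relatedness pruning.

The cascade applies, in this fixed order:

1. individual missingness (``--mind``): drop individuals with *more than*
   the threshold fraction of missing genotypes;
2. minor allele frequency (``--maf``): drop SNPs with MAF strictly below
   the threshold (kept at equality);
3. SNP missingness (``--geno``): drop SNPs with *more than* the threshold
   fraction of missing calls;
4. relatedness: pairs of individuals closer than the IBS-distance cutoff
   are treated as near-duplicates and pruned down to one member per
   connected group.

Strict-inequality semantics for steps 1 and 3 follow PLINK's "more than"
wording; MAF keeps sites at exact equality.  The order matters (MAF is
computed before low-call-rate SNPs are dropped) and is recorded in the
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from camelroutes.genotype_io import MISSING, GenotypeMatrix


@dataclass
class FilterParams:
    """Thresholds of the filter cascade (defaults: the standard stringent
    ddRAD settings --mind 0.25, --maf 0.01, --geno 0.25, IBS cutoff 0.05)."""

    max_ind_missing: float = 0.25
    min_maf: float = 0.01
    max_geno_missing: float = 0.25
    ibs_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_ind_missing", "min_maf", "max_geno_missing", "ibs_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class FilterReport:
    """Per-step record of what the cascade removed, in order."""

    steps: list[dict] = field(default_factory=list)

    def record(self, step: str, removed_individuals=(), removed_snps=()) -> None:
        self.steps.append(
            {
                "step": step,
                "n_individuals_removed": len(removed_individuals),
                "n_snps_removed": len(removed_snps),
                "removed_individuals": list(removed_individuals),
                "removed_snps": list(removed_snps),
            }
        )

    @property
    def order(self) -> list[str]:
        return [s["step"] for s in self.steps]

    def to_dict(self) -> dict:
        return {"order": self.order, "steps": self.steps}


def filter_individual_missingness(G: GenotypeMatrix, max_ind_missing: float):
    """Drop individuals with missing fraction strictly above the threshold."""
    rates = G.individual_missing_rate()
    drop = [s for s, r in zip(G.samples, rates) if r > max_ind_missing]
    if len(drop) == G.n_samples:
        raise ValueError("individual-missingness filter would remove every individual")
    return G.drop_samples(drop), drop


def filter_maf(G: GenotypeMatrix, min_maf: float):
    """Drop SNPs with minor allele frequency strictly below the threshold.

    MAF is computed on non-missing calls; SNPs with zero non-missing calls
    are dropped with a warning.
    """
    maf = G.maf()
    nocall = np.isnan(maf)
    if nocall.any():
        warnings.warn(f"{int(nocall.sum())} SNPs have no non-missing calls; dropped")
    keep = ~nocall & (maf >= min_maf)
    drop = [sid for sid, k in zip(G.snp_ids, keep) if not k]
    return G.take_snps(keep), drop


def filter_genotype_missingness(G: GenotypeMatrix, max_geno_missing: float):
    """Drop SNPs with missing fraction strictly above the threshold."""
    rates = G.snp_missing_rate()
    keep = rates <= max_geno_missing
    drop = [sid for sid, k in zip(G.snp_ids, keep) if not k]
    return G.take_snps(keep), drop


def ibs_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Symmetric identity-by-state distance matrix.

    For a pair of individuals the per-SNP shared-allele fraction is
    ``(2 - |g_i - g_j|) / 2``; the distance is one minus its mean over
    pairwise-complete SNPs.  Pairs with zero overlapping SNPs get NaN
    (warned).
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    n = G.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i] - calls[i + 1 :])  # (n-i-1, m) with NaN where incomplete
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = 1.0 - np.nanmean((2.0 - diff) / 2.0, axis=1)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    if np.isnan(D).any():
        warnings.warn("some pairs share no genotyped SNPs; their distance is NaN")
    return D


def prune_relatives(dist: np.ndarray, samples: list[str], cutoff: float,
                    missing_rate=None) -> list[str]:
    """Greedily prune near-duplicates (pairs with distance < cutoff).

    While any below-cutoff pair remains, remove the member with higher
    missingness (ties: lexicographically later id).  Returns removed ids.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(samples)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match sample list")
    if missing_rate is None:
        missing_rate = np.zeros(n)
    missing_rate = np.asarray(missing_rate, dtype=float)
    alive = set(range(n))
    removed: list[str] = []
    while True:
        pairs = [
            (i, j)
            for i in alive
            for j in alive
            if i < j and np.isfinite(dist[i, j]) and dist[i, j] < cutoff
        ]
        if not pairs:
            break
        # pick the vertex involved in below-cutoff pairs that is "worst":
        # highest missingness, then lexicographically latest id
        candidates = sorted({v for p in pairs for v in p})
        victim = max(candidates, key=lambda v: (missing_rate[v], samples[v]))
        alive.discard(victim)
        removed.append(samples[victim])
    return removed


def run_filter_cascade(G: GenotypeMatrix, params: FilterParams | None = None):
    """Apply the full cascade; returns ``(filtered, FilterReport)``."""
    if params is None:
        params = FilterParams()
    report = FilterReport()

    G1, dropped_ind = filter_individual_missingness(G, params.max_ind_missing)
    report.record("individual_missingness", removed_individuals=dropped_ind)

    G2, dropped_maf = filter_maf(G1, params.min_maf)
    report.record("maf", removed_snps=dropped_maf)

    G3, dropped_geno = filter_genotype_missingness(G2, params.max_geno_missing)
    report.record("genotype_missingness", removed_snps=dropped_geno)

    if G3.n_samples >= 2 and G3.n_snps >= 1:
        D = ibs_distance_matrix(G3)
        removed = prune_relatives(
            D, G3.samples, params.ibs_cutoff, G3.individual_missing_rate()
        )
    else:
        removed = []
    G4 = G3.drop_samples(removed)
    report.record("relatedness", removed_individuals=removed)

    if G4.n_samples == 0 or G4.n_snps == 0:
        raise ValueError("filter cascade removed everything")
    return G4, report
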