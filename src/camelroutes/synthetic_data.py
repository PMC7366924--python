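"""Synthetic-data generators for every input the pipeline consumes.

Each generator has known ground truth, so downstream stages can be tested
for parameter recovery without any external data:

* :func:`simulate_island_genotypes` — Balding-Nichols island model with an
  analytic target FST (population allele frequencies Beta-distributed
  around a shared ancestral frequency);
* :func:`inject_relatives` — plant near-duplicate individuals to exercise
  identity-by-state relatedness pruning;
* :func:`simulate_read_assignments` — per-individual dual-reference read
  counts with a baseline cross-mapping fraction and elevated fractions in
  planted hybrids;
* :func:`simulate_grid_genotypes` — spatially structured allele
  frequencies from a logistic Gaussian Markov random field on a deme
  grid, with controllable corridors and barriers;
* :func:`simulate_rad_loci` — short RAD-locus alignments with a chosen
  number of segregating sites and a diverged outgroup.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from camelroutes.demographic_prep import IUPAC_DIPLOID, RadLocus, RadLocusSet
from camelroutes.genotype_io import MISSING, GenotypeMatrix, orient_minor
from camelroutes.migration_surface import DemeGrid, build_deme_grid

# Country codes used to label simulated island-model populations;
# populations alternate between African and Asian countries so that
# continental contrasts exist on simulated metadata for any n_pops >= 2.
_AFRICA = ["DZ", "EG", "ET", "KE", "LY", "ML", "MA", "NE", "NG", "SD", "TD", "TN"]
_ASIA = ["AE", "IR", "JO", "KZ", "OM", "PK", "QA", "SA", "SY", "YE"]
_COUNTRY_CYCLE = [c for pair in zip(_AFRICA, _ASIA) for c in pair]


@dataclass
class IslandModelSpec:
    """Balding-Nichols island model: ``n_pops`` populations of
    ``n_per_pop`` diploids at ``n_snps`` biallelic SNPs with target
    differentiation ``fst``."""

    n_pops: int = 2
    n_per_pop: int = 50
    n_snps: int = 5000
    fst: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    ind_missing_rate: float = 0.0
    geno_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("ind_missing_rate", "geno_missing_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class HybridSimSpec:
    """Dual-reference read-assignment simulation with planted hybrids."""

    n_ind: int = 50
    mean_reads: int = 100_000
    baseline_frac: float = 0.01
    hybrid_ids: tuple[str, ...] = ()
    hybrid_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_reads <= 0:
            raise ValueError("mean_reads must be positive (no assignable reads)")
        if not 0.0 <= self.baseline_frac < 1.0:
            raise ValueError("baseline_frac must be in [0, 1)")
        if not 0.0 <= self.hybrid_frac < 1.0:
            raise ValueError("hybrid_frac must be in [0, 1)")
        if self.hybrid_ids and self.hybrid_frac <= self.baseline_frac:
            raise ValueError("hybrid_frac must exceed baseline_frac")


@dataclass
class GridModelSpec:
    """Spatial stepping-stone simulation on a deme grid.

    ``migration_field`` may be a positive scalar, an array of per-deme
    rates, or a callable ``(lon, lat) -> m`` evaluated at deme centres.
    ``within_deme_diversity`` is the GMRF's local variance scale ``q``.
    """

    polygon: Polygon
    n_demes: int = 25
    migration_field: object = 1.0
    within_deme_diversity: float = 1.0
    n_per_deme: int = 4
    n_snps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_deme_diversity <= 0:
            raise ValueError("within_deme_diversity must be positive")
        if self.n_per_deme < 1 or self.n_snps < 1:
            raise ValueError("n_per_deme and n_snps must be >= 1")


# ---------------------------------------------------------------------------
# Island model
# ---------------------------------------------------------------------------

def simulate_island_genotypes(spec: IslandModelSpec):
    """Balding-Nichols genotypes with known target FST.

    Ancestral frequency p ~ Uniform(maf_range); each population's
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) for F > 0 (identical to p at
    F = 0); genotypes ~ Binomial(2, population frequency).  Missing calls
    are inserted uniformly at random at ``geno_missing_rate``, and a
    fraction ``ind_missing_rate`` of individuals additionally get half of
    their calls masked (planted high-missingness individuals for the QC
    stage).  Population labels cycle through African then Asian country
    codes so continent groupings exist on the metadata.

    Returns ``(GenotypeMatrix, metadata DataFrame, SNP table DataFrame)``.
    """
    rng = np.random.default_rng(spec.seed)
    K, n, m, F = spec.n_pops, spec.n_per_pop, spec.n_snps, spec.fst
    p_anc = rng.uniform(*spec.maf_range, size=m)
    if F > 0:
        scale = (1.0 - F) / F
        pop_freq = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(K, m))
    else:
        pop_freq = np.broadcast_to(p_anc, (K, m)).copy()
    calls = np.empty((K * n, m), dtype=np.int8)
    for k in range(K):
        calls[k * n : (k + 1) * n] = rng.binomial(2, pop_freq[k], size=(n, m))

    if spec.geno_missing_rate > 0:
        mask = rng.random(calls.shape) < spec.geno_missing_rate
        calls[mask] = MISSING
    if spec.ind_missing_rate > 0:
        high = rng.random(K * n) < spec.ind_missing_rate
        mask = rng.random(calls.shape) < 0.5
        calls[np.outer(high, np.ones(m, dtype=bool)) & mask] = MISSING

    countries = _COUNTRY_CYCLE[:K] if K <= len(_COUNTRY_CYCLE) else None
    samples, meta_rows = [], []
    for k in range(K):
        country = countries[k] if countries else "XX"
        continent = "Africa" if (countries and country in _AFRICA) else "Asia"
        for i in range(n):
            sid = f"{country}{k:02d}_{i:03d}"
            samples.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "country": country,
                    "continent": continent,
                    "population": f"pop{k:02d}",
                    "lon": np.nan,
                    "lat": np.nan,
                }
            )
    snp_ids = [f"snp{j:06d}" for j in range(m)]
    bases = np.array(list("ACGT"))
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    snp_table = pd.DataFrame(
        {
            "snp": snp_ids,
            "scaffold": [f"scaf{j % 20:02d}" for j in range(m)],
            "pos": [10_000 * (j // 20) + 1 for j in range(m)],
            "allele1": bases[a_idx],
            "allele2": bases[b_idx],
        }
    )
    G = GenotypeMatrix(samples, snp_ids, calls)
    # fix the package-wide minor-allele orientation at generation time
    G, snp_table = orient_minor(G, snp_table)
    return G, pd.DataFrame(meta_rows), snp_table


def inject_relatives(
    G: GenotypeMatrix, pairs, copy_error: float = 0.0, seed: int = 0
) -> GenotypeMatrix:
    """Turn the second member of each id pair into a near-copy of the first.

    Each non-missing genotype of the copy is independently replaced, with
    probability ``copy_error``, by a different random call.  Overlapping
    pairs are rejected.
    """
    if not 0.0 <= copy_error <= 1.0:
        raise ValueError("copy_error must be in [0, 1]")
    used: set[str] = set()
    for a, b in pairs:
        if a in used or b in used or a == b:
            raise ValueError(f"overlapping or degenerate pair ({a}, {b})")
        used |= {a, b}
    rng = np.random.default_rng(seed)
    out = G.copy()
    idx = {s: i for i, s in enumerate(out.samples)}
    for a, b in pairs:
        src = out.calls[idx[a]].copy()
        perturb = (rng.random(out.n_snps) < copy_error) & (src != MISSING)
        shifted = (src + rng.integers(1, 3, size=out.n_snps)) % 3
        src[perturb] = shifted[perturb]
        out.calls[idx[b]] = src
    return out


# ---------------------------------------------------------------------------
# Read assignments (hybrid screen input)
# ---------------------------------------------------------------------------

def simulate_read_assignments(spec: HybridSimSpec) -> pd.DataFrame:
    """Per-individual dual-reference read counts.

    Totals ~ Poisson(mean_reads); the alternate-reference count is
    Binomial(total, f) with f = ``hybrid_frac`` for planted hybrids and
    ``baseline_frac`` otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    hybrid = set(spec.hybrid_ids)
    samples = [f"ind{i:03d}" for i in range(spec.n_ind)]
    unknown = hybrid - set(samples)
    if unknown:
        raise ValueError(f"hybrid_ids not in cohort: {sorted(unknown)}")
    totals = rng.poisson(spec.mean_reads, size=spec.n_ind)
    totals = np.maximum(totals, 1)  # Poisson zeros would be unscreenable
    fracs = np.array(
        [spec.hybrid_frac if s in hybrid else spec.baseline_frac for s in samples]
    )
    alt = rng.binomial(totals, fracs)
    return pd.DataFrame(
        {"sample": samples, "reads_primary": totals - alt, "reads_alt": alt}
    )


# ---------------------------------------------------------------------------
# Spatial grid model
# ---------------------------------------------------------------------------

def _resolve_field(fieldspec, grid: DemeGrid) -> np.ndarray:
    if callable(fieldspec):
        vals = np.array([fieldspec(c[0], c[1]) for c in grid.centres], dtype=float)
    else:
        vals = np.broadcast_to(np.asarray(fieldspec, dtype=float), (grid.n_demes,)).copy()
    if (vals <= 0).any():
        raise ValueError("migration rates must be positive")
    return vals


def simulate_grid_genotypes(spec: GridModelSpec):
    """Spatially structured genotypes from a logistic GMRF on a deme grid.

    Per SNP, latent per-deme values are drawn from a Gaussian Markov
    random field with precision ``L_m + diag(1/q)`` (``L_m`` the
    migration-weighted graph Laplacian, matching the edge-conductance
    convention of the migration-surface stage), centred on the logit of a
    random ancestral frequency; the logistic transform maps them to deme
    allele frequencies and genotypes are Binomial(2, frequency).  High
    migration couples neighbouring demes tightly (weak isolation by
    distance), low-m bands act as barriers.

    Returns ``(GenotypeMatrix, metadata DataFrame, DemeGrid)`` with
    samples assigned to their demes.
    """
    rng = np.random.default_rng(spec.seed)
    grid = build_deme_grid(spec.polygon, spec.n_demes)
    d = grid.n_demes
    m_field = _resolve_field(spec.migration_field, grid)
    q = float(spec.within_deme_diversity)

    L = np.zeros((d, d))
    for a, b in grid.edges:
        c = 0.5 * (m_field[a] + m_field[b])
        L[a, a] += c
        L[b, b] += c
        L[a, b] -= c
        L[b, a] -= c
    Q = L + np.eye(d) / q
    chol = np.linalg.cholesky(Q)

    p_anc = rng.uniform(0.2, 0.8, size=spec.n_snps)
    mu = np.log(p_anc / (1 - p_anc))
    # z = mu + Q^{-1/2} eps, per SNP
    eps = rng.standard_normal((d, spec.n_snps))
    z = mu[None, :] + np.linalg.solve(chol.T, eps)
    freq = 1.0 / (1.0 + np.exp(-z))

    samples, meta_rows = [], []
    calls = np.empty((d * spec.n_per_deme, spec.n_snps), dtype=np.int8)
    assignment = {}
    row = 0
    for a in range(d):
        lon, lat = grid.centres[a]
        for i in range(spec.n_per_deme):
            sid = f"deme{a:03d}_{i:02d}"
            samples.append(sid)
            assignment[sid] = a
            calls[row] = rng.binomial(2, freq[a], size=spec.n_snps)
            meta_rows.append(
                {
                    "sample": sid,
                    "country": "XX",
                    "continent": "Africa" if lon < 45 else "Asia",
                    "population": f"deme{a:03d}",
                    "lon": lon,
                    "lat": lat,
                }
            )
            row += 1
    grid.assignment = assignment
    snp_ids = [f"gsnp{j:05d}" for j in range(spec.n_snps)]
    G = GenotypeMatrix(samples, snp_ids, calls)
    return G, pd.DataFrame(meta_rows), grid


# ---------------------------------------------------------------------------
# RAD loci
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def simulate_rad_loci(
    n_loci: int = 100,
    locus_len: int = 110,
    snps_per_locus=(4, 6),
    presence: float = 0.85,
    outgroup_divergence: float = 0.0159231,
    n_ind: int = 20,
    seed: int = 0,
) -> RadLocusSet:
    """Short RAD-locus alignments with a diverged outgroup.

    Per locus: a random reference sequence; a number of segregating sites
    drawn uniformly from ``snps_per_locus`` (inclusive range or fixed
    int), with minor-allele counts drawn from a neutral 1/i frequency
    spectrum over the present haplotypes; each individual present with
    probability ``presence`` (at least two always kept).  Ingroup
    individuals are emitted as IUPAC diploid consensus sequences.

    ``outgroup_divergence`` is the target *measured* mean per-site
    divergence between ingroup sequences and the outgroup — the quantity
    the clock calibration uses.  Because segregating sites already
    contribute to that measurement (alternate alleles differ from the
    ancestral base the outgroup carries), the generator plants fixed
    outgroup differences at a rate reduced by each locus's realized
    polymorphism contribution, clamping at zero with a warning when
    polymorphism alone exceeds the target.
    """
    if not 0.0 <= outgroup_divergence <= 1.0:
        raise ValueError("outgroup_divergence must be in [0, 1]")
    if not 0.0 < presence <= 1.0:
        raise ValueError("presence must be in (0, 1]")
    if isinstance(snps_per_locus, int):
        s_lo = s_hi = snps_per_locus
    else:
        s_lo, s_hi = snps_per_locus
    if not 0 <= s_lo <= s_hi <= locus_len:
        raise ValueError("snps_per_locus must lie within [0, locus_len]")
    rng = np.random.default_rng(seed)
    clamped = 0
    loci = []
    for li in range(n_loci):
        ref = rng.integers(0, 4, size=locus_len)
        present = np.flatnonzero(rng.random(n_ind) < presence)
        if len(present) < 2:
            present = rng.choice(n_ind, size=2, replace=False)
        n_hap = 2 * len(present)

        s = int(rng.integers(s_lo, s_hi + 1))
        sites = rng.choice(locus_len, size=s, replace=False) if s else np.array([], int)
        # minor-allele count per site from a neutral (1/i) spectrum
        hap_alt = np.zeros((n_hap, locus_len), dtype=bool)
        for j in sites:
            i_vals = np.arange(1, max(n_hap // 2, 1) + 1)  # folded: minor allele
            counts = rng.choice(i_vals, p=(1.0 / i_vals) / np.sum(1.0 / i_vals))
            carriers = rng.choice(n_hap, size=counts, replace=False)
            hap_alt[carriers, j] = True
        alt_base = (ref + rng.integers(1, 4, size=locus_len)) % 4

        # polymorphism contribution to measured divergence (alt dosage / 2)
        dosage = hap_alt[0::2].astype(int) + hap_alt[1::2].astype(int)
        poly_contrib = float(dosage.sum()) / (2 * len(present))

        target_diffs = outgroup_divergence * locus_len
        k_exp = target_diffs - poly_contrib
        if k_exp < 0:
            clamped += 1
            k_exp = 0.0
        k = int(k_exp) + (1 if rng.random() < (k_exp % 1.0) else 0)
        non_seg = np.setdiff1d(np.arange(locus_len), sites)
        out_seq = ref.copy()
        if k > 0:
            mut = rng.choice(non_seg, size=min(k, len(non_seg)), replace=False)
            out_seq[mut] = (ref[mut] + rng.integers(1, 4, size=len(mut))) % 4

        sequences = {}
        for pi, ind in enumerate(present):
            hap1, hap2 = hap_alt[2 * pi], hap_alt[2 * pi + 1]
            chars = []
            for j in range(locus_len):
                a = _BASES[alt_base[j]] if hap1[j] else _BASES[ref[j]]
                b = _BASES[alt_base[j]] if hap2[j] else _BASES[ref[j]]
                chars.append(IUPAC_DIPLOID[frozenset((a, b))])
            sequences[f"ind{ind:03d}"] = "".join(chars)
        loci.append(
            RadLocus(
                name=f"locus{li:04d}",
                sequences=sequences,
                outgroup="".join(_BASES[b] for b in out_seq),
                n_individuals_total=n_ind,
            )
        )
    if clamped:
        warnings.warn(
            f"{clamped} loci: polymorphism contribution alone exceeds the "
            "divergence target; fixed differences clamped at zero"
        )
    return RadLocusSet(loci)
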