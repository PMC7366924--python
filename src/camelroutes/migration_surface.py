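"""Simplified effective-migration-surface estimation on a deme grid.

The model is the stepping-stone picture behind estimated-effective-
migration-surface (EEMS) methods: a triangular lattice of demes covers the
habitat polygon, each deme carries an effective migration rate ``m`` and a
within-deme diversity ``q``, and the expected genetic dissimilarity
between two demes is the effective resistance between them on the graph
whose edge conductances average the incident demes' ``m``, plus the mean
of their ``q``.  Posterior inference is random-walk Metropolis over
per-deme ``log10 m`` and ``log10 q``.

Two deliberate simplifications relative to the original Voronoi-tile
formulation: the spatial prior is a Gaussian (graph-Laplacian) smoothing
prior on per-deme log-rates, and the likelihood is Gaussian on the
observed between-deme mean dissimilarities with a profiled noise variance
rather than a Wishart on the full matrix.  Both keep the qualitative
surface (corridors/barriers relative to the overall mean) while making
the MCMC far simpler; the absolute scale of ``m`` is reported only after
normalizing each draw to zero mean on the log10 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import Point, Polygon

from camelroutes.genotype_io import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Haversine great-circle distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass
class DemeGrid:
    """Triangular-lattice deme graph clipped to a habitat polygon."""

    centres: np.ndarray  # (d, 2) lon/lat
    edges: list[tuple[int, int]]
    polygon: Polygon
    assignment: dict[str, int] = field(default_factory=dict)  # sample -> deme

    @property
    def n_demes(self) -> int:
        return len(self.centres)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_demes))
        g.add_edges_from(self.edges)
        return g

    def assign_samples(self, meta) -> "DemeGrid":
        """Assign each sample to its nearest deme centre (great-circle)."""
        assignment = {}
        for _, row in meta.iterrows():
            lon, lat = float(row["lon"]), float(row["lat"])
            d = [great_circle_km(lon, lat, c[0], c[1]) for c in self.centres]
            assignment[str(row["sample"])] = int(np.argmin(d))
        self.assignment = assignment
        return self


def _triangular_points(poly: Polygon, h: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = h * math.sqrt(3) / 2
    pts = []
    row = 0
    y = miny
    while y <= maxy + 1e-12:
        x0 = minx + (h / 2 if row % 2 else 0.0)
        x = x0
        while x <= maxx + 1e-12:
            if poly.covers(Point(x, y)):
                pts.append((x, y))
            x += h
        y += dy
        row += 1
    return np.array(pts) if pts else np.empty((0, 2))


def build_deme_grid(poly: Polygon, n_demes: int) -> DemeGrid:
    """Build a connected triangular deme lattice with about ``n_demes``
    demes (within 10% where geometry allows) inside the polygon."""
    if n_demes < 1:
        raise ValueError("n_demes must be >= 1")
    if n_demes == 1:
        c = poly.centroid
        return DemeGrid(np.array([[c.x, c.y]]), [], poly)
    # initial spacing from the area of a triangular lattice cell
    h = math.sqrt(2 * poly.area / (math.sqrt(3) * n_demes))
    best = None
    for scale in np.geomspace(0.5, 2.0, 25):
        pts = _triangular_points(poly, h * scale)
        if len(pts) == 0:
            continue
        err = abs(len(pts) - n_demes)
        if best is None or err < best[0]:
            best = (err, h * scale, pts)
    if best is None:
        raise ValueError("polygon too small to hold any deme")
    _, h_used, pts = best
    edges = []
    tol = 1.05 * h_used
    for i in range(len(pts)):
        d = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1])
        for j in np.flatnonzero((d > 0) & (d <= tol)):
            if i < j:
                edges.append((i, int(j)))
    grid = DemeGrid(pts, edges, poly)
    g = grid.graph()
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError(
            "clipped deme grid is disconnected; use a larger deme count or a "
            "less fragmented polygon"
        )
    if abs(grid.n_demes - n_demes) > max(1, 0.1 * n_demes):
        warnings.warn(
            f"requested {n_demes} demes, lattice holds {grid.n_demes} "
            "(polygon geometry constrains the count)"
        )
    return grid


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def observed_dissimilarity(G: GenotypeMatrix) -> np.ndarray:
    """Mean squared genotype difference per pair of individuals.

    ``D_ij = mean over pairwise-complete SNPs of (g_i - g_j)^2`` with
    genotypes in {0,1,2}.  Raises if any pair has no overlapping SNPs.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    n = G.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        sq = (calls[i] - calls[i + 1 :]) ** 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = np.nanmean(sq, axis=1)
        if np.isnan(d).any():
            raise ValueError("a pair of individuals shares no genotyped SNPs")
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


def expected_dissimilarity(grid: DemeGrid, m: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Model dissimilarity between demes.

    Between demes a != b: effective resistance on the graph with edge
    conductance ``(m_u + m_v)/2``, plus ``(q_a + q_b)/2``.  Within a deme:
    ``q_a``.
    """
    m = np.asarray(m, dtype=float)
    q = np.asarray(q, dtype=float)
    d = grid.n_demes
    if (m <= 0).any() or (q <= 0).any():
        raise ValueError("migration and diversity rates must be positive")
    if d == 1:
        return np.array([[q[0]]])
    g = nx.Graph()
    g.add_nodes_from(range(d))
    g.add_edges_from(grid.edges)
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected (infinite resistance)")
    L = np.zeros((d, d))
    for a, b in grid.edges:
        c = 0.5 * (m[a] + m[b])
        L[a, a] += c
        L[b, b] += c
        L[a, b] -= c
        L[b, a] -= c
    # effective resistance via the pseudoinverse of the Laplacian
    Lp = np.linalg.pinv(L, hermitian=True)
    diag = np.diag(Lp)
    R = diag[:, None] + diag[None, :] - 2 * Lp
    if not np.isfinite(R).all() or R[~np.eye(d, dtype=bool)].max() > 1e12:
        raise ValueError("graph is effectively disconnected (infinite resistance)")
    E = R + 0.5 * (q[:, None] + q[None, :])
    np.fill_diagonal(E, q)
    return E


def deme_mean_dissimilarity(D: np.ndarray, samples: list[str], grid: DemeGrid):
    """Average the individual dissimilarity matrix into deme pairs.

    Returns ``(pairs, values)`` where pairs are (a, b) deme index tuples
    with a <= b; within-deme entries require >= 2 samples in the deme.
    """
    deme_of = np.array([grid.assignment[s] for s in samples])
    occupied = sorted(set(deme_of.tolist()))
    pairs, values = [], []
    for ai, a in enumerate(occupied):
        ia = np.flatnonzero(deme_of == a)
        for b in occupied[ai:]:
            ib = np.flatnonzero(deme_of == b)
            if a == b:
                if len(ia) < 2:
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = D[np.ix_(ia, ia)][iu, ju]
            else:
                vals = D[np.ix_(ia, ib)].ravel()
            pairs.append((a, b))
            values.append(float(np.mean(vals)))
    return pairs, np.array(values)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MigrationSurfacePosterior:
    """Posterior summary of the migration surface.

    ``mean_log10_m`` etc. are on the normalized scale: each retained draw
    of per-deme log10 m is centred to zero mean, so 0 is the overall mean
    migration rate and positive values are corridors.
    """

    grid: DemeGrid
    draws_log10_m: np.ndarray  # (n_draws, d), normalized per draw
    draws_log10_q: np.ndarray  # (n_draws, d)
    mean_log10_m: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_log10_q: np.ndarray
    acceptance_rate: float
    chain_means: list[np.ndarray]  # per-chain normalized posterior means

    def chain_agreement(self) -> float:
        """Minimum Pearson correlation of per-deme means across chains."""
        if len(self.chain_means) < 2:
            return 1.0
        cors = []
        for i in range(len(self.chain_means)):
            for j in range(i + 1, len(self.chain_means)):
                cors.append(np.corrcoef(self.chain_means[i], self.chain_means[j])[0, 1])
        return float(min(cors))


def _log_posterior(pairs, obs, grid, log10_m, log10_q, smooth_tau, sigma_floor):
    m = 10.0 ** log10_m
    q = 10.0 ** log10_q
    E = expected_dissimilarity(grid, m, q)
    pred = np.array([E[a, b] for a, b in pairs])
    resid = obs - pred
    # profiled Gaussian noise variance with a small floor
    s2 = max(float(np.mean(resid**2)), sigma_floor)
    n = len(obs)
    loglik = -0.5 * n * math.log(2 * math.pi * s2) - 0.5 * np.sum(resid**2) / s2
    lp = 0.0
    for a, b in grid.edges:
        lp -= (log10_m[a] - log10_m[b]) ** 2 / (2 * smooth_tau**2)
        lp -= (log10_q[a] - log10_q[b]) ** 2 / (2 * smooth_tau**2)
    # weak anchors keep the (nearly) non-identified overall scales proper
    lp -= np.mean(log10_m) ** 2 / (2 * 2.0**2)
    lp -= np.sum((log10_q - np.mean(log10_q)) ** 2) / (2 * 4.0**2)
    return loglik + lp


def fit_migration_surface(
    D_obs: np.ndarray,
    samples: list[str],
    grid: DemeGrid,
    n_iter: int = 50_000,
    burn_in: int | None = None,
    thin: int = 10,
    proposal_scale: float = 0.15,
    seed: int = 0,
    n_chains: int = 2,
    smooth_tau: float = 0.7,
) -> MigrationSurfacePosterior:
    """Random-walk Metropolis over per-deme log10 m and log10 q.

    Each iteration proposes one move: a single-deme or block perturbation
    of the migration field, or a single-deme / global move of the
    diversity field.  Draws after burn-in are thinned and the migration
    field normalized to zero mean per draw.
    """
    if not grid.assignment:
        raise ValueError("grid has no sample assignment; call assign_samples first")
    occupied = {grid.assignment[s] for s in samples}
    if len(occupied) < 2:
        raise ValueError("need samples in at least 2 demes")
    if burn_in is None:
        burn_in = n_iter // 2
    pairs, obs = deme_mean_dissimilarity(D_obs, samples, grid)
    d = grid.n_demes
    sigma_floor = 1e-6 * max(float(np.var(obs)), 1e-12) + 1e-12

    all_draws_m, all_draws_q, chain_means = [], [], []
    n_acc = n_prop = 0
    for chain in range(n_chains):
        rng = np.random.default_rng((seed + 1) * 10_000 + chain)
        # init: flat migration field, q from the within/min dissimilarity scale
        log10_m = np.zeros(d)
        q0 = max(float(np.min(obs)), 1e-3)
        log10_q = np.full(d, math.log10(q0))
        lp = _log_posterior(pairs, obs, grid, log10_m, log10_q, smooth_tau, sigma_floor)
        draws_m, draws_q = [], []
        # per-move-type proposal scales, adapted during burn-in toward ~30%
        scales = {"m1": proposal_scale, "mb": proposal_scale,
                  "q1": proposal_scale, "qg": proposal_scale}
        win_acc = {k: 0 for k in scales}
        win_prop = {k: 0 for k in scales}
        for it in range(n_iter):
            u = rng.random()
            new_m, new_q = log10_m, log10_q
            if u < 0.40:  # single-deme m
                move = "m1"
                new_m = log10_m.copy()
                new_m[rng.integers(d)] += scales[move] * rng.standard_normal()
            elif u < 0.60:  # block m
                move = "mb"
                new_m = log10_m + (scales[move] / math.sqrt(d)) * rng.standard_normal(d)
            elif u < 0.85:  # single-deme q
                move = "q1"
                new_q = log10_q.copy()
                new_q[rng.integers(d)] += scales[move] * rng.standard_normal()
            else:  # global q shift
                move = "qg"
                new_q = log10_q + scales[move] * rng.standard_normal()
            new_lp = _log_posterior(pairs, obs, grid, new_m, new_q,
                                    smooth_tau, sigma_floor)
            if not np.isfinite(new_lp) and not np.isfinite(lp):
                raise RuntimeError("posterior diverged (non-finite likelihood)")
            n_prop += 1
            win_prop[move] += 1
            if math.log(rng.random() + 1e-300) < new_lp - lp:
                log10_m, log10_q, lp = new_m, new_q, new_lp
                n_acc += 1
                win_acc[move] += 1
            if it < burn_in and (it + 1) % 250 == 0:
                for k in scales:
                    if win_prop[k] >= 20:
                        rate = win_acc[k] / win_prop[k]
                        scales[k] *= math.exp(0.5 * (rate - 0.3))
                        scales[k] = min(max(scales[k], 1e-3), 5.0)
                    win_acc[k] = win_prop[k] = 0
            if it >= burn_in and (it - burn_in) % thin == 0:
                draws_m.append(log10_m - np.mean(log10_m))
                draws_q.append(log10_q.copy())
        draws_m = np.array(draws_m)
        draws_q = np.array(draws_q)
        chain_means.append(draws_m.mean(axis=0))
        all_draws_m.append(draws_m)
        all_draws_q.append(draws_q)

    draws_m = np.vstack(all_draws_m)
    draws_q = np.vstack(all_draws_q)
    acc = n_acc / max(n_prop, 1)
    if not 0.05 <= acc <= 0.8:
        warnings.warn(f"MCMC acceptance rate {acc:.2f} outside [0.05, 0.8]")
    return MigrationSurfacePosterior(
        grid=grid,
        draws_log10_m=draws_m,
        draws_log10_q=draws_q,
        mean_log10_m=draws_m.mean(axis=0),
        ci_low=np.percentile(draws_m, 2.5, axis=0),
        ci_high=np.percentile(draws_m, 97.5, axis=0),
        mean_log10_q=draws_q.mean(axis=0),
        acceptance_rate=acc,
        chain_means=chain_means,
    )


def classify_surface(posterior: MigrationSurfacePosterior, prob: float = 0.9) -> list[str]:
    """Per-deme classification from the normalized posterior draws.

    corridor if P(log10 m > 0) >= prob, barrier if P(log10 m < 0) >= prob,
    else neutral.
    """
    draws = posterior.draws_log10_m
    p_above = (draws > 0).mean(axis=0)
    p_below = (draws < 0).mean(axis=0)
    out = []
    for pa, pb in zip(p_above, p_below):
        if pa >= prob:
            out.append("corridor")
        elif pb >= prob:
            out.append("barrier")
        else:
            out.append("neutral")
    return out
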