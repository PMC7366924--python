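"""Shared data model and readers/writers for the formats the pipeline touches.

The central container is :class:`GenotypeMatrix`: diploid biallelic calls
coded as the count of the *minor* allele (0, 1, 2) with ``-1`` for missing.
Minor-allele orientation is fixed once, at load time; every downstream
statistic is invariant to allele-label flipping, so this is a convention,
not a modelling choice.

Coordinates are 1-based and inclusive throughout (PLINK / GFF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

MISSING = -1

#: Continent lookup for the ISO-2 country codes in the dromedary range
#: (plus a few neighbours).  Used to validate metadata consistency.
COUNTRY_CONTINENT = {
    # Africa
    "DZ": "Africa", "EG": "Africa", "ET": "Africa", "KE": "Africa",
    "LY": "Africa", "MA": "Africa", "ML": "Africa", "MR": "Africa",
    "NE": "Africa", "NG": "Africa", "SD": "Africa", "SO": "Africa",
    "TD": "Africa", "TN": "Africa",
    # Asia
    "AE": "Asia", "AF": "Asia", "BH": "Asia", "IL": "Asia", "IN": "Asia",
    "IQ": "Asia", "IR": "Asia", "JO": "Asia", "KW": "Asia", "KZ": "Asia",
    "MN": "Asia", "OM": "Asia", "PK": "Asia", "QA": "Asia", "SA": "Asia",
    "SY": "Asia", "TM": "Asia", "UZ": "Asia", "YE": "Asia",
}


class GenotypeIOError(ValueError):
    """Malformed input file (the message names the offending line)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of minor-allele counts.

    Parameters
    ----------
    samples
        Ordered, unique individual identifiers (length n).
    snp_ids
        Ordered, unique SNP identifiers (length m).
    calls
        ``(n, m)`` int8 array with values in {0, 1, 2} or ``MISSING`` (-1).
    """

    samples: list[str]
    snp_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.snp_ids) != m:
            raise ValueError("dimension mismatch between ids and calls")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or missing (-1)")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def individual_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    def snp_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per SNP."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return self.missing_mask().mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (minor-at-load) allele per SNP,
        over non-missing calls; NaN where a SNP has no calls."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        freq = calls.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(freq, dtype=float)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (folded)."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ----------------------------------------------------

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in ids]
        return GenotypeMatrix(list(ids), list(self.snp_ids), self.calls[idx, :])

    def drop_samples(self, ids) -> "GenotypeMatrix":
        drop = set(ids)
        keep = [s for s in self.samples if s not in drop]
        return self.take_samples(keep)

    def take_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.snp_ids[i] for i in keep]
        return GenotypeMatrix(list(self.samples), ids, self.calls[:, keep])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), list(self.snp_ids), self.calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

_VALID_ALLELES = {"A", "C", "G", "T", "1", "2", "3", "4"}


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK text PED/MAP into a genotype matrix and SNP table.

    MAP columns: chromosome/scaffold, SNP id, genetic distance, position.
    PED rows: six leading columns (family, individual id, father, mother,
    sex, phenotype) then two allele columns per SNP; the pair ``0 0`` codes
    a missing genotype.  The counted (alternate) allele is the minor allele
    computed on load and recorded as ``allele1`` in the returned table;
    ``allele2`` is the major allele.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        SNP table with columns ``snp, scaffold, pos, allele1, allele2``.
    """
    snps = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeIOError(
                    f"{map_path} line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _gdist, pos = parts
            pos = int(pos)
            if pos < 1:
                raise GenotypeIOError(f"{map_path} line {lineno}: position must be >= 1")
            snps.append((snp_id, chrom, pos))
    m = len(snps)

    samples: list[str] = []
    rows: list[np.ndarray] = []  # allele pairs as strings, shape (m, 2)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeIOError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} columns, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            alleles = np.array(parts[6:], dtype="U2").reshape(m, 2)
            for a in np.unique(alleles):
                if a != "0" and a not in _VALID_ALLELES:
                    raise GenotypeIOError(
                        f"{ped_path} line {lineno}: unknown allele code {a!r}"
                    )
            rows.append(alleles)
    n = len(samples)
    if len(set(samples)) != n:
        raise GenotypeIOError(f"{ped_path}: duplicate individual ids")

    calls = np.full((n, m), MISSING, dtype=np.int8)
    allele1 = []
    allele2 = []
    for j in range(m):
        col = np.stack([rows[i][j] for i in range(n)])  # (n, 2)
        present = col[col != "0"]
        uniq, counts = np.unique(present, return_counts=True)
        if len(uniq) > 2:
            raise GenotypeIOError(
                f"{ped_path}: SNP {snps[j][0]} has {len(uniq)} alleles; "
                "only biallelic sites are supported"
            )
        half_missing = (col == "0").sum(axis=1) == 1
        if half_missing.any():
            i = int(np.flatnonzero(half_missing)[0])
            raise GenotypeIOError(
                f"{ped_path} line {i + 1}: half-missing genotype at SNP {snps[j][0]}"
            )
        if len(uniq) == 0:
            allele1.append("0")
            allele2.append("0")
            continue
        if len(uniq) == 1:
            # monomorphic: observed allele is the major; minor unknown ("0")
            allele1.append("0")
            allele2.append(str(uniq[0]))
            calls[col[:, 0] != "0", j] = 0
            continue
        # minor allele = least frequent; ties broken lexicographically
        order = np.lexsort((uniq, counts))
        minor = uniq[order[0]]
        major = uniq[order[-1]]
        allele1.append(str(minor))
        allele2.append(str(major))
        nonmiss = col[:, 0] != "0"
        calls[nonmiss, j] = (col[nonmiss] == minor).sum(axis=1)

    snp_table = pd.DataFrame(
        {
            "snp": [s[0] for s in snps],
            "scaffold": [s[1] for s in snps],
            "pos": [s[2] for s in snps],
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    G = GenotypeMatrix(samples, [s[0] for s in snps], calls)
    return G, snp_table


def write_ped_map(G: GenotypeMatrix, snp_table: pd.DataFrame, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP; inverse of :func:`read_ped_map`.

    Allele labels come from the SNP table (``allele1`` = counted/minor,
    ``allele2`` = major); missing calls are written as ``0 0``.
    """
    if list(snp_table["snp"]) != list(G.snp_ids):
        raise ValueError("SNP table does not match genotype matrix")
    with open(map_path, "w") as fh:
        for _, row in snp_table.iterrows():
            fh.write(f"{row['scaffold']}\t{row['snp']}\t0\t{row['pos']}\n")
    a1 = snp_table["allele1"].to_numpy(dtype="U2")
    a2 = snp_table["allele2"].to_numpy(dtype="U2")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(G.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            g = G.calls[i]
            for j in range(G.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [a2[j], a2[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")


def orient_minor(G: GenotypeMatrix, snp_table: pd.DataFrame):
    """Re-orient calls so the counted allele is the minor allele, with the
    same tie-break as :func:`read_ped_map` (equal counts: lexicographically
    smaller allele code counted).  Returns a new (matrix, table) pair; this
    makes PED/MAP writing followed by reading an exact round trip.
    """
    calls = G.calls.copy()
    table = snp_table.copy()
    nonmiss = (calls != MISSING).sum(axis=0)
    alt = np.where(calls != MISSING, calls, 0).sum(axis=0)
    ref = 2 * nonmiss - alt
    a1 = table["allele1"].to_numpy(dtype="U2")
    a2 = table["allele2"].to_numpy(dtype="U2")
    flip = (alt > ref) | ((alt == ref) & (a2 < a1))
    flip &= nonmiss > 0
    cols = np.flatnonzero(flip)
    sub = calls[:, cols]
    calls[:, cols] = np.where(sub == MISSING, MISSING, 2 - sub)
    table.loc[flip, ["allele1", "allele2"]] = table.loc[
        flip, ["allele2", "allele1"]
    ].to_numpy()
    # monomorphic columns: counted allele count is 0, identity unknown
    alt2 = np.where(calls != MISSING, calls, 0).sum(axis=0)
    mono = (alt2 == 0) & (nonmiss > 0)
    table.loc[mono, "allele1"] = "0"
    return GenotypeMatrix(list(G.samples), list(G.snp_ids), calls), table


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample", "country", "continent", "population", "lon", "lat"]


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample metadata table.

    Columns: sample, country (ISO-2), continent, population, lon, lat
    (lon/lat optional, empty allowed).  Raises when a stated continent
    contradicts the bundled country map.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing_cols = [c for c in METADATA_COLUMNS[:4] if c not in meta.columns]
    if missing_cols:
        raise GenotypeIOError(f"{path}: missing metadata columns {missing_cols}")
    for _, row in meta.iterrows():
        known = COUNTRY_CONTINENT.get(str(row["country"]))
        if known is not None and str(row["continent"]) != known:
            raise GenotypeIOError(
                f"{path}: sample {row['sample']} states continent "
                f"{row['continent']!r} but country {row['country']} is in {known}"
            )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def check_metadata_covers(G: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Every genotyped individual must have a metadata row."""
    missing = set(G.samples) - set(meta["sample"])
    if missing:
        raise GenotypeIOError(f"samples without metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

def read_gff_genes(path) -> pd.DataFrame:
    """Extract ``gene`` features from a GFF3 file.

    Returns a DataFrame with 1-based inclusive coordinates and columns
    ``scaffold, start, end, name``; the name comes from the ``Name=``
    attribute, falling back to ``ID=``.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GenotypeIOError(
                    f"{path} line {lineno}: expected 9 tab-separated columns"
                )
            scaffold, _src, ftype, start, end, _score, _strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            start, end = int(start), int(end)
            if end < start:
                raise GenotypeIOError(f"{path} line {lineno}: end < start")
            fields = {}
            for item in attrs.split(";"):
                item = item.strip()
                if not item:
                    continue
                if "=" not in item:
                    raise GenotypeIOError(
                        f"{path} line {lineno}: malformed attribute {item!r}"
                    )
                k, v = item.split("=", 1)
                fields[k] = v
            name = fields.get("Name") or fields.get("ID")
            if name is None:
                raise GenotypeIOError(
                    f"{path} line {lineno}: gene without Name= or ID= attribute"
                )
            records.append((scaffold, start, end, name))
    return pd.DataFrame(records, columns=["scaffold", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Habitat polygon
# ---------------------------------------------------------------------------

def read_polygon(path) -> Polygon:
    """Read a habitat polygon from whitespace-separated ``lon lat`` lines.

    The ring is auto-closed and its orientation normalized (CCW exterior).
    Self-intersecting rings are rejected.
    """
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GenotypeIOError(f"{path} line {lineno}: expected 'lon lat'")
            pts.append((float(parts[0]), float(parts[1])))
    return polygon_from_vertices(pts)


def polygon_from_vertices(pts) -> Polygon:
    pts = list(pts)
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(pts) < 3:
        raise GenotypeIOError("polygon needs at least 3 distinct vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise GenotypeIOError("polygon ring is invalid (self-intersecting?)")
    # normalize orientation to counter-clockwise exterior
    if not poly.exterior.is_ccw:
        poly = Polygon(list(poly.exterior.coords)[::-1])
    return poly


def write_polygon(poly: Polygon, path) -> None:
    with open(path, "w") as fh:
        for lon, lat in list(poly.exterior.coords)[:-1]:
            fh.write(f"{lon} {lat}\n")


# ---------------------------------------------------------------------------
# RAD-locus FASTA
# ---------------------------------------------------------------------------

def write_rad_fasta(sequences: dict[str, str], path) -> None:
    """Write one RAD locus alignment (id -> sequence) as FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_rad_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
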