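"""Microsatellite genotypes, sibling subsampling, and genetic distances.

Individuals carry diploid allele calls at a set of codominant loci and are
grouped by sampling site (breeding wetland). Two between-site statistics
are provided:

* ``dps_matrix`` — D_ps, one minus the proportion of shared alleles,
  computed between individuals and averaged over all inter-site pairs;
* ``gst`` — Nei's G_ST = (H_T - H_S) / H_T from unweighted mean allele
  frequencies, summed over loci before taking the ratio.

Larval samples arrive in full-sibling family clusters; to avoid
family-induced allele-frequency bias, each cluster at a site is randomly
subsampled down to the size of the smallest cluster at that site before
distance computation (``subsample_siblings``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "GenotypeTable",
    "read_genepop",
    "write_genepop",
    "read_clusters",
    "write_clusters",
    "subsample_siblings",
    "GeneticDistanceMatrix",
    "shared_allele_matrix",
    "dps_matrix",
    "gst",
    "gst_permutation_test",
]

MISSING = 0  # allele code for a missing call


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls, grouped by site.

    ``alleles`` has shape (n_individuals, n_loci, 2) with positive integer
    allele codes and 0 marking a missing locus (both calls are missing
    together). Site order follows first appearance.
    """

    individual_ids: list
    site_ids: list
    loci: list
    alleles: np.ndarray
    life_stages: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n = len(self.individual_ids)
        if not self.life_stages:
            self.life_stages = ["adult"] * n
        if len(self.site_ids) != n or len(self.life_stages) != n:
            raise ValueError("individual, site, and stage lists must align")
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"({n}, {len(self.loci)}, 2)"
            )
        if np.any(self.alleles < 0):
            raise ValueError("allele codes must be non-negative integers")
        if any(not s for s in self.site_ids):
            raise ValueError("site ids must be nonempty")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def sites(self) -> list:
        seen: dict = {}
        for s in self.site_ids:
            seen.setdefault(s, None)
        return list(seen)

    def scored_mask(self) -> np.ndarray:
        """(n, L) boolean: locus scored (neither call missing)."""
        return np.all(self.alleles != MISSING, axis=2)

    def subset(self, indices) -> "GenotypeTable":
        indices = list(indices)
        return GenotypeTable(
            individual_ids=[self.individual_ids[i] for i in indices],
            site_ids=[self.site_ids[i] for i in indices],
            loci=list(self.loci),
            alleles=self.alleles[indices],
            life_stages=[self.life_stages[i] for i in indices],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.site_ids == other.site_ids
            and self.loci == other.loci
            and self.life_stages == other.life_stages
            and np.array_equal(self.alleles, other.alleles)
        )


# ---------------------------------------------------------------------------
# GENEPOP dialect IO


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file (title line, locus names, "Pop"-separated samples).

    Diploid genotypes are 6-digit (two 3-digit alleles) or 4-digit (two
    2-digit) codes; 000000/0000 marks a missing locus. Individual labels of
    the form ``site:individual`` (this package's writer convention) recover
    both ids; otherwise sites are named ``pop_1``, ``pop_2``, ... in file
    order and labels become individual ids.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GENEPOP file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' separator found")
    ind_ids: list = []
    site_ids: list = []
    rows: list = []
    pop_index = 0
    pop_sites: list[str | None] = []
    current_members: list[int] = []

    def flush_pop():
        nonlocal current_members
        if current_members and all(site_ids[k] is None for k in current_members):
            for k in current_members:
                site_ids[k] = f"pop_{pop_index}"
        current_members = []

    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            flush_pop()
            pop_index += 1
            continue
        if "," not in line:
            raise ValueError(f"line {lineno + 1}: expected 'label , genotypes'")
        label, geno = line.split(",", 1)
        label = label.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"line {lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        pair_row = []
        for tok in tokens:
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise ValueError(f"line {lineno + 1}: unknown genotype token {tok!r}")
            half = len(tok) // 2
            a1, a2 = int(tok[:half]), int(tok[half:])
            if (a1 == 0) != (a2 == 0):
                a1 = a2 = 0  # half-missing calls are treated as missing
            pair_row.append((a1, a2))
        if ":" in label:
            site, ind = label.split(":", 1)
            site_ids.append(site.strip())
            ind_ids.append(ind.strip())
        else:
            site_ids.append(None)
            ind_ids.append(label)
        rows.append(pair_row)
        current_members.append(len(rows) - 1)
    flush_pop()
    alleles = np.array(rows, dtype=int) if rows else np.empty((0, len(loci), 2), int)
    # ensure uniqueness for files that repeat the pop name as the label
    if len(set(ind_ids)) != len(ind_ids):
        ind_ids = [f"{ind}_{k}" for k, ind in enumerate(ind_ids, 1)]
    return GenotypeTable(
        individual_ids=ind_ids, site_ids=site_ids, loci=loci, alleles=alleles
    )


def write_genepop(table: GenotypeTable, path, title: str = "chorusnet genotypes") -> None:
    """Write a GENEPOP file with ``site:individual`` labels (round-trips)."""
    width = 3 if (table.alleles.size == 0 or table.alleles.max() < 1000) else 4
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        last_site = None
        for k in range(table.n_individuals):
            site = table.site_ids[k]
            if site != last_site:
                fh.write("Pop\n")
                last_site = site
            codes = " ".join(
                f"{a1:0{width}d}{a2:0{width}d}" for a1, a2 in table.alleles[k]
            )
            fh.write(f"{site}:{table.individual_ids[k]} , {codes}\n")


def read_clusters(path) -> pd.DataFrame:
    """Read a sibling-cluster CSV (individual_id, site_id, cluster_id)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"individual_id", "site_id", "cluster_id"}
    if not required <= set(df.columns):
        raise ValueError(f"cluster file must have columns {sorted(required)}")
    return df


def write_clusters(clusters: pd.DataFrame, path) -> None:
    clusters.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sibling subsampling


def subsample_siblings(table: GenotypeTable, clusters: pd.DataFrame, seed: int) -> GenotypeTable:
    """Subsample each full-sib cluster to the smallest cluster size per site.

    For each site, let n* be the number of individuals in the smallest
    sibling cluster at that site; every cluster there is randomly reduced
    (without replacement) to n* members. Individuals not listed in
    ``clusters`` (adults) pass through untouched. Deterministic under seed.
    """
    if clusters.empty:
        return table.subset(range(table.n_individuals))
    cl = clusters.astype(str)
    by_cluster = cl.groupby("cluster_id")["site_id"].nunique()
    spanning = by_cluster[by_cluster > 1]
    if len(spanning):
        raise ValueError(
            f"sibling clusters span multiple sites: {sorted(spanning.index)}"
        )
    member_of = dict(zip(cl["individual_id"], zip(cl["site_id"], cl["cluster_id"])))
    pos = {str(ind): k for k, ind in enumerate(table.individual_ids)}
    for ind, (site, _) in member_of.items():
        if ind in pos and str(table.site_ids[pos[ind]]) != site:
            raise ValueError(f"individual {ind} listed at site {site} but sampled elsewhere")

    rng = np.random.default_rng(seed)
    # cluster membership restricted to individuals present in the table
    groups: dict = {}
    for ind, key in member_of.items():
        if ind in pos:
            groups.setdefault(key, []).append(pos[ind])
    smallest: dict = {}
    for (site, _), members in groups.items():
        smallest[site] = min(smallest.get(site, len(members)), len(members))
    keep = set(range(table.n_individuals)) - {i for ms in groups.values() for i in ms}
    for key in sorted(groups):  # deterministic iteration order
        members = sorted(groups[key])
        n_star = smallest[key[0]]
        chosen = rng.choice(len(members), size=n_star, replace=False)
        keep.update(members[c] for c in chosen)
    return table.subset(sorted(keep))


# ---------------------------------------------------------------------------
# D_ps


@dataclass
class GeneticDistanceMatrix:
    """Symmetric between-site genetic distance with per-site sample sizes."""

    site_ids: list
    matrix: np.ndarray
    sample_sizes: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.site_ids, columns=self.site_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site")


def shared_allele_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise proportion of shared alleles between individuals.

    ps(x, y) = sum over loci scored in both of sum_a min(count_x_a,
    count_y_a), divided by 2 x (number of loci scored in both). Pairs with
    no commonly scored locus get NaN.
    """
    n, L, _ = table.alleles.shape
    scored = table.scored_mask()
    shared_sum = np.zeros((n, n))
    both = np.zeros((n, n))
    for l in range(L):
        codes = np.unique(table.alleles[:, l, :])
        codes = codes[codes != MISSING]
        if codes.size == 0:
            continue
        index = {c: k for k, c in enumerate(codes)}
        counts = np.zeros((n, codes.size))
        for c in range(2):
            col = table.alleles[:, l, c]
            for i in np.flatnonzero(col != MISSING):
                counts[i, index[col[i]]] += 1
        # sum_a min(x_a, y_a) = (sum x + sum y - L1(x, y)) / 2 = (4 - L1)/2
        l1 = cdist(counts, counts, metric="cityblock")
        mask = np.outer(scored[:, l], scored[:, l])
        shared_sum += np.where(mask, (4.0 - l1) / 2.0, 0.0)
        both += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = shared_sum / (2.0 * both)
    ps[both == 0] = np.nan
    return ps


def dps_matrix(table: GenotypeTable) -> GeneticDistanceMatrix:
    """Between-site D_ps: 1 - mean shared-allele proportion over inter-site
    individual pairs. Diagonal is 0; entries lie in [0, 1]."""
    sites = table.sites
    if len(sites) < 2:
        raise ValueError("D_ps needs at least 2 sites")
    scored = table.scored_mask()
    site_arr = np.asarray(table.site_ids, dtype=object)
    for s in sites:
        if not scored[site_arr == s].any():
            raise ValueError(f"site {s!r} has no scored loci")
    ps = shared_allele_matrix(table)
    m = len(sites)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            block = ps[np.ix_(site_arr == sites[i], site_arr == sites[j])]
            if np.all(np.isnan(block)):
                raise ValueError(
                    f"no comparable genotypes between sites {sites[i]!r} and {sites[j]!r}"
                )
            d = 1.0 - float(np.nanmean(block))
            out[i, j] = out[j, i] = min(max(d, 0.0), 1.0)
    sizes = {s: int(np.sum(site_arr == s)) for s in sites}
    return GeneticDistanceMatrix(site_ids=sites, matrix=out, sample_sizes=sizes)


# ---------------------------------------------------------------------------
# G_ST


def _site_allele_freqs(table: GenotypeTable, locus: int) -> dict:
    """Per-site allele frequency vectors at one locus (sites with data only)."""
    site_arr = np.asarray(table.site_ids, dtype=object)
    codes = np.unique(table.alleles[:, locus, :])
    codes = codes[codes != MISSING]
    freqs = {}
    for s in table.sites:
        calls = table.alleles[site_arr == s, locus, :].ravel()
        calls = calls[calls != MISSING]
        if calls.size == 0:
            continue
        freqs[s] = np.array([np.mean(calls == c) for c in codes])
    return freqs


def _gst_from_freqs(freq_list: list[np.ndarray]) -> tuple[float, float]:
    """(H_T, H_S) for one locus from per-site frequency vectors."""
    p = np.vstack(freq_list)
    h_s = float(np.mean(1.0 - np.sum(p**2, axis=1)))
    p_bar = p.mean(axis=0)
    h_t = float(1.0 - np.sum(p_bar**2))
    return h_t, h_s


def gst(table: GenotypeTable) -> tuple[float, pd.DataFrame]:
    """Nei's G_ST: global over all sites, plus the pairwise site matrix.

    G_ST = (H_T - H_S)/H_T with H_T from unweighted mean allele frequencies
    across sites; heterozygosities are summed over loci before the ratio.
    Monomorphic data (H_T = 0) give G_ST = 0.
    """
    sites = table.sites
    if len(sites) < 2:
        raise ValueError("G_ST needs at least 2 sites")
    per_locus = [_site_allele_freqs(table, l) for l in range(len(table.loci))]

    def gst_over(site_subset: list) -> float:
        num = den = 0.0
        for freqs in per_locus:
            fl = [freqs[s] for s in site_subset if s in freqs]
            if len(fl) < 2:
                continue
            h_t, h_s = _gst_from_freqs(fl)
            num += h_t - h_s
            den += h_t
        return num / den if den > 0 else 0.0

    global_gst = gst_over(sites)
    m = len(sites)
    pw = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            pw[i, j] = pw[j, i] = gst_over([sites[i], sites[j]])
    return global_gst, pd.DataFrame(pw, index=sites, columns=sites)


def gst_permutation_test(
    table: GenotypeTable,
    n_permutations: int = 999,
    seed: int = 0,
    bonferroni: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of pairwise G_ST (individuals shuffled between sites).

    Returns a tidy frame (site_i, site_j, gst, p_value, significant) where
    the p-value is (1 + #{G_perm >= G_obs}) / (n_permutations + 1) and the
    significance threshold is Bonferroni-corrected across pairs by default.
    """
    rng = np.random.default_rng(seed)
    sites = table.sites
    site_arr = np.asarray(table.site_ids, dtype=object)
    _, pw = gst(table)
    rows = []
    pairs = [(i, j) for i in range(len(sites)) for j in range(i + 1, len(sites))]
    for i, j in pairs:
        members = np.flatnonzero((site_arr == sites[i]) | (site_arr == sites[j]))
        labels = site_arr[members].copy()
        sub = table.subset(members)
        obs = pw.iloc[i, j]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            shuffled = GenotypeTable(
                individual_ids=sub.individual_ids,
                site_ids=list(perm),
                loci=sub.loci,
                alleles=sub.alleles,
                life_stages=sub.life_stages,
            )
            _, pw_perm = gst(shuffled)
            if pw_perm.iloc[0, 1] >= obs:
                exceed += 1
        p = (1 + exceed) / (n_permutations + 1)
        rows.append({"site_i": sites[i], "site_j": sites[j], "gst": obs, "p_value": p})
    out = pd.DataFrame(rows)
    threshold = alpha / len(pairs) if bonferroni else alpha
    out["significant"] = out["p_value"] < threshold
    return out
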