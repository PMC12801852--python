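"""Population-genetic summary statistics for phased multilocus data.

Per-locus diversity (nucleotide diversity, haplotype diversity, Watterson's
theta, segregating sites), neutrality tests (Tajima's D, Fu's F_S via the
Ewens sampling formula, the Ewens-Watterson homozygosity test), hypergeometric
rarefaction of allelic richness, Hudson-type multilocus F_ST with a
permutation test, and the fixed-order feature vector used by the ABC layer.

Missing data ('N'/'-') are handled by pairwise deletion: a site enters a
pairwise comparison only when both haplotypes carry a defined base there.
Statistics that are undefined on a locus (e.g. Tajima's D with no
segregating sites) are reported as None and, in the feature vector,
imputed as 0 with a paired fraction-undefined indicator — never dropped
silently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .seqio import MISSING, REGIONS, LocusAlignment, PhasedMultilocusDataset

__all__ = [
    "nucleotide_diversity",
    "haplotype_diversity",
    "segregating_sites",
    "tajimas_d",
    "fus_fs",
    "ewens_watterson_test",
    "allelic_richness",
    "pairwise_fst",
    "summary_vector",
    "summary_vector_from_binary",
    "locus_stats",
    "locus_stats_table",
    "population_stats_table",
    "SummaryVector",
    "LocusStats",
    "PopulationStats",
]

FS_CLAMP = 700.0  # sentinel magnitude for numerically infinite Fu's F_S


# ---------------------------------------------------------------------------
# pairwise machinery on integer-coded matrices (missing = -1)

def _as_matrix(locus, subset):
    if isinstance(locus, LocusAlignment):
        return locus.matrix(subset)
    mat = np.asarray(locus)
    if subset is not None:
        mat = mat[np.asarray(subset)]
    return mat


def pairwise_diff_stats(mat: np.ndarray) -> tuple[float, float]:
    """(mean per-pair difference count, mean per-pair per-site difference).

    Pairwise deletion: each pair is compared over its jointly non-missing
    sites.  Pairs with zero jointly defined sites contribute 0 differences
    and are excluded from the per-site mean.
    """
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    ok = mat != MISSING
    sum_diff = 0.0
    sum_frac = 0.0
    n_frac_pairs = 0
    for i in range(n - 1):
        valid = ok[i] & ok[i + 1:]
        diff = (valid & (mat[i + 1:] != mat[i])).sum(axis=1)
        nv = valid.sum(axis=1)
        sum_diff += diff.sum()
        pos = nv > 0
        sum_frac += (diff[pos] / nv[pos]).sum()
        n_frac_pairs += int(pos.sum())
    n_pairs = n * (n - 1) // 2
    per_site = sum_frac / n_frac_pairs if n_frac_pairs else 0.0
    return sum_diff / n_pairs, per_site


def nucleotide_diversity(locus, subset=None) -> float:
    """Mean pairwise difference per aligned site (pi), pairwise deletion."""
    mat = _as_matrix(locus, subset)
    if mat.shape[0] < 2:
        raise ValueError("nucleotide_diversity needs >= 2 haplotypes")
    return pairwise_diff_stats(mat)[1]


def mean_pairwise_differences(locus, subset=None) -> float:
    """Mean pairwise difference count per locus (theta-pi on the locus scale)."""
    mat = _as_matrix(locus, subset)
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    return pairwise_diff_stats(mat)[0]


def _haplotype_counts(locus, subset=None) -> np.ndarray:
    """Multiplicities of distinct full-length haplotype strings."""
    if isinstance(locus, LocusAlignment):
        ids = locus.haplotype_ids if subset is None else list(subset)
        seqs = [locus.haplotypes[h] for h in ids]
        return np.asarray(list(pd.Series(seqs).value_counts()), dtype=int)
    mat = _as_matrix(locus, subset)
    _, counts = np.unique(mat, axis=0, return_counts=True)
    return counts


def haplotype_diversity(locus, subset=None) -> float:
    """H_d = n(1 - sum p_i^2)/(n - 1) over distinct haplotype classes."""
    counts = _haplotype_counts(locus, subset)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype_diversity needs n >= 2")
    p = counts / n
    return float(n * (1.0 - (p ** 2).sum()) / (n - 1))


def segregating_sites(locus, subset=None) -> int:
    """Sites with >= 2 observed non-missing character states."""
    mat = _as_matrix(locus, subset)
    if mat.shape[0] < 2:
        raise ValueError("segregating_sites needs >= 2 haplotypes")
    s = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states = np.unique(col[col != MISSING])
        if states.size >= 2:
            s += 1
    return s


# ---------------------------------------------------------------------------
# neutrality tests

def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i ** power for i in range(1, n))


def tajimas_d_from_counts(n: int, s: int, k_hat: float) -> float | None:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs.

    Returns None when undefined (S = 0).  For n = 2 the statistic is
    identically 0 (pi equals S equals Watterson's estimate) and 0.0 is
    returned.
    """
    if s == 0:
        return None
    if n < 2:
        raise ValueError("n >= 2 required")
    if n == 2:
        return 0.0
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return None
    return float((k_hat - s / a1) / math.sqrt(var))


def tajimas_d(locus, subset=None) -> float | None:
    mat = _as_matrix(locus, subset)
    s = segregating_sites(mat)
    if s == 0:
        return None
    k_hat, _ = pairwise_diff_stats(mat)
    return tajimas_d_from_counts(mat.shape[0], s, k_hat)


@lru_cache(maxsize=512)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1; |s(0,0)| = 1
    if n == 0:
        row[0] = 0.0
        return tuple(row)
    for m in range(2, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        new[1 : m + 1] = np.logaddexp(row[0:m], math.log(m - 1) + row[1 : m + 1])
        row = new
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = np.asarray(_log_stirling_row(n))
    k = np.arange(n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logp = logs + k * math.log(theta) - log_rising
    p = np.exp(logp)
    return p / p.sum()


def fus_fs(locus=None, subset=None, *, n: int | None = None,
           k_obs: int | None = None, theta_pi: float | None = None) -> float | None:
    """Fu's F_S = ln(S'/(1-S')), S' = P(K >= k_obs | theta_pi-hat, n).

    theta_pi-hat is the mean pairwise difference count per locus (not per
    site).  Either pass a locus/subset or the (n, k_obs, theta_pi) triple
    directly.  Returns None when the locus carries no variation; values
    beyond the numeric range are clamped to +/-FS_CLAMP.
    """
    if locus is not None:
        mat = _as_matrix(locus, subset)
        n = mat.shape[0]
        counts = _haplotype_counts(mat)
        k_obs = len(counts)
        theta_pi = pairwise_diff_stats(mat)[0]
        if segregating_sites(mat) == 0:
            return None
    assert n is not None and k_obs is not None and theta_pi is not None
    if theta_pi <= 0 or k_obs <= 1:
        return None
    pk = ewens_k_distribution(n, theta_pi)
    s_prime = float(pk[k_obs:].sum())
    eps = 1e-300
    s_prime = min(max(s_prime, eps), 1 - 1e-16)
    fs = math.log(s_prime) - math.log1p(-s_prime)
    return float(np.clip(fs, -FS_CLAMP, FS_CLAMP))


def _crp_sample_counts(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """One Chinese-restaurant-process draw: class sizes for n customers."""
    counts: list[int] = []
    for i in range(n):
        if i == 0 or rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            tbl = rng.choice(len(counts), p=np.asarray(counts) / i)
            counts[tbl] += 1
    return np.asarray(counts)


def _theta_matching_k(n: int, k: int) -> float:
    """theta with E[K] = k under the Ewens formula (watterson-test tuning)."""
    from scipy.optimize import brentq

    if k <= 1:
        return 1e-6
    if k >= n:
        return 1e6

    def expected_k(theta):
        return sum(theta / (theta + i) for i in range(n)) - k

    return float(brentq(expected_k, 1e-9, 1e9))


def ewens_watterson_test(locus, subset=None, n_null: int = 1000,
                         rng_seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Ewens-Watterson homozygosity test.

    F_obs = sum p_i^2 over haplotype-class frequencies; the null is the
    Ewens sampling formula conditioned on (n, k_obs), sampled by the
    Chinese-restaurant construction with theta tuned so E[K] = k_obs and
    draws retained when K = k_obs.  The p-value is two-sided:
    2*min(P(F <= F_obs), P(F >= F_obs)) capped at 1, ties inclusive.
    """
    counts = _haplotype_counts(locus, subset)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("ewens_watterson_test needs n >= 2")
    k_obs = len(counts)
    f_obs = float(((counts / n) ** 2).sum())
    if k_obs == 1:
        return f_obs, 1.0
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    theta = _theta_matching_k(n, k_obs)
    f_null = []
    attempts = 0
    while len(f_null) < n_null and attempts < 200 * n_null:
        attempts += 1
        c = _crp_sample_counts(n, theta, rng)
        if len(c) == k_obs:
            f_null.append(((c / n) ** 2).sum())
    f_null = np.asarray(f_null)
    if f_null.size == 0:  # pathological; conditioning failed
        return f_obs, 1.0
    lo = (f_null <= f_obs + 1e-12).mean()
    hi = (f_null >= f_obs - 1e-12).mean()
    return f_obs, float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# allelic richness (hypergeometric rarefaction)

def allelic_richness_from_counts(counts, g: int) -> float:
    """A_R = sum_i [1 - C(N - N_i, g)/C(N, g)] over allele counts."""
    counts = [int(c) for c in counts]
    n_tot = sum(counts)
    if g < 1:
        raise ValueError("rarefaction depth g must be >= 1")
    if n_tot < g:
        raise ValueError(f"only {n_tot} gene copies but g = {g}")
    denom = math.comb(n_tot, g)
    return float(sum(1.0 - math.comb(n_tot - c, g) / denom for c in counts))


def allelic_richness(locus, subset=None, g: int = 4) -> float:
    """Rarefied allelic richness of distinct haplotype alleles at depth g."""
    return allelic_richness_from_counts(_haplotype_counts(locus, subset), g)


# ---------------------------------------------------------------------------
# Hudson F_ST

def _plugin_within(mat: np.ndarray) -> float | None:
    """Plug-in mean pairwise differences: ordered pairs incl. self, /n^2.

    The uncorrected (Nei-style) estimator makes F_ST exactly 0 when the
    two groups carry identical haplotype multisets (H_w == H_b there),
    at the cost of an O(1/n) downward bias within groups."""
    n = mat.shape[0]
    if n < 2:
        return None
    mean_unordered, _ = pairwise_diff_stats(mat)
    return mean_unordered * (n - 1) / n


def _within_between_sums(mat_a: np.ndarray, mat_b: np.ndarray) -> tuple[float, float]:
    """(H_w, H_b) for one locus: plug-in mean within (averaged over groups)
    and mean between pairwise difference counts, pairwise deletion."""
    hw_a = _plugin_within(mat_a)
    hw_b = _plugin_within(mat_b)
    parts = [h for h in (hw_a, hw_b) if h is not None]
    hw = float(np.mean(parts)) if parts else 0.0
    ok_a = mat_a != MISSING
    total = 0.0
    npair = 0
    for i in range(mat_a.shape[0]):
        valid = ok_a[i] & (mat_b != MISSING)
        total += (valid & (mat_b != mat_a[i])).sum()
        npair += mat_b.shape[0]
    hb = total / npair if npair else 0.0
    return hw, hb


def hudson_fst_matrices(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Multilocus Hudson F_ST = 1 - sum(H_w)/sum(H_b) (ratio of sums)."""
    sw = sb = 0.0
    for mat_a, mat_b in pairs:
        hw, hb = _within_between_sums(mat_a, mat_b)
        sw += hw
        sb += hb
    if sb == 0:
        return 0.0
    return float(1.0 - sw / sb)


def pairwise_fst(dataset: PhasedMultilocusDataset,
                 grouping: dict[str, list[str]],
                 n_permutations: int = 0,
                 rng_seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise multilocus Hudson F_ST between groups of populations.

    grouping maps a group label to a list of population codes.  Returns a
    symmetric F_ST DataFrame and, when n_permutations > 0, a matching
    one-sided permutation p-value DataFrame (haplotypes shuffled between
    the two groups).
    """
    labels = list(grouping)
    rng = np.random.default_rng(rng_seed)
    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    pvals = pd.DataFrame(1.0, index=labels, columns=labels) if n_permutations else None

    def group_matrices(label):
        mats = []
        for loc in dataset.loci:
            ids = []
            for pop in grouping[label]:
                ids.extend(dataset.haplotype_ids_for(loc, population=pop))
            mats.append(loc.matrix(ids) if ids else np.empty((0, loc.length_bp), dtype=np.int8))
        return mats

    mats_by_label = {lab: group_matrices(lab) for lab in labels}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pairs = list(zip(mats_by_label[a], mats_by_label[b]))
            obs = hudson_fst_matrices(pairs)
            fst.loc[a, b] = fst.loc[b, a] = obs
            if n_permutations:
                count = 0
                for _ in range(n_permutations):
                    perm_pairs = []
                    for mat_a, mat_b in pairs:
                        pooled = np.vstack([mat_a, mat_b])
                        idx = rng.permutation(pooled.shape[0])
                        na = mat_a.shape[0]
                        perm_pairs.append((pooled[idx[:na]], pooled[idx[na:]]))
                    if hudson_fst_matrices(perm_pairs) >= obs:
                        count += 1
                p = (1 + count) / (1 + n_permutations)
                pvals.loc[a, b] = pvals.loc[b, a] = p
    return fst, pvals


# ---------------------------------------------------------------------------
# tables

@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    n_haplotypes: int
    S: int
    pi: float
    Hd: float
    theta_w: float
    tajima_d: float | None
    fu_fs: float | None
    ew_F: float
    ew_p: float


@dataclass(frozen=True)
class PopulationStats:
    population_code: str
    n_individuals: int
    AR: float
    pi: float


def locus_stats(locus: LocusAlignment, subset=None, n_null: int = 200,
                rng_seed: int = 0) -> LocusStats:
    mat = locus.matrix(subset)
    n = mat.shape[0]
    s = segregating_sites(mat)
    k_hat, pi = pairwise_diff_stats(mat)
    hd = haplotype_diversity(locus, subset)
    theta_w = (s / _harmonic(n)) / locus.length_bp if n > 1 else 0.0
    d = tajimas_d_from_counts(n, s, k_hat)
    fs = fus_fs(locus, subset)
    f_obs, p = ewens_watterson_test(locus, subset, n_null=n_null, rng_seed=rng_seed)
    return LocusStats(locus.locus_id, n, s, pi, hd, theta_w, d, fs, f_obs, p)


def locus_stats_table(dataset: PhasedMultilocusDataset, region: str | None = None,
                      n_null: int = 200, rng_seed: int = 0) -> pd.DataFrame:
    rows = []
    for loc in dataset.loci:
        ids = dataset.haplotype_ids_for(loc, region=region)
        if len(ids) < 2:
            continue
        rows.append(locus_stats(loc, ids, n_null=n_null, rng_seed=rng_seed).__dict__)
    return pd.DataFrame(rows)


def population_stats_table(dataset: PhasedMultilocusDataset,
                           g: int | None = None) -> pd.DataFrame:
    """Per-population mean rarefied allelic richness and pi over loci.

    Rarefaction depth defaults to the smallest per-population gene-copy
    count observed at any locus (min 2); loci where a population has fewer
    copies than g are excluded from that population's mean.
    """
    pops = dataset.sample_map.populations
    if g is None:
        g = min(
            (
                len(dataset.haplotype_ids_for(loc, population=pop))
                for loc in dataset.loci
                for pop in pops
                if len(dataset.haplotype_ids_for(loc, population=pop)) >= 2
            ),
            default=2,
        )
    rows = []
    for pop in pops:
        ars, pis = [], []
        for loc in dataset.loci:
            ids = dataset.haplotype_ids_for(loc, population=pop)
            if len(ids) >= 2:
                pis.append(nucleotide_diversity(loc, ids))
            if len(ids) >= g:
                ars.append(allelic_richness(loc, ids, g=g))
        n_ind = len(dataset.sample_map.individuals_in(population=pop))
        rows.append(PopulationStats(pop, n_ind,
                                    float(np.mean(ars)) if ars else float("nan"),
                                    float(np.mean(pis)) if pis else float("nan")).__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ABC feature vector

@dataclass(frozen=True)
class SummaryVector:
    names: tuple[str, ...]
    values: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SummaryVector)
            and self.names == other.names
            and np.array_equal(self.values, other.values)
        )


def _group_features(prefix: str, pis, ss, hds, ds):
    """Mean/variance over loci of {pi, S, Hd, D} with undefined-D handling."""
    ds = list(ds)
    defined = [d for d in ds if d is not None]
    undef_frac = 1.0 - len(defined) / len(ds) if ds else 1.0
    d_imputed = [0.0 if d is None else d for d in ds]
    names, vals = [], []
    for stat, arr in (("pi", pis), ("S", ss), ("Hd", hds), ("tajd", d_imputed)):
        arr = np.asarray(arr, dtype=float)
        names += [f"{prefix}_{stat}_mean", f"{prefix}_{stat}_var"]
        vals += [float(arr.mean()), float(arr.var(ddof=0))]
    names.append(f"{prefix}_tajd_undef_frac")
    vals.append(undef_frac)
    return names, vals


def _fst_from_site_counts(counts_a, n_a, counts_b, n_b):
    """Hudson F_ST across loci from per-site derived-allele counts."""
    sw = sb = 0.0
    for ca, cb in zip(counts_a, counts_b):
        # plug-in within-group diversity (ordered pairs incl. self, /n^2)
        hw_terms = []
        if n_a >= 2:
            hw_terms.append(2.0 * (ca * (n_a - ca)).sum() / (n_a * n_a))
        if n_b >= 2:
            hw_terms.append(2.0 * (cb * (n_b - cb)).sum() / (n_b * n_b))
        sw += float(np.mean(hw_terms)) if hw_terms else 0.0
        sb += float((ca * (n_b - cb) + (n_a - ca) * cb).sum() / (n_a * n_b))
    return 0.0 if sb == 0 else float(1.0 - sw / sb)


def summary_vector_from_binary(matrices: list[np.ndarray],
                               region_idx: dict[str, np.ndarray],
                               lengths: list[int]) -> SummaryVector:
    """Feature vector from per-locus 0/1 haplotype matrices (no missing data).

    region_idx maps each region name (SEA, NEA) to the row indices of its
    haplotypes; the same fixed feature order as :func:`summary_vector`.
    """
    names: list[str] = []
    vals: list[float] = []
    per_region_counts = {}
    for region in REGIONS:
        idx = np.asarray(region_idx[region])
        n = idx.size
        pis, ss, hds, ds = [], [], [], []
        counts = []
        for mat, length in zip(matrices, lengths):
            sub = mat[idx]
            c = sub.sum(axis=0)
            counts.append(c)
            seg = (c > 0) & (c < n)
            s = int(seg.sum())
            k_hat = float((c * (n - c)).sum() / (n * (n - 1) / 2))
            pis.append(k_hat / length)
            ss.append(s)
            _, cls = np.unique(sub, axis=0, return_counts=True)
            p = cls / n
            hds.append(float(n * (1 - (p ** 2).sum()) / (n - 1)))
            ds.append(tajimas_d_from_counts(n, s, k_hat))
        per_region_counts[region] = (counts, n)
        nm, vl = _group_features(region, pis, ss, hds, ds)
        names += nm
        vals += vl
    # pooled over both regions
    idx_all = np.concatenate([np.asarray(region_idx[r]) for r in REGIONS])
    n = idx_all.size
    pis, ss, hds, ds = [], [], [], []
    for mat, length in zip(matrices, lengths):
        sub = mat[idx_all]
        c = sub.sum(axis=0)
        seg = (c > 0) & (c < n)
        s = int(seg.sum())
        k_hat = float((c * (n - c)).sum() / (n * (n - 1) / 2))
        pis.append(k_hat / length)
        ss.append(s)
        _, cls = np.unique(sub, axis=0, return_counts=True)
        p = cls / n
        hds.append(float(n * (1 - (p ** 2).sum()) / (n - 1)))
        ds.append(tajimas_d_from_counts(n, s, k_hat))
    nm, vl = _group_features("pooled", pis, ss, hds, ds)
    names += nm
    vals += vl
    # private segregating sites per region
    (ca, na), (cb, nb) = per_region_counts[REGIONS[0]], per_region_counts[REGIONS[1]]
    priv_a = priv_b = 0
    for c1, c2 in zip(ca, cb):
        seg1 = (c1 > 0) & (c1 < na)
        seg2 = (c2 > 0) & (c2 < nb)
        priv_a += int((seg1 & ~seg2).sum())
        priv_b += int((seg2 & ~seg1).sum())
    names += [f"{REGIONS[0]}_private_S", f"{REGIONS[1]}_private_S"]
    vals += [float(priv_a), float(priv_b)]
    names.append("fst_regions")
    vals.append(_fst_from_site_counts(ca, na, cb, nb))
    return SummaryVector(tuple(names), np.asarray(vals, dtype=float))


def summary_vector(dataset: PhasedMultilocusDataset) -> SummaryVector:
    """Canonical fixed-order ABC feature vector from a sequence dataset.

    Per region and pooled: mean/variance over loci of {pi, S, Hd, Tajima's
    D} plus the fraction of loci with undefined D; then private
    segregating-site counts per region and the pooled between-region
    Hudson F_ST.
    """
    names: list[str] = []
    vals: list[float] = []
    region_mats: dict[str, list[np.ndarray]] = {}
    for region in REGIONS:
        mats = []
        pis, ss, hds, ds = [], [], [], []
        for loc in dataset.loci:
            ids = dataset.haplotype_ids_for(loc, region=region)
            if len(ids) < 2:
                raise ValueError(f"region {region} has < 2 haplotypes at locus {loc.locus_id}")
            mat = loc.matrix(ids)
            mats.append(mat)
            k_hat, pi = pairwise_diff_stats(mat)
            s = segregating_sites(mat)
            pis.append(pi)
            ss.append(s)
            hds.append(haplotype_diversity(loc, ids))
            ds.append(tajimas_d_from_counts(mat.shape[0], s, k_hat))
        region_mats[region] = mats
        nm, vl = _group_features(region, pis, ss, hds, ds)
        names += nm
        vals += vl
    pis, ss, hds, ds = [], [], [], []
    for loc in dataset.loci:
        ids = [h for r in REGIONS for h in dataset.haplotype_ids_for(loc, region=r)]
        mat = loc.matrix(ids)
        k_hat, pi = pairwise_diff_stats(mat)
        s = segregating_sites(mat)
        pis.append(pi)
        ss.append(s)
        hds.append(haplotype_diversity(loc, ids))
        ds.append(tajimas_d_from_counts(mat.shape[0], s, k_hat))
    nm, vl = _group_features("pooled", pis, ss, hds, ds)
    names += nm
    vals += vl
    priv = {r: 0 for r in REGIONS}
    for i_loc, loc in enumerate(dataset.loci):
        seg_sets = {}
        for region in REGIONS:
            mat = region_mats[region][i_loc]
            seg = set()
            for j in range(mat.shape[1]):
                col = mat[:, j]
                if np.unique(col[col != MISSING]).size >= 2:
                    seg.add(j)
            seg_sets[region] = seg
        priv[REGIONS[0]] += len(seg_sets[REGIONS[0]] - seg_sets[REGIONS[1]])
        priv[REGIONS[1]] += len(seg_sets[REGIONS[1]] - seg_sets[REGIONS[0]])
    names += [f"{REGIONS[0]}_private_S", f"{REGIONS[1]}_private_S"]
    vals += [float(priv[REGIONS[0]]), float(priv[REGIONS[1]])]
    pairs = list(zip(region_mats[REGIONS[0]], region_mats[REGIONS[1]]))
    names.append("fst_regions")
    vals.append(hudson_fst_matrices(pairs))
    return SummaryVector(tuple(names), np.asarray(vals, dtype=float))
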