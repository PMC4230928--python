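"""Population differentiation, AMOVA, ordination and bottleneck tests.

F_ST follows Weir & Cockerham's variance-component estimator theta, R_ST is
the allele-size analogue, and Phi_PT comes from a squared-distance AMOVA on
inter-individual allele differences. Distances can be linearized as
d/(1-d) for regression against spatial distances. Bottleneck screening
combines the M-ratio, the heterozygosity-excess Wilcoxon test against
coalescent equilibrium expectations, and the allele-frequency mode-shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import MultilocusGenotype


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def locus_array(individuals: list[MultilocusGenotype], locus: str) -> np.ndarray:
    """(N, 2) int array of alleles at one locus, -1 for missing."""
    out = np.full((len(individuals), 2), -1, dtype=int)
    for i, ind in enumerate(individuals):
        pair = ind.loci.get(locus)
        if pair is not None:
            out[i] = pair
    return out


def group_vector(individuals: list[MultilocusGenotype],
                 groups: dict[str, str] | None = None) -> np.ndarray:
    labels = [(groups or {}).get(ind.sample_id, ind.locality or "all")
              for ind in individuals]
    return np.asarray(labels, dtype=object)


@dataclass
class GeneticDistanceMatrix:
    labels: list[str]
    values: np.ndarray            # raw estimates (may be negative)
    p_values: np.ndarray | None = None
    estimator: str = "fst"
    flags: dict = field(default_factory=dict)

    def clipped(self) -> np.ndarray:
        """Report-side matrix with negative estimates clipped to 0."""
        return np.clip(self.values, 0.0, None)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (F_ST)
# ---------------------------------------------------------------------------

def _wc_components_locus(allele_mat: np.ndarray, group_idx: np.ndarray,
                         n_groups: int) -> tuple[float, float, float]:
    """Weir-Cockerham a, b, c summed over alleles at one locus."""
    typed = allele_mat[:, 0] >= 0
    allele_mat = allele_mat[typed]
    gidx = group_idx[typed]
    present = np.unique(gidx)
    if len(present) < n_groups or len(allele_mat) == 0:
        return 0.0, 0.0, 0.0
    r = n_groups
    n_i = np.array([np.sum(gidx == g) for g in range(r)], dtype=float)
    if np.any(n_i < 1):
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1) if r > 1 else nbar
    alleles = np.unique(allele_mat)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        is_a = allele_mat == allele
        p_i = np.array([is_a[gidx == g].mean() for g in range(r)])
        het_i = np.array([(is_a[gidx == g].sum(axis=1) == 1).mean()
                          for g in range(r)])
        pbar = float(np.sum(n_i * p_i) / (r * nbar))
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)) if r > 1 else 0.0
        hbar = float(np.sum(n_i * het_i) / (r * nbar))
        if nbar <= 1:
            continue
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) *
                           (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(individuals: list[MultilocusGenotype],
             groups: dict[str, str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta over all groups."""
    gvec = group_vector(individuals, groups)
    labels, gidx = np.unique(gvec, return_inverse=True)
    loci = sorted({k for ind in individuals for k in ind.loci})
    num = den = 0.0
    for locus in loci:
        a, b, c = _wc_components_locus(locus_array(individuals, locus),
                                       gidx, len(labels))
        num += a
        den += a + b + c
    return num / den if den != 0 else 0.0


def _pairwise_stat(individuals, groups, stat_fn, n_perm, seed, estimator):
    gvec = group_vector(individuals, groups)
    labels = sorted(set(gvec))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    k = len(labels)
    values = np.zeros((k, k))
    pvals = np.ones((k, k))
    rng = np.random.default_rng(seed)
    flags: dict = {}
    by_group = {lab: [ind for ind, g in zip(individuals, gvec) if g == lab]
                for lab in labels}
    for i in range(k):
        for j in range(i + 1, k):
            pair = by_group[labels[i]] + by_group[labels[j]]
            pair_groups = {ind.sample_id: lab
                           for lab, members in ((labels[i], by_group[labels[i]]),
                                                (labels[j], by_group[labels[j]]))
                           for ind in members}
            obs = stat_fn(pair, pair_groups)
            values[i, j] = values[j, i] = obs
            if n_perm > 0:
                ids = [ind.sample_id for ind in pair]
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(ids)
                    pg = {sid: pair_groups[orig]
                          for sid, orig in zip(perm, ids)}
                    if stat_fn(pair, pg) >= obs - 1e-12:
                        count += 1
                pvals[i, j] = pvals[j, i] = (count + 1) / (n_perm + 1)
    return GeneticDistanceMatrix(labels=labels, values=values,
                                 p_values=pvals, estimator=estimator,
                                 flags=flags)


def pairwise_fst(individuals: list[MultilocusGenotype],
                 groups: dict[str, str] | None = None,
                 n_perm: int = 999, seed: int | None = None) -> GeneticDistanceMatrix:
    """Pairwise Weir-Cockerham F_ST with individual-permutation p-values."""
    return _pairwise_stat(individuals, groups, wc_theta, n_perm, seed, "fst")


# ---------------------------------------------------------------------------
# R_ST (allele-size variance)
# ---------------------------------------------------------------------------

def rst_value(individuals: list[MultilocusGenotype],
              groups: dict[str, str] | None = None) -> float:
    """Slatkin's R_ST: (S̄ − S_W)/S̄ from allele-size variance components.

    S̄ is the average squared size difference between gene copies drawn at
    random from the pooled sample, S_W the within-population analogue,
    averaged over loci with locus weights equal to total copy counts.
    """
    gvec = group_vector(individuals, groups)
    labels = sorted(set(gvec))
    loci = sorted({k for ind in individuals for k in ind.loci})
    num = den = 0.0
    for locus in loci:
        mat = locus_array(individuals, locus)
        typed = mat[:, 0] >= 0
        sizes = mat[typed].reshape(-1).astype(float)
        gi = np.repeat(gvec[typed], 2)
        if len(sizes) < 4:
            continue
        # mean squared pairwise difference = 2 * variance
        s_total = 2.0 * float(np.var(sizes, ddof=1))
        sw_parts = []
        weights = []
        for lab in labels:
            s = sizes[gi == lab]
            if len(s) >= 2:
                sw_parts.append(2.0 * float(np.var(s, ddof=1)))
                weights.append(len(s))
        if not sw_parts:
            continue
        s_within = float(np.average(sw_parts, weights=weights))
        w = len(sizes)
        num += w * (s_total - s_within)
        den += w * s_total
    return num / den if den != 0 else 0.0


def pairwise_rst(individuals: list[MultilocusGenotype],
                 groups: dict[str, str] | None = None,
                 n_perm: int = 999, seed: int | None = None) -> GeneticDistanceMatrix:
    """Pairwise R_ST with individual-permutation p-values."""
    return _pairwise_stat(individuals, groups, rst_value, n_perm, seed, "rst")


# ---------------------------------------------------------------------------
# AMOVA / Phi_PT
# ---------------------------------------------------------------------------

def allele_difference_matrix(individuals: list[MultilocusGenotype]) -> np.ndarray:
    """Squared inter-individual distance: allele differences over shared loci.

    Per locus the distance between two diploid genotypes is the number of
    alleles (0, 1 or 2) not shared as a multiset; loci missing in either
    individual are skipped (pairwise-complete).
    """
    n = len(individuals)
    loci = sorted({k for ind in individuals for k in ind.loci})
    d = np.zeros((n, n))
    for locus in loci:
        mat = locus_array(individuals, locus)
        for i in range(n):
            if mat[i, 0] < 0:
                continue
            for j in range(i + 1, n):
                if mat[j, 0] < 0:
                    continue
                gi = sorted(mat[i])
                gj = sorted(mat[j])
                shared = 0
                used = [False, False]
                for x in gi:
                    for t in range(2):
                        if not used[t] and gj[t] == x:
                            used[t] = True
                            shared += 1
                            break
                d[i, j] += 2 - shared
    d += d.T
    return d


@dataclass
class AmovaResult:
    components: dict[str, float]          # raw variance components
    percentages: dict[str, float]         # negative components floored at 0
    phi: dict[str, float]
    p_values: dict[str, float]
    df: dict[str, int]
    notes: list[str] = field(default_factory=list)


def _ss_within(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    total = 0.0
    for idx in idx_groups:
        if len(idx) == 0:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2 * len(idx))
    return total


def _amova_components(d2: np.ndarray, pops: np.ndarray,
                      clusters: np.ndarray | None):
    n = len(pops)
    pop_labels = np.unique(pops)
    pop_idx = [np.where(pops == p)[0] for p in pop_labels]
    ss_total = d2.sum() / (2 * n)
    ss_wp = _ss_within(d2, pop_idx)
    if clusters is None:
        df_a, df_w = len(pop_labels) - 1, n - len(pop_labels)
        ms_a = (ss_total - ss_wp) / df_a if df_a else 0.0
        ms_w = ss_wp / df_w if df_w else 0.0
        n_i = np.array([len(ix) for ix in pop_idx], dtype=float)
        n0 = (n - np.sum(n_i ** 2) / n) / (len(pop_labels) - 1)
        sig_w = ms_w
        sig_a = (ms_a - ms_w) / n0
        return {"among_pops": sig_a, "within_pops": sig_w}, \
               {"among_pops": df_a, "within_pops": df_w}
    cl_labels = np.unique(clusters)
    cl_idx = [np.where(clusters == c)[0] for c in cl_labels]
    ss_wg = _ss_within(d2, cl_idx)
    g, p = len(cl_labels), len(pop_labels)
    df_ag, df_ap, df_wp = g - 1, p - g, n - p
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    ms_ag = ss_ag / df_ag if df_ag else 0.0
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    pop_of = {p_: clusters[pops == p_][0] for p_ in pop_labels}
    n_p = {p_: np.sum(pops == p_) for p_ in pop_labels}
    n_g = {c: np.sum(clusters == c) for c in cl_labels}
    sum_sq_over_g = sum(sum(n_p[p_] ** 2 for p_ in pop_labels if pop_of[p_] == c) / n_g[c]
                        for c in cl_labels)
    n1 = (n - sum_sq_over_g) / df_ap if df_ap else 1.0
    n2 = (sum_sq_over_g - sum(n_p[p_] ** 2 for p_ in pop_labels) / n) / df_ag if df_ag else 1.0
    n3 = (n - sum(n_g[c] ** 2 for c in cl_labels) / n) / df_ag if df_ag else 1.0
    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n1 if n1 else 0.0
    sig_a = (ms_ag - sig_c - n2 * sig_b) / n3 if n3 else 0.0
    return ({"among_clusters": sig_a, "among_pops_within": sig_b,
             "within_pops": sig_c},
            {"among_clusters": df_ag, "among_pops_within": df_ap,
             "within_pops": df_wp})


def amova(individuals: list[MultilocusGenotype],
          populations: dict[str, str] | None = None,
          clusters: dict[str, str] | None = None,
          n_perm: int = 999, seed: int | None = None,
          d2: np.ndarray | None = None) -> AmovaResult:
    """Hierarchical AMOVA on squared allele-difference distances.

    Partitions variance among clusters, among populations within clusters,
    and within populations (or two levels when ``clusters`` is None).
    Significance of each Phi statistic by label permutation.
    """
    pops = group_vector(individuals, populations)
    cl = None
    notes: list[str] = []
    if clusters is not None:
        cl = np.asarray([clusters[p] for p in pops], dtype=object)
        # clusters with a single population cannot separate levels
        for c in np.unique(cl):
            if len(np.unique(pops[cl == c])) < 2:
                notes.append(f"cluster {c} has one population; "
                             "among-within component partly confounded")
    if d2 is None:
        d2 = allele_difference_matrix(individuals)
    comps, df = _amova_components(d2, pops, cl)
    raw = dict(comps)
    floored = {k: max(0.0, v) for k, v in comps.items()}
    total = sum(floored.values())
    pct = {k: (100.0 * v / total if total > 0 else 0.0)
           for k, v in floored.items()}
    if cl is None:
        a, w = floored["among_pops"], floored["within_pops"]
        phi = {"phi_pt": a / (a + w) if a + w > 0 else 0.0}
    else:
        a, b, c = (floored["among_clusters"], floored["among_pops_within"],
                   floored["within_pops"])
        tot = a + b + c
        phi = {"phi_ct": a / tot if tot else 0.0,
               "phi_sc": b / (b + c) if b + c else 0.0,
               "phi_st": (a + b) / tot if tot else 0.0}
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_perm > 0:
        # permute individuals across everything for the top-level test
        def stat(pv, cv):
            cmp_, _ = _amova_components(d2, pv, cv)
            vals = {k: max(0.0, v) for k, v in cmp_.items()}
            t = sum(vals.values())
            if cv is None:
                return vals["among_pops"] / t if t else 0.0
            return ((vals["among_clusters"] + vals["among_pops_within"]) / t
                    if t else 0.0)
        obs = stat(pops, cl)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            if stat(pops[perm], cl[perm] if cl is not None else None) >= obs - 1e-12:
                count += 1
        p_values["phi_st" if cl is not None else "phi_pt"] = \
            (count + 1) / (n_perm + 1)
    return AmovaResult(components=raw, percentages=pct, phi=phi,
                       p_values=p_values, df=df, notes=notes)


def phi_pt_matrix(individuals: list[MultilocusGenotype],
                  groups: dict[str, str] | None = None,
                  n_perm: int = 0, seed: int | None = None) -> GeneticDistanceMatrix:
    """Pairwise Phi_PT from two-level AMOVAs on each population pair."""

    def stat(pair, pg):
        return amova(pair, pg, n_perm=0).phi["phi_pt"]

    return _pairwise_stat(individuals, groups, stat, n_perm, seed, "phi_pt")


# ---------------------------------------------------------------------------
# Linearization and PCoA
# ---------------------------------------------------------------------------

def linearize(d):
    """Rousset linearization d/(1-d), elementwise; d=1 maps to +inf."""
    arr = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        out = arr / (1.0 - arr)
    if np.any(arr >= 1.0):
        warnings.warn("differentiation of 1 linearizes to infinity")
    if np.ndim(d) == 0:
        return float(out)
    return out


@dataclass
class PcoaResult:
    coordinates: np.ndarray      # (n, n_positive_axes)
    eigenvalues: np.ndarray      # all, descending (negatives included)
    explained: np.ndarray        # fraction of positive-eigenvalue variance
    negative_eigenvalues: np.ndarray


def pcoa(distance: np.ndarray) -> PcoaResult:
    """Principal coordinates analysis by double-centering eigendecomposition.

    Negative eigenvalues (non-Euclidean input) are reported, not dropped;
    coordinates span the positive axes only.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    explained = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return PcoaResult(coordinates=coords, eigenvalues=vals,
                      explained=explained,
                      negative_eigenvalues=vals[vals < -1e-10])


# ---------------------------------------------------------------------------
# Bottleneck suite
# ---------------------------------------------------------------------------

def m_ratio(individuals: list[MultilocusGenotype]) -> float:
    """Garza-Williamson M = mean over loci of k/(r+1), r in repeat units."""
    loci = sorted({k for ind in individuals for k in ind.loci})
    ratios = []
    for locus in loci:
        mat = locus_array(individuals, locus)
        sizes = mat[mat[:, 0] >= 0].reshape(-1)
        if len(sizes) == 0:
            continue
        k = len(np.unique(sizes))
        r = int(sizes.max() - sizes.min())
        ratios.append(k / (r + 1))
    return float(np.mean(ratios)) if ratios else math.nan


def _tpm_step(rng: np.random.Generator, n: int, single_step: float,
              variance: float) -> np.ndarray:
    """Mutation step sizes under the two-phase model.

    With probability ``single_step`` a +/-1 step; otherwise a +/- geometric
    multi-step whose variance matches ``variance`` repeat units squared.
    """
    steps = np.ones(n, dtype=int)
    multi = rng.random(n) >= single_step
    if multi.any():
        # geometric(p): var (1-p)/p^2 = variance  ->  p from the quadratic
        p = (-1.0 + math.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance)
        steps[multi] = rng.geometric(p, size=multi.sum())
    signs = rng.choice([-1, 1], size=n)
    return steps * signs


def _coalescent_alleles(n: int, theta: float, rng: np.random.Generator,
                        single_step: float, variance: float) -> np.ndarray:
    """Simulate allele sizes for n gene copies under coalescent + stepwise mutation."""
    active = list(range(n))
    children: dict[int, tuple[int, int]] = {}
    parent_of: dict[int, int] = {}
    blen = {}
    t = 0.0
    next_id = n
    times = {i: 0.0 for i in range(n)}
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        a, b = rng.choice(j, size=2, replace=False)
        ia, ib = active[a], active[b]
        children[next_id] = (ia, ib)
        times[next_id] = t
        for x in (ia, ib):
            blen[x] = t - times[x]
            parent_of[x] = next_id
        active = [x for k, x in enumerate(active) if k not in (a, b)]
        active.append(next_id)
        next_id += 1
    root = active[0]
    sizes = np.zeros(next_id, dtype=int)
    # walk down from root applying mutations per branch
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        if node in children:
            stack.extend(children[node])
    for node in order:
        if node == root:
            continue
        n_mut = rng.poisson(theta * blen[node] / 2.0)
        delta = int(_tpm_step(rng, n_mut, single_step, variance).sum()) if n_mut else 0
        sizes[node] = sizes[parent_of[node]] + delta
    return sizes[:n]


def _ewens_theta(k: int, n: int) -> float:
    """Solve E[K | theta, n] = k under the Ewens sampling formula."""
    if k <= 1:
        return 1e-3
    i = np.arange(n, dtype=float)

    def expected(theta):
        return float(np.sum(theta / (theta + i)))

    lo, hi = 1e-4, 1e4
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if expected(mid) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


@dataclass
class BottleneckResult:
    m_ratio: float
    wilcoxon_p: dict[str, float]           # model -> one-tailed excess p
    mode_shift_classes: np.ndarray         # counts per 0.05 frequency class
    l_shaped: bool
    per_locus_dh: dict[str, dict[str, float]]
    flags: list[str] = field(default_factory=list)


def heterozygosity_excess_p(individuals: list[MultilocusGenotype],
                            model: str = "TPM", single_step: float = 0.95,
                            variance: float = 12.0, n_sim: int = 1000,
                            rng: np.random.Generator | None = None
                            ) -> tuple[float, dict[str, float]]:
    """One-tailed Wilcoxon test of heterozygosity excess at mutation-drift
    equilibrium (Cornuet-Luikart), conditioning simulated samples on the
    observed allele count per locus by rejection.
    """
    rng = rng or np.random.default_rng()
    ss = 1.0 if model.upper() == "SMM" else single_step
    loci = sorted({k for ind in individuals for k in ind.loci})
    dh: dict[str, float] = {}
    diffs = []
    for locus in loci:
        mat = locus_array(individuals, locus)
        sizes = mat[mat[:, 0] >= 0].reshape(-1)
        n = len(sizes)
        k_obs = len(np.unique(sizes))
        if k_obs < 2 or n < 8:
            continue
        counts = np.bincount(np.unique(sizes, return_inverse=True)[1])
        p = counts / n
        he_obs = (n / (n - 1)) * (1 - float(np.sum(p ** 2)))
        theta = _ewens_theta(k_obs, n)
        sims = []
        attempts = 0
        while len(sims) < n_sim and attempts < 30 * n_sim:
            attempts += 1
            alleles = _coalescent_alleles(n, theta, rng, ss, variance)
            uniq, inv = np.unique(alleles, return_inverse=True)
            if len(uniq) != k_obs:
                # adapt theta toward the target allele count
                theta *= math.exp(0.05 * (math.log(k_obs) - math.log(max(1, len(uniq)))))
                continue
            c = np.bincount(inv) / n
            sims.append((n / (n - 1)) * (1 - float(np.sum(c ** 2))))
        if len(sims) < max(20, n_sim // 10):
            continue
        sims = np.asarray(sims)
        sd = sims.std(ddof=1)
        if sd == 0:
            continue
        d = (he_obs - sims.mean()) / sd
        dh[locus] = d
        diffs.append(d)
    if len(diffs) < 4:
        return 1.0, dh
    stat = stats.wilcoxon(diffs, alternative="greater")
    return float(stat.pvalue), dh


def mode_shift(individuals: list[MultilocusGenotype]) -> tuple[np.ndarray, bool]:
    """Allele-frequency histogram in 0.05-wide classes; L-shaped iff the
    lowest class is modal (no bottleneck signal)."""
    loci = sorted({k for ind in individuals for k in ind.loci})
    freqs = []
    for locus in loci:
        mat = locus_array(individuals, locus)
        sizes = mat[mat[:, 0] >= 0].reshape(-1)
        if len(sizes) == 0:
            continue
        counts = np.bincount(np.unique(sizes, return_inverse=True)[1])
        freqs.extend(counts / len(sizes))
    hist, _ = np.histogram(freqs, bins=np.arange(0, 1.0001, 0.05))
    l_shaped = bool(hist[0] == hist.max())
    return hist, l_shaped


def bottleneck_suite(individuals: list[MultilocusGenotype],
                     model: str = "TPM", single_step: float = 0.95,
                     variance: float = 12.0, n_sim: int = 1000,
                     rng: np.random.Generator | None = None) -> BottleneckResult:
    """Run M-ratio, heterozygosity-excess and mode-shift tests on one group."""
    flags = []
    if len(individuals) < 5:
        flags.append("n < 5: low power, interpret with caution")
    p, dh = heterozygosity_excess_p(individuals, model, single_step,
                                    variance, n_sim, rng)
    hist, l_shaped = mode_shift(individuals)
    return BottleneckResult(
        m_ratio=m_ratio(individuals),
        wilcoxon_p={model.upper(): p},
        mode_shift_classes=hist, l_shaped=l_shaped,
        per_locus_dh={model.upper(): dh}, flags=flags)
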