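"""Individual identification and diversity statistics from microsatellite data.

The workflow mirrors non-invasive (scat) genotyping practice: replicate PCR
genotypes are reduced to consensus multilocus genotypes, consensus samples are
matched into unique individuals allowing for allelic dropout, and the
resulting individuals feed allele frequencies, probability-of-identity,
heterozygosity and Hardy-Weinberg / linkage-disequilibrium tests.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

AllelePair = tuple[int, int]


def _norm_pair(pair) -> AllelePair:
    a, b = int(pair[0]), int(pair[1])
    if a <= 0 or b <= 0:
        raise ValueError("alleles must be positive repeat counts")
    return (a, b) if a <= b else (b, a)


@dataclass
class MultilocusGenotype:
    """A diploid multilocus genotype keyed by locus name.

    Allele pairs are unordered repeat-count integers; a locus mapped to
    ``None`` (or absent) is missing.
    """

    sample_id: str
    loci: dict[str, AllelePair | None] = field(default_factory=dict)
    locality: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.loci = {k: (None if v is None else _norm_pair(v))
                     for k, v in self.loci.items()}

    def typed_loci(self) -> list[str]:
        return [k for k, v in self.loci.items() if v is not None]

    def n_typed(self) -> int:
        return len(self.typed_loci())

    def is_het(self, locus: str) -> bool:
        v = self.loci.get(locus)
        return v is not None and v[0] != v[1]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies plus gene-copy sample sizes."""

    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int]

    def loci(self) -> list[str]:
        return list(self.freqs)

    def validate(self) -> None:
        for locus, table in self.freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}")


# ---------------------------------------------------------------------------
# Consensus calling
# ---------------------------------------------------------------------------

def consensus_genotype(replicates: list[MultilocusGenotype],
                       het_min: int = 2, hom_min: int = 5,
                       sample_id: str | None = None) -> tuple[MultilocusGenotype, dict[str, str]]:
    """Collapse replicate genotypes of one sample into a consensus call.

    A heterozygote is accepted once the same unordered pair is seen in at
    least ``het_min`` replicates; a homozygote needs ``hom_min`` consistent
    observations (protecting against allelic dropout). Anything else is
    missing. Returns the consensus genotype and a per-locus flag dict
    (``"conflict"`` marks two competing heterozygote pairs).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    loci = sorted({k for r in replicates for k in r.loci})
    calls: dict[str, AllelePair | None] = {}
    flags: dict[str, str] = {}
    for locus in loci:
        obs = [r.loci.get(locus) for r in replicates if r.loci.get(locus) is not None]
        het_counts = Counter(p for p in obs if p[0] != p[1])
        hom_counts = Counter(p for p in obs if p[0] == p[1])
        confirmed = [p for p, c in het_counts.items() if c >= het_min]
        if len(confirmed) > 1:
            calls[locus] = None
            flags[locus] = "conflict"
        elif len(confirmed) == 1:
            calls[locus] = confirmed[0]
        elif len(hom_counts) == 1 and not het_counts:
            pair, count = next(iter(hom_counts.items()))
            calls[locus] = pair if count >= hom_min else None
        else:
            calls[locus] = None
    sid = sample_id or replicates[0].sample_id
    cons = MultilocusGenotype(sample_id=sid, loci=calls,
                              locality=replicates[0].locality,
                              sex=replicates[0].sex)
    return cons, flags


# ---------------------------------------------------------------------------
# Individual matching
# ---------------------------------------------------------------------------

def _compare(a: MultilocusGenotype, b: MultilocusGenotype) -> tuple[int, int, bool]:
    """Return (shared typed loci, mismatches, all mismatches dropout-consistent).

    A mismatch is dropout-consistent when one call is a homozygote and the
    other a heterozygote containing that allele (a single dropped allele
    explains the difference).
    """
    shared = mism = 0
    consistent = True
    for locus, pa in a.loci.items():
        pb = b.loci.get(locus)
        if pa is None or pb is None:
            continue
        shared += 1
        if pa == pb:
            continue
        mism += 1
        hom, het = (pa, pb) if pa[0] == pa[1] else (pb, pa)
        if not (hom[0] == hom[1] and het[0] != het[1] and hom[0] in het):
            consistent = False
    return shared, mism, consistent


def match_individuals(samples: list[MultilocusGenotype],
                      min_loci: int = 7, max_mismatch: int = 2
                      ) -> tuple[list[MultilocusGenotype], dict[str, str], list[tuple[str, str]]]:
    """Collapse samples into unique individuals.

    Samples typed at fewer than ``min_loci`` loci are excluded. Pairs that
    agree at every shared locus are the same individual; pairs mismatching at
    1..``max_mismatch`` loci are merged only when every mismatch is
    dropout-consistent (and flagged for review); three or more mismatches
    mean distinct animals. Merging is via union-find so the partition does
    not depend on input order.

    Returns (individuals, sample_id -> individual_id map, review pairs).
    """
    usable = sorted((s for s in samples if s.n_typed() >= min_loci),
                    key=lambda s: s.sample_id)
    if not usable:
        warnings.warn("no samples pass the minimum-loci filter")
        return [], {}, []
    parent = list(range(len(usable)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    review: list[tuple[str, str]] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            shared, mism, consistent = _compare(usable[i], usable[j])
            if shared == 0:
                continue
            if mism == 0 or (mism <= max_mismatch and consistent):
                if mism > 0:
                    review.append((usable[i].sample_id, usable[j].sample_id))
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[MultilocusGenotype]] = {}
    for i in range(len(usable)):
        clusters.setdefault(find(i), []).append(usable[i])
    individuals: list[MultilocusGenotype] = []
    assignment: dict[str, str] = {}
    for root in sorted(clusters):
        members = clusters[root]
        iid = members[0].sample_id
        loci = sorted({k for m in members for k in m.loci})
        merged: dict[str, AllelePair | None] = {}
        for locus in loci:
            calls = [m.loci.get(locus) for m in members if m.loci.get(locus) is not None]
            if not calls:
                merged[locus] = None
                continue
            hets = [c for c in calls if c[0] != c[1]]
            # prefer the heterozygote: dropout-consistent merges imply the
            # homozygote lost one allele
            merged[locus] = Counter(hets or calls).most_common(1)[0][0]
        individuals.append(MultilocusGenotype(
            sample_id=iid, loci=merged, locality=members[0].locality,
            sex=members[0].sex))
        for m in members:
            assignment[m.sample_id] = iid
    return individuals, assignment, review


# ---------------------------------------------------------------------------
# Allele frequencies, identity and diversity
# ---------------------------------------------------------------------------

def allele_frequencies(individuals: list[MultilocusGenotype]) -> AlleleFrequencyTable:
    """Per-locus allele frequencies from non-missing gene copies."""
    if not individuals:
        raise ValueError("need at least one individual")
    loci = sorted({k for ind in individuals for k in ind.loci})
    freqs: dict[str, dict[int, float]] = {}
    n_copies: dict[str, int] = {}
    for locus in loci:
        counts: Counter[int] = Counter()
        for ind in individuals:
            pair = ind.loci.get(locus)
            if pair is not None:
                counts.update(pair)
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"locus {locus} has no calls; omitted")
            continue
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        n_copies[locus] = total
    return AlleleFrequencyTable(freqs=freqs, n_copies=n_copies)


def pi_sib_locus(p: np.ndarray) -> float:
    """Sibling probability of identity for one locus.

    PIsib = 1/4 + (1/2)Σp² + (1/2)(Σp²)² − (1/4)Σp⁴ — the probability that
    two full sibs share a genotype, the conservative benchmark for deciding
    whether a marker panel can separate related individuals.
    """
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def pi_locus(p: np.ndarray, n: int | None = None) -> float:
    """Probability of identity for unrelated individuals at one locus.

    With ``n`` (diploid sample size) given, applies the small-sample
    unbiased estimator; otherwise the plain theoretical form
    PI = 2(Σp²)² − Σp⁴.
    """
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p ** 2))
    a4 = float(np.sum(p ** 4))
    if n is None or n < 4:
        return 2 * a2 ** 2 - a4
    a3 = float(np.sum(p ** 3))
    num = (n ** 3 * (2 * a2 ** 2 - a4) - 2 * n ** 2 * (a3 + 2 * a2)
           + n * (9 * a2 + 2) - 6)
    den = n * (n - 1) * (n - 2) * (n - 3)
    return min(1.0, max(0.0, num / den))


def identity_statistics(freqs: AlleleFrequencyTable
                        ) -> tuple[float, float, dict[str, float], dict[str, float]]:
    """Cumulative and per-locus PI and PIsib over all loci.

    Returns (cumulative PI, cumulative PIsib, per-locus PI, per-locus PIsib);
    cumulative values are products across loci (independence assumption).
    """
    per_pi: dict[str, float] = {}
    per_sib: dict[str, float] = {}
    for locus, table in freqs.freqs.items():
        p = np.array(list(table.values()))
        n = freqs.n_copies[locus] // 2
        per_pi[locus] = pi_locus(p, n)
        per_sib[locus] = pi_sib_locus(p)
    cum_pi = float(np.prod(list(per_pi.values()))) if per_pi else 1.0
    cum_sib = float(np.prod(list(per_sib.values()))) if per_sib else 1.0
    return cum_pi, cum_sib, per_pi, per_sib


@dataclass
class DiversitySummary:
    group: str
    n: int
    per_locus: "dict[str, dict[str, float]]"   # locus -> {Ho, He, A, size_range, private}
    mean_ho: float
    mean_he: float
    mean_a: float
    mean_size_range: float
    n_private: int
    he_flagged: bool = False


def diversity_summary(individuals: list[MultilocusGenotype],
                      by: dict[str, str] | None = None) -> dict[str, DiversitySummary]:
    """Observed/expected heterozygosity, allele counts, size ranges and
    private alleles per locality group.

    He uses the small-sample correction n/(n−1) on gene copies. Private
    alleles are alleles observed in exactly one group.
    """
    groups: dict[str, list[MultilocusGenotype]] = {}
    for ind in individuals:
        label = (by or {}).get(ind.sample_id, ind.locality or "all")
        groups.setdefault(label, []).append(ind)
    loci = sorted({k for ind in individuals for k in ind.loci})
    # which groups carry each allele, for private-allele tallies
    carriers: dict[tuple[str, int], set[str]] = {}
    for label, members in groups.items():
        for ind in members:
            for locus, pair in ind.loci.items():
                if pair is not None:
                    for a in pair:
                        carriers.setdefault((locus, a), set()).add(label)
    out: dict[str, DiversitySummary] = {}
    for label, members in groups.items():
        per_locus: dict[str, dict[str, float]] = {}
        for locus in loci:
            pairs = [m.loci.get(locus) for m in members if m.loci.get(locus) is not None]
            if not pairs:
                continue
            n_ind = len(pairs)
            ho = sum(1 for p in pairs if p[0] != p[1]) / n_ind
            counts = Counter(a for p in pairs for a in p)
            copies = sum(counts.values())
            p = np.array([c / copies for c in counts.values()])
            he = 1.0 - float(np.sum(p ** 2))
            if copies > 1:
                he *= copies / (copies - 1)
            alleles = sorted(counts)
            private = sum(1 for a in alleles if carriers[(locus, a)] == {label})
            per_locus[locus] = {
                "Ho": ho, "He": he, "A": len(alleles),
                "size_range": alleles[-1] - alleles[0], "private": private,
            }
        vals = list(per_locus.values())
        out[label] = DiversitySummary(
            group=label, n=len(members), per_locus=per_locus,
            mean_ho=float(np.mean([v["Ho"] for v in vals])) if vals else math.nan,
            mean_he=float(np.mean([v["He"] for v in vals])) if vals else math.nan,
            mean_a=float(np.mean([v["A"] for v in vals])) if vals else math.nan,
            mean_size_range=float(np.mean([v["size_range"] for v in vals])) if vals else math.nan,
            n_private=sum(int(v["private"]) for v in vals),
            he_flagged=len(members) < 2,
        )
    return out


# ---------------------------------------------------------------------------
# HWE and LD permutation tests
# ---------------------------------------------------------------------------

def _log_prob_genotype_array(pairs: list[AllelePair]) -> float:
    """Log conditional probability of a genotype array given allele counts.

    P = n! 2^h Π(allele_count!)/( (2n)! Π genotype_count! ) — the statistic
    of the exact HWE test (Guo & Thompson).
    """
    n = len(pairs)
    geno = Counter(pairs)
    alleles = Counter(a for p in pairs for a in p)
    h = sum(c for p, c in geno.items() if p[0] != p[1])
    lp = (gammaln(n + 1) + h * math.log(2)
          + sum(gammaln(c + 1) for c in alleles.values())
          - gammaln(2 * n + 1)
          - sum(gammaln(c + 1) for c in geno.values()))
    return lp


def hwe_test(individuals: list[MultilocusGenotype], locus: str,
             n_perm: int = 10_000, rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg at one locus.

    Gene copies are shuffled into new diploid genotypes; the p-value is the
    +1-corrected fraction of permuted arrays at most as probable as the
    observed one. Monomorphic loci return 1 by convention.
    """
    rng = rng or np.random.default_rng()
    pairs = [ind.loci[locus] for ind in individuals
             if ind.loci.get(locus) is not None]
    if len(pairs) < 5:
        raise ValueError("need at least 5 typed individuals")
    copies = np.array([a for p in pairs for a in p])
    if len(np.unique(copies)) < 2:
        return 1.0
    obs = _log_prob_genotype_array(pairs)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(copies)
        perm_pairs = [_norm_pair((perm[2 * i], perm[2 * i + 1]))
                      for i in range(len(pairs))]
        if _log_prob_genotype_array(perm_pairs) <= obs + 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio (G) statistic of association of two label vectors."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xs), len(ys)))
    np.add.at(table, (xi, yi), 1)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    mask = table > 0
    return 2.0 * float(np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_test(individuals: list[MultilocusGenotype], locus_a: str, locus_b: str,
            n_perm: int = 10_000, rng: np.random.Generator | None = None) -> float:
    """Permutation test of linkage disequilibrium between two loci.

    Single-locus genotypes at ``locus_b`` are permuted across individuals
    (complete cases only); the statistic is the G log-likelihood ratio of the
    two-locus genotype contingency table.
    """
    rng = rng or np.random.default_rng()
    pairs = [(ind.loci[locus_a], ind.loci[locus_b]) for ind in individuals
             if ind.loci.get(locus_a) is not None and ind.loci.get(locus_b) is not None]
    if len(pairs) < 5:
        raise ValueError("need at least 5 typed individuals")
    ga = np.array([hash(p[0]) for p in pairs])
    gb = np.array([hash(p[1]) for p in pairs])
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        return 1.0
    obs = _g_statistic(ga, gb)
    count = 0
    for _ in range(n_perm):
        if _g_statistic(ga, rng.permutation(gb)) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test critical value."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
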