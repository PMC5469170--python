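"""Nuclear and mitochondrial diversity and differentiation statistics.

Microsatellite statistics operate on allele sizes; all estimators use
pairwise deletion of missing genotypes. Differentiation estimators:

* F_ST — Weir & Cockerham's θ from per-allele variance components, loci
  combined by summing components across alleles and loci.
* Φ_ST — two-level AMOVA on haplotype pairwise-difference distances.
* R_ST — ANOVA on allele sizes; its permutation test randomizes the
  assignment of sizes to allelic states within loci, asking whether the
  sizes carry phylogenetic information beyond allele identity (i.e.
  whether mutation has contributed to differentiation).

Neutrality tests: Tajima's D from the standard variance coefficients and
Fu's Fs from the Ewens sampling distribution of the number of distinct
haplotypes, computed in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rescuegen.containers import MISSING, GenotypeTable, HaplotypeSet

__all__ = [
    "allele_counts",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "homozygosity_by_locus",
    "allelic_richness",
    "private_alleles",
    "weir_cockerham_theta",
    "pairwise_fst",
    "pairwise_phist",
    "rst_anova",
    "allele_size_permutation_test",
    "mtdna_summary",
    "tajimas_d",
    "fus_fs",
    "neutrality_tests",
    "diversity_summary",
    "pairwise_matrix",
]


# ---------------------------------------------------------------------------
# Allele bookkeeping
# ---------------------------------------------------------------------------

def allele_counts(table: GenotypeTable, locus_index: int) -> dict[int, int]:
    """Counts of each allele size at one locus, missing excluded."""
    alleles = table.genotypes[:, locus_index, :].ravel()
    alleles = alleles[alleles != MISSING]
    sizes, counts = np.unique(alleles, return_counts=True)
    return dict(zip(sizes.tolist(), counts.tolist()))


def _locus_frequencies(table: GenotypeTable, locus_index: int) -> dict[int, float]:
    counts = allele_counts(table, locus_index)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: c / total for a, c in counts.items()}


# ---------------------------------------------------------------------------
# Diversity within populations
# ---------------------------------------------------------------------------

def expected_heterozygosity(pop: GenotypeTable) -> tuple[np.ndarray, float]:
    """Unbiased expected heterozygosity per locus and its mean over loci.

    Per locus with n genotyped diploids: He = (2n/(2n-1)) (1 - sum p_k^2).
    Loci with fewer than two genotyped individuals are excluded from the
    mean (NaN in the per-locus vector) with a warning.
    """
    per_locus = np.full(pop.n_loci, np.nan)
    for j in range(pop.n_loci):
        alleles = pop.genotypes[:, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        n_genes = alleles.size
        if n_genes < 4:  # <2 diploid individuals
            warnings.warn(
                f"locus {pop.loci[j]}: fewer than 2 genotyped individuals; "
                "excluded from He",
                stacklevel=2,
            )
            continue
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / n_genes
        per_locus[j] = (n_genes / (n_genes - 1)) * (1.0 - np.sum(p**2))
    mean = float(np.nanmean(per_locus)) if np.isfinite(per_locus).any() else math.nan
    return per_locus, mean


def observed_heterozygosity(pop: GenotypeTable) -> tuple[np.ndarray, float]:
    """Proportion of heterozygous genotypes per locus and its mean."""
    per_locus = np.full(pop.n_loci, np.nan)
    for j in range(pop.n_loci):
        g = pop.genotypes[:, j, :]
        ok = g[:, 0] != MISSING
        if ok.sum() == 0:
            continue
        per_locus[j] = float(np.mean(g[ok, 0] != g[ok, 1]))
    mean = float(np.nanmean(per_locus)) if np.isfinite(per_locus).any() else math.nan
    return per_locus, mean


def homozygosity_by_locus(pop: GenotypeTable) -> np.ndarray:
    """Homozygosity-by-locus (HL) per individual.

    HL = sum_{h in homozygous loci} E_h / (sum_h E_h + sum_j E_j over
    heterozygous loci j), where E is the locus expected heterozygosity
    (1 - sum p^2) computed from the individual's own population. Missing
    loci drop out of both sums; homozygosity at more variable loci is
    thereby weighted more heavily. Individuals with all loci missing get
    NaN with a warning.
    """
    # population-specific locus weights
    E = np.zeros((len(pop.population_names), pop.n_loci))
    pop_index = {name: k for k, name in enumerate(pop.population_names)}
    for name, k in pop_index.items():
        sub = pop.population(name)
        for j in range(pop.n_loci):
            freqs = _locus_frequencies(sub, j)
            E[k, j] = 1.0 - sum(f * f for f in freqs.values())

    hl = np.full(pop.n_individuals, np.nan)
    for i in range(pop.n_individuals):
        k = pop_index[pop.populations[i]]
        g = pop.genotypes[i]
        ok = g[:, 0] != MISSING
        if not ok.any():
            warnings.warn(
                f"individual {pop.individual_ids[i]}: all loci missing; HL undefined",
                stacklevel=2,
            )
            continue
        hom = ok & (g[:, 0] == g[:, 1])
        denom = E[k, ok].sum()
        hl[i] = E[k, hom].sum() / denom if denom > 0 else 0.0
    return hl


def allelic_richness(pop: GenotypeTable, g: int = 28) -> tuple[np.ndarray, float]:
    """Rarefied allelic richness per locus, standardized to g sampled genes.

    AR = sum over alleles of [1 - C(N - N_i, g) / C(N, g)], the expected
    number of distinct alleles in a random subsample of g genes. The
    default g = 28 genes corresponds to 14 diploid individuals. Loci with
    fewer than g genes sampled are excluded with a warning.
    """
    per_locus = np.full(pop.n_loci, np.nan)
    for j in range(pop.n_loci):
        counts = allele_counts(pop, j)
        N = sum(counts.values())
        if N < g:
            warnings.warn(
                f"locus {pop.loci[j]}: {N} genes < rarefaction size {g}; excluded",
                stacklevel=2,
            )
            continue
        denom = math.comb(N, g)
        ar = 0.0
        for n_i in counts.values():
            ar += 1.0 - math.comb(N - n_i, g) / denom
        per_locus[j] = ar
    mean = float(np.nanmean(per_locus)) if np.isfinite(per_locus).any() else math.nan
    return per_locus, mean


def private_alleles(table: GenotypeTable) -> dict[str, int]:
    """Number of alleles observed in exactly one population, per population."""
    pops = table.population_names
    if len(pops) < 2:
        raise ValueError("private alleles require at least 2 populations")
    counts = {p: 0 for p in pops}
    for j in range(table.n_loci):
        seen: dict[int, set[str]] = {}
        for p in pops:
            sub = table.population(p)
            for a in allele_counts(sub, j):
                seen.setdefault(a, set()).add(p)
        for a, owners in seen.items():
            if len(owners) == 1:
                counts[next(iter(owners))] += 1
    return counts


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (F_ST)
# ---------------------------------------------------------------------------

def weir_cockerham_theta(table: GenotypeTable) -> float:
    """Multi-population, multi-locus Weir & Cockerham θ.

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are computed per
    allele per locus and summed; θ = Σa / Σ(a+b+c). Loci/alleles with
    undefined components (e.g. a population fully missing) drop out.
    """
    pops = table.population_names
    r = len(pops)
    if r < 2:
        raise ValueError("θ requires at least 2 populations")
    subs = [table.population(p) for p in pops]

    sum_a = sum_abc = 0.0
    for j in range(table.n_loci):
        # per-population sample sizes (diploids genotyped at locus j)
        n = np.array([
            int((s.genotypes[:, j, 0] != MISSING).sum()) for s in subs
        ], dtype=float)
        use = n > 0
        if use.sum() < 2:
            continue
        n_use = n[use]
        r_j = int(use.sum())
        alleles = sorted(
            set().union(*(allele_counts(s, j) for s, u in zip(subs, use) if u))
        )
        if len(alleles) < 2:
            continue
        nbar = n_use.mean()
        if nbar <= 1:
            continue
        n_c = (r_j * nbar - np.sum(n_use**2) / (r_j * nbar)) / (r_j - 1)
        if n_c <= 0:
            continue
        for allele in alleles:
            p_i = np.zeros(r_j)
            h_i = np.zeros(r_j)
            for k, s in enumerate(s for s, u in zip(subs, use) if u):
                g = s.genotypes[:, j, :]
                ok = g[:, 0] != MISSING
                gi = g[ok]
                p_i[k] = np.mean(gi == allele)
                h_i[k] = np.mean((gi[:, 0] == allele) ^ (gi[:, 1] == allele))
            pbar = np.sum(n_use * p_i) / (r_j * nbar)
            s2 = np.sum(n_use * (p_i - pbar) ** 2) / ((r_j - 1) * nbar)
            hbar = np.sum(n_use * h_i) / (r_j * nbar)
            a = (nbar / n_c) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - s2 * (r_j - 1) / r_j - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r_j - 1) / r_j
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            sum_a += a
            sum_abc += a + b + c
    if sum_abc == 0:
        return math.nan
    return sum_a / sum_abc


@dataclass
class PermutationResult:
    statistic: float
    p_value: float | None
    n_perm: int
    flags: list[str] = field(default_factory=list)


def pairwise_fst(
    pop_a: GenotypeTable,
    pop_b: GenotypeTable,
    n_perm: int = 0,
    seed: int | None = None,
) -> PermutationResult:
    """Pairwise Weir–Cockerham θ with a permutation p-value.

    The null distribution permutes individuals between the two
    populations; p is the fraction of permuted θ ≥ observed (add-one).
    """
    for pop in (pop_a, pop_b):
        if pop.n_individuals < 2:
            raise ValueError("each population needs at least 2 individuals")
    merged = _stack(pop_a, pop_b)
    theta = weir_cockerham_theta(merged)
    flags = []
    if not math.isfinite(theta):
        flags.append("monomorphic")
    if n_perm <= 0:
        return PermutationResult(theta, None, 0, flags)
    rng = np.random.default_rng(seed)
    n_a = pop_a.n_individuals
    labels = np.array(merged.populations)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(merged.n_individuals)
        shuffled = GenotypeTable(
            merged.individual_ids,
            [("A" if i < n_a else "B") for i in np.argsort(perm)],
            merged.loci,
            merged.genotypes,
        )
        t = weir_cockerham_theta(shuffled)
        if math.isfinite(t) and t >= theta:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(theta, p, n_perm, flags)


def _stack(pop_a: GenotypeTable, pop_b: GenotypeTable) -> GenotypeTable:
    if pop_a.loci != pop_b.loci:
        raise ValueError("locus lists differ between populations")
    return GenotypeTable(
        pop_a.individual_ids + pop_b.individual_ids,
        ["A"] * pop_a.n_individuals + ["B"] * pop_b.n_individuals,
        list(pop_a.loci),
        np.concatenate([pop_a.genotypes, pop_b.genotypes], axis=0),
    )


# ---------------------------------------------------------------------------
# AMOVA Phi_ST on haplotypes
# ---------------------------------------------------------------------------

def _pairwise_differences(haps: HaplotypeSet) -> np.ndarray:
    """Matrix of pairwise nucleotide differences; gap/N sites pairwise-deleted."""
    mat = haps.matrix()
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    n = haps.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        d[i, i + 1:] = diff.sum(axis=1)
    return d + d.T


def _phist_from_distance(d: np.ndarray, labels: np.ndarray) -> float:
    """Two-level AMOVA Φ_ST from a squared-distance matrix and group labels."""
    n = len(labels)
    groups = np.unique(labels)
    P = len(groups)
    ss_total = d[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    sizes = np.zeros(P)
    for k, g in enumerate(groups):
        idx = np.where(labels == g)[0]
        sizes[k] = len(idx)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = P - 1, n - P
    if df_within <= 0:
        return math.nan
    sigma_w = ss_within / df_within
    n_c = (n - np.sum(sizes**2) / n) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return math.nan
    return sigma_a / denom


def pairwise_phist(
    pop_a: HaplotypeSet,
    pop_b: HaplotypeSet,
    n_perm: int = 0,
    seed: int | None = None,
) -> PermutationResult:
    """AMOVA Φ_ST between two haplotype samples, permuting individuals."""
    haps = HaplotypeSet(
        pop_a.sequence_ids + pop_b.sequence_ids,
        ["A"] * pop_a.n_sequences + ["B"] * pop_b.n_sequences,
        pop_a.sequences + pop_b.sequences,
    )
    d = _pairwise_differences(haps)
    labels = np.array(haps.populations)
    phi = _phist_from_distance(d, labels)
    flags = [] if math.isfinite(phi) else ["undefined: no haplotype variation"]
    if n_perm <= 0 or not math.isfinite(phi):
        return PermutationResult(phi, None, 0, flags)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        t = _phist_from_distance(d, rng.permutation(labels))
        if math.isfinite(t) and t >= phi:
            exceed += 1
    return PermutationResult(phi, (exceed + 1) / (n_perm + 1), n_perm, flags)


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

def _rst_components(
    sizes_by_pop: list[np.ndarray],
) -> tuple[float, float]:
    """One-locus ANOVA on allele sizes: (among-pop, within-pop) components."""
    sizes_by_pop = [s for s in sizes_by_pop if s.size > 0]
    P = len(sizes_by_pop)
    if P < 2:
        return 0.0, 0.0
    all_sizes = np.concatenate(sizes_by_pop)
    n = all_sizes.size
    counts = np.array([s.size for s in sizes_by_pop], dtype=float)
    grand = all_sizes.mean()
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in sizes_by_pop)
    ss_among = sum(
        c * (s.mean() - grand) ** 2 for c, s in zip(counts, sizes_by_pop)
    )
    df_among, df_within = P - 1, n - P
    if df_within <= 0:
        return 0.0, 0.0
    sigma_w = ss_within / df_within
    n_c = (n - np.sum(counts**2) / n) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_c
    return sigma_a, sigma_w


def rst_anova(table: GenotypeTable, exclude: list[str] | None = None) -> float:
    """Multi-locus R_ST: allele-size variance components summed over loci.

    Monomorphic loci (and any in `exclude`) are dropped.
    """
    exclude = set(exclude or [])
    pops = table.population_names
    subs = [table.population(p) for p in pops]
    sum_a = sum_w = 0.0
    for j, locus in enumerate(table.loci):
        if locus in exclude:
            continue
        per_pop = []
        for s in subs:
            alleles = s.genotypes[:, j, :].ravel()
            per_pop.append(alleles[alleles != MISSING].astype(float))
        pooled = np.concatenate(per_pop)
        if pooled.size == 0 or np.unique(pooled).size < 2:
            continue  # monomorphic
        a, w = _rst_components(per_pop)
        sum_a += a
        sum_w += w
    if sum_a + sum_w == 0:
        return math.nan
    return sum_a / (sum_a + sum_w)


def allele_size_permutation_test(
    table: GenotypeTable,
    n_perm: int = 10000,
    exclude: list[str] | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Test whether allele sizes carry differentiation information (pRST).

    The observed R_ST is compared with a null distribution obtained by
    randomly permuting the sizes assigned to the distinct allelic states
    within each locus (allele identity, and hence F_ST, is preserved).
    One-sided p = fraction of permuted R_ST ≥ observed; a small p
    indicates that stepwise mutation has contributed to divergence, i.e.
    populations have been isolated on an evolutionary timescale.
    """
    exclude_set = set(exclude or [])
    observed = rst_anova(table, exclude)
    if n_perm <= 0:
        return PermutationResult(observed, None, 0)
    rng = np.random.default_rng(seed)
    # monomorphic loci never contribute; identify usable loci once
    usable = []
    for j, locus in enumerate(table.loci):
        if locus in exclude_set:
            continue
        alleles = table.genotypes[:, j, :].ravel()
        if np.unique(alleles[alleles != MISSING]).size >= 2:
            usable.append(j)
    exceed = 0
    for _ in range(n_perm):
        geno = table.genotypes.copy()
        for j in usable:
            col = geno[:, j, :]
            states = np.unique(col[col != MISSING])
            remap = dict(zip(states.tolist(), rng.permutation(states).tolist()))
            remap[MISSING] = MISSING
            geno[:, j, :] = np.vectorize(remap.get)(col)
        permuted = GenotypeTable(
            table.individual_ids, table.populations, table.loci, geno,
        )
        t = rst_anova(permuted, exclude)
        if math.isfinite(t) and t >= observed:
            exceed += 1
    return PermutationResult(observed, (exceed + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# mtDNA summaries and neutrality tests
# ---------------------------------------------------------------------------

def mtdna_summary(haps: HaplotypeSet) -> tuple[float, float, int]:
    """(Hd, π per site, S) for one population's aligned haplotypes.

    Hd uses the unbiased n/(n−1) factor; π is the mean pairwise
    difference per site with gap/N sites excluded pairwise; S counts
    sites with ≥2 distinct valid bases.
    """
    n = haps.n_sequences
    if n < 2:
        raise ValueError("mtDNA summary requires at least 2 sequences")
    _, counts = np.unique(haps.sequences, return_counts=True)
    f = counts / n
    hd = (n / (n - 1)) * (1.0 - np.sum(f**2))

    mat = haps.matrix()
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"])
    total_diff = total_sites = 0.0
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        total_diff += diff.sum()
        total_sites += both.sum()
    pi = total_diff / total_sites if total_sites > 0 else math.nan

    s = 0
    for col in range(haps.length):
        bases = mat[valid[:, col], col]
        if np.unique(bases).size >= 2:
            s += 1
    return float(hd), float(pi), int(s)


def mean_pairwise_differences(haps: HaplotypeSet) -> float:
    """Mean number of pairwise nucleotide differences (not per site)."""
    d = _pairwise_differences(haps)
    n = haps.n_sequences
    return float(d[np.triu_indices(n, 1)].mean())


def tajimas_d(haps: HaplotypeSet) -> float:
    """Tajima's D comparing π-based and S-based estimates of θ.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    n = haps.n_sequences
    if n < 3:
        raise ValueError("Tajima's D requires at least 3 sequences")
    _, _, S = mtdna_summary(haps)
    if S == 0:
        return math.nan
    k = mean_pairwise_differences(haps)
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((k - S / a1) / math.sqrt(var))


def _log_stirling_first_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grow = log_s + (math.log(m - 1) if m > 1 else -np.inf)
        new[1:] = np.logaddexp(grow[1:], log_s[:-1])
        new[0] = -np.inf if m > 0 else 0.0
        log_s = new
    return log_s


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k | θ, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_first_row(n)
    ks = np.arange(n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    with np.errstate(divide="ignore"):
        log_p = log_s + ks * math.log(theta) - log_rising
    p = np.exp(log_p)
    p[0] = 0.0
    return p / p.sum()


def fus_fs(haps: HaplotypeSet) -> float:
    """Fu's Fs from the Ewens sampling probability of ≥ k_obs haplotypes.

    θ is estimated by the mean number of pairwise differences. Strongly
    negative Fs indicates an excess of haplotypes (recent expansion or
    selection). NaN when there is no sequence variation.
    """
    n = haps.n_sequences
    if n < 3:
        raise ValueError("Fu's Fs requires at least 3 sequences")
    theta = mean_pairwise_differences(haps)
    if theta <= 0:
        return math.nan
    k_obs = len(set(haps.sequences))
    p = ewens_k_distribution(n, theta)
    s_prime = p[k_obs:].sum()
    if s_prime <= 0 or s_prime >= 1:
        return math.nan
    return float(math.log(s_prime / (1 - s_prime)))


def neutrality_tests(haps: HaplotypeSet) -> tuple[float, float]:
    """(Tajima's D, Fu's Fs) for one population's haplotypes."""
    return tajimas_d(haps), fus_fs(haps)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------

def diversity_summary(
    genotypes: GenotypeTable,
    haplotypes: HaplotypeSet | None = None,
    rarefaction_genes: int = 28,
) -> pd.DataFrame:
    """Per-population diversity table (He, Ho, AR, private alleles, Hd, π, S, D, Fs)."""
    rows = []
    priv = private_alleles(genotypes) if len(genotypes.population_names) > 1 else {}
    for pop_name in genotypes.population_names:
        sub = genotypes.population(pop_name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, he = expected_heterozygosity(sub)
            _, ho = observed_heterozygosity(sub)
            _, ar = allelic_richness(sub, g=rarefaction_genes)
        row: dict[str, object] = {
            "population": pop_name,
            "n": sub.n_individuals,
            "He": he,
            "Ho": ho,
            "AR": ar,
            "private_alleles": priv.get(pop_name, 0),
        }
        if haplotypes is not None and pop_name in haplotypes.population_names:
            hpop = haplotypes.population(pop_name)
            if hpop.n_sequences >= 2:
                hd, pi, s = mtdna_summary(hpop)
                row.update(Hd=hd, pi=pi, S=s)
                if hpop.n_sequences >= 3:
                    row["TajimaD"] = tajimas_d(hpop)
                    row["FuFs"] = fus_fs(hpop)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_matrix(
    table: GenotypeTable, n_perm: int = 0, seed: int | None = None
) -> pd.DataFrame:
    """Symmetric pairwise θ matrix over all populations."""
    pops = table.population_names
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            res = pairwise_fst(table.population(a), table.population(b), n_perm, seed)
            mat.loc[a, b] = mat.loc[b, a] = res.statistic
    return mat
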