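"""Synthetic genotype, haplotype and environmental fixtures with known truth.

The genotype generator uses the Balding–Nichols model: each population's
allele frequencies are drawn from a Dirichlet centred on the ancestral
frequencies with concentration (1 − F)/F, so the drift parameter F plays
the role of F_ST. Haplotypes follow a star-like genealogy with
population-private and shared haplotypes in controllable proportions.
The environmental generator plants known effects of multivariate-normal
site variables on an individual homozygosity-like response, with basin
and site variance components, so variable-selection recovery can be
scored against truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rescuegen.containers import GenotypeTable, HaplotypeSet, SiteEnvTable
from rescuegen import io as rio

__all__ = [
    "MetapopSpec",
    "EnvEffectSpec",
    "simulate_metapopulation",
    "simulate_haplotypes",
    "simulate_env_hl",
    "make_fixture_bundle",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class MetapopSpec:
    """Hierarchically structured multi-population genotype specification.

    `ancestral_freqs` is one frequency vector per locus; `drift_f` is the
    Balding–Nichols differentiation parameter per population (scalar
    broadcast allowed), strictly inside (0, 1).
    """

    n_populations: int = 16
    n_per_pop: int = 50
    ancestral_freqs: list[np.ndarray] = field(default_factory=list)
    drift_f: float | list[float] = 0.1
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.n_per_pop < 1:
            raise ValueError("population count and sample size must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        fs = self.drift_values
        if any(f <= 0 or f >= 1 for f in fs):
            raise ValueError("drift F must be strictly inside (0, 1)")
        for j, p in enumerate(self.ancestral_freqs):
            p = np.asarray(p, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"ancestral frequencies at locus {j} must sum to 1")
            self.ancestral_freqs[j] = p

    @property
    def drift_values(self) -> list[float]:
        if np.isscalar(self.drift_f):
            return [float(self.drift_f)] * self.n_populations
        return [float(f) for f in self.drift_f]

    @property
    def n_loci(self) -> int:
        return len(self.ancestral_freqs)


def default_ancestral_freqs(
    rng: np.random.Generator, n_loci: int = 19, mean_alleles: float = 13.0
) -> list[np.ndarray]:
    """Microsatellite-like ancestral frequency vectors (Dirichlet draws)."""
    out = []
    for _ in range(n_loci):
        k = max(2, int(rng.poisson(mean_alleles - 1)) + 1)
        out.append(rng.dirichlet(np.ones(k)))
    return out


def simulate_metapopulation(spec: MetapopSpec, seed: int) -> GenotypeTable:
    """Draw a multi-population genotype table under Balding–Nichols drift.

    Population frequencies ~ Dirichlet(ancestral × (1 − F)/F); genotypes
    are two binomial draws per locus; missing genotypes are masked
    completely at random at the specified rate.
    """
    rng = np.random.default_rng(seed)
    if not spec.ancestral_freqs:
        spec = MetapopSpec(
            spec.n_populations, spec.n_per_pop,
            default_ancestral_freqs(rng), spec.drift_f, spec.missing_rate,
        )
    n_loci = spec.n_loci
    loci = [f"L{j:02d}" for j in range(n_loci)]
    ids: list[str] = []
    pops: list[str] = []
    geno = np.zeros((spec.n_populations * spec.n_per_pop, n_loci, 2), dtype=np.int32)
    row = 0
    for k, f_drift in enumerate(spec.drift_values):
        pop_name = f"pop{k:02d}"
        conc = (1.0 - f_drift) / f_drift
        for j, anc in enumerate(spec.ancestral_freqs):
            p = rng.dirichlet(np.maximum(anc * conc, 1e-9))
            sizes = 100 + 2 * np.arange(len(anc))
            draws = rng.choice(sizes, size=(spec.n_per_pop, 2), p=p)
            geno[row:row + spec.n_per_pop, j, :] = draws
        for i in range(spec.n_per_pop):
            ids.append(f"{pop_name}_ind{i:03d}")
            pops.append(pop_name)
        row += spec.n_per_pop
    if spec.missing_rate > 0:
        mask = rng.random((geno.shape[0], n_loci)) < spec.missing_rate
        geno[mask] = 0
    return GenotypeTable(ids, pops, loci, geno)


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_haplotypes(
    n_pops: int,
    per_pop: int,
    length: int = 400,
    shared_fraction: float = 0.5,
    haplotypes_per_pop: int = 3,
    n_shared: int = 2,
    singleton_excess: int = 0,
    seed: int = 0,
) -> HaplotypeSet:
    """Star-like haplotype genealogy with private and shared haplotypes.

    A central ancestral haplotype is mutated at distinct sites to create
    `n_shared` haplotypes available to every population and
    `haplotypes_per_pop` private haplotypes per population. Each sampled
    sequence is a shared haplotype with probability `shared_fraction`,
    otherwise a private one. `singleton_excess` adds that many sampled
    sequences per population carrying a unique extra mutation each
    (star-expansion signature driving Tajima's D negative).
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    needed = n_shared + n_pops * haplotypes_per_pop + n_pops * per_pop
    if length < needed:
        raise ValueError(
            f"alignment length {length} too short for {needed} distinct mutation sites"
        )
    ancestral = _BASES[rng.integers(0, 4, size=length)].copy()
    sites = rng.permutation(length)
    cursor = 0

    def mutate(base_seq: np.ndarray, n_mut: int) -> np.ndarray:
        nonlocal cursor
        seq = base_seq.copy()
        for _ in range(n_mut):
            pos = sites[cursor]
            cursor += 1
            current = seq[pos]
            choices = _BASES[_BASES != current]
            seq[pos] = rng.choice(choices)
        return seq

    shared = [mutate(ancestral, 1) for _ in range(n_shared)]
    ids, pops, seqs = [], [], []
    for k in range(n_pops):
        private = [mutate(ancestral, 1) for _ in range(haplotypes_per_pop)]
        pop_name = f"pop{k:02d}"
        for i in range(per_pop):
            if n_shared > 0 and rng.random() < shared_fraction:
                hap = shared[rng.integers(0, n_shared)]
            else:
                hap = private[rng.integers(0, len(private))]
            seqs.append(hap.tobytes().decode())
            ids.append(f"seq{k:02d}_{i:03d}|{pop_name}")
            pops.append(pop_name)
        for s in range(singleton_excess):
            hap = mutate(private[0], 1)
            seqs.append(hap.tobytes().decode())
            ids.append(f"seq{k:02d}_s{s:03d}|{pop_name}")
            pops.append(pop_name)
    return HaplotypeSet(ids, pops, seqs)


# ---------------------------------------------------------------------------
# Environment + homozygosity response
# ---------------------------------------------------------------------------

@dataclass
class EnvEffectSpec:
    """Planted-truth specification for the environment → homozygosity model."""

    n_variables: int = 7
    true_inclusion: list[bool] = field(default_factory=list)
    true_effects: list[float] = field(default_factory=list)
    noise_sd: float = 0.1
    basin_sd: float = 0.05
    site_sd: float = 0.05
    intercept: float = 0.4
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.true_inclusion:
            self.true_inclusion = [False] * self.n_variables
        if not self.true_effects:
            self.true_effects = [0.0] * self.n_variables
        if len(self.true_inclusion) != self.n_variables:
            raise ValueError("one inclusion indicator per variable required")
        if len(self.true_effects) != self.n_variables:
            raise ValueError("one effect size per variable required")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (self.n_variables, self.n_variables):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            self.correlation = c

    @property
    def effects(self) -> np.ndarray:
        return np.where(self.true_inclusion, self.true_effects, 0.0)


def simulate_env_hl(
    genotypes: GenotypeTable,
    spec: EnvEffectSpec,
    seed: int,
    sites_per_pop: int = 2,
) -> tuple[SiteEnvTable, pd.DataFrame]:
    """Environmental table plus a per-individual homozygosity-like response.

    Sites are assigned within populations (populations alternate between
    two basins); site variables are multivariate normal with the requested
    correlation; the response is
    intercept + Σ effects·x + basin + site + noise, truncated to [0, 1].
    Returns ``(SiteEnvTable, DataFrame[individual_id, population, site,
    basin, hl])``; the genotype table's individuals are also assigned
    sites round-robin.
    """
    rng = np.random.default_rng(seed)
    pops = genotypes.population_names
    corr = spec.correlation if spec.correlation is not None else np.eye(spec.n_variables)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(spec.n_variables))

    site_rows = []
    basin_of = {p: f"basin{(i % 2)}" for i, p in enumerate(pops)}
    basin_eff = {b: rng.normal(0, spec.basin_sd) for b in {*basin_of.values()}}
    site_ids, site_env, site_eff, site_pop = [], {}, {}, {}
    for p in pops:
        for s in range(sites_per_pop):
            sid = f"{p}_site{s}"
            x = chol @ rng.standard_normal(spec.n_variables)
            site_ids.append(sid)
            site_env[sid] = x
            site_eff[sid] = rng.normal(0, spec.site_sd)
            site_pop[sid] = p
            site_rows.append({
                "site_id": sid, "population": p, "basin": basin_of[p],
                **{f"env{v:02d}": x[v] for v in range(spec.n_variables)},
            })
    env = SiteEnvTable(pd.DataFrame(site_rows))

    effects = spec.effects
    rows = []
    for i in range(genotypes.n_individuals):
        p = genotypes.populations[i]
        sid = f"{p}_site{i % sites_per_pop}"
        x = site_env[sid]
        hl = (
            spec.intercept
            + float(effects @ x)
            + basin_eff[basin_of[p]]
            + site_eff[sid]
            + rng.normal(0, spec.noise_sd)
        )
        rows.append({
            "individual_id": genotypes.individual_ids[i],
            "population": p,
            "site": sid,
            "basin": basin_of[p],
            "hl": float(np.clip(hl, 0.0, 1.0)),
        })
    return env, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def make_fixture_bundle(out_dir: str | Path, seed: int) -> dict:
    """Write a coherent small synthetic dataset plus a truth manifest.

    Contents: a 16-population, 19-locus genotype table (Genepop + CSV),
    a haplotype alignment (FASTA), a site environment table (CSV) with
    one planted effect on the homozygosity response, and
    ``manifest.json`` recording every generating parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    drift = [round(0.02 + 0.015 * k, 4) for k in range(16)]
    spec = MetapopSpec(
        n_populations=16,
        n_per_pop=50,
        ancestral_freqs=default_ancestral_freqs(rng, n_loci=19, mean_alleles=13.0),
        drift_f=drift,
        missing_rate=0.01,
    )
    genotypes = simulate_metapopulation(spec, seed=seed + 1)
    haps = simulate_haplotypes(
        n_pops=16, per_pop=12, length=400, shared_fraction=0.4, seed=seed + 2
    )
    env_spec = EnvEffectSpec(
        n_variables=7,
        true_inclusion=[True, False, False, False, False, False, False],
        true_effects=[0.3, 0, 0, 0, 0, 0, 0],
    )
    env, hl = simulate_env_hl(genotypes, env_spec, seed=seed + 3)

    rio.write_genepop(genotypes, out / "genotypes.gen")
    rio.write_genotype_csv(genotypes, out / "genotypes.csv")
    rio.write_fasta_alignment(haps, out / "haplotypes.fasta")
    rio.write_env_table(env, out / "environment.csv")
    hl.to_csv(out / "hl_response.csv", index=False)

    manifest = {
        "seed": seed,
        "n_populations": spec.n_populations,
        "n_per_pop": spec.n_per_pop,
        "n_loci": spec.n_loci,
        "drift_f": drift,
        "mean_drift_f": float(np.mean(drift)),
        "missing_rate": spec.missing_rate,
        "haplotype_shared_fraction": 0.4,
        "env_true_effects": env_spec.true_effects,
        "env_true_inclusion": env_spec.true_inclusion,
        "env_noise_sd": env_spec.noise_sd,
        "files": [
            "genotypes.gen", "genotypes.csv", "haplotypes.fasta",
            "environment.csv", "hl_response.csv",
        ],
    }
    payload = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
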