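"""Age-structured, two-sex, individual-based genetic-rescue simulator.

Simulates adult-only populations of a long-lived iteroparous fish with
pedigree inbreeding, inbreeding depression from lethal equivalents, and
neutral marker tracking (19 unlinked diploid microsatellite-like loci
plus one maternally inherited haplotype locus). Juvenile life stages are
folded into a single recruitment-survival probability applied when a
cohort enters the adult population at the age of maturity.

Annual cycle: (1) breeding — the realized proportion of females breeding
is the configured mean perturbed by a normal environmental deviate,
truncated to [0, 1]; sires are drawn with replacement from a randomly
chosen fraction of adult males (polygyny); (2) viability — offspring
homozygous for any recessive lethal allele die; the rest recruit with
probability ``recruit_survival × exp(−b·F)`` where ``b`` is the
non-lethal portion of the diploid lethal-equivalent load and F the
offspring's pedigree inbreeding coefficient; (3) mortality — annual
adult survival per age class, death beyond the maximum age; (4)
regulation — uniform random truncation to carrying capacity.

Inbreeding depression follows the standard lethal-equivalents
partition: each founder carries ``Poisson(LE × lethal_fraction)`` unique
recessive lethal alleles per diploid genome; the remaining load acts as
the exponential decline
``exp(−LE × (1 − lethal_fraction) × F)`` of recruitment survival.

All populations of a scenario share one state object and one kinship
matrix, so translocation is a change of population label and the union
pedigree is preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from rescuegen.ne import LifeHistory, temporal_ne

__all__ = [
    "PopulationInit",
    "TranslocationPlan",
    "SimConfig",
    "MetapopState",
    "ScenarioSummary",
    "marker_frequencies_for_he",
    "init_population",
    "step_year",
    "translocate",
    "run_scenario",
    "summarize_pair",
    "DEFAULT_CALIBRATION",
]

_SENT = np.iinfo(np.int32).max
_LETHAL_WIDTH = 32


@njit(cache=False)
def _kin_update(K, slots, mothers, fathers, f_off):  # pragma: no cover - jitted
    """Insert recruit rows/columns into the kinship matrix in place.

    Three passes keep the memory access cache-friendly: (1) contiguous
    row writes from parent rows; (2) recruit-recruit entries via the
    recursive rule applied to already-written recruit rows (half/full-sib
    kinship emerges automatically) plus the (1 + F)/2 diagonal; (3) a
    row-major sweep mirroring recruit rows into columns.
    """
    n = K.shape[0]
    B = slots.shape[0]
    half = np.float32(0.5)
    for b in range(B):
        m, f, s = mothers[b], fathers[b], slots[b]
        for j in range(n):
            K[s, j] = half * (K[m, j] + K[f, j])
        for c in range(b):
            sc = slots[c]
            v = half * (K[sc, m] + K[sc, f])
            K[s, sc] = v
            K[sc, s] = v
        K[s, s] = half * (np.float32(1.0) + f_off[b])
    for j in range(n):
        for b in range(B):
            K[j, slots[b]] = K[slots[b], j]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationInit:
    """Initial conditions for one population."""

    name: str
    n0: int
    carrying_capacity: int | None = None  # defaults to n0
    marker_freqs: list[np.ndarray] | None = None  # per locus, sums to 1
    mt_freqs: np.ndarray | None = None  # haplotype frequencies

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("initial population size must be positive")
        if self.carrying_capacity is None:
            self.carrying_capacity = self.n0
        if self.marker_freqs is not None:
            for j, f in enumerate(self.marker_freqs):
                f = np.asarray(f, dtype=float)
                if f.min() < 0 or abs(f.sum() - 1.0) > 1e-8:
                    raise ValueError(f"marker frequencies at locus {j} must sum to 1")
                self.marker_freqs[j] = f
        if self.mt_freqs is not None:
            self.mt_freqs = np.asarray(self.mt_freqs, dtype=float)
            if abs(self.mt_freqs.sum() - 1.0) > 1e-8:
                raise ValueError("mtDNA haplotype frequencies must sum to 1")


@dataclass
class TranslocationPlan:
    """Move `males` + `females` adults per year from source to recipient."""

    source: str
    recipient: str
    males: int = 3
    females: int = 3
    start_year: int = 1
    stop_year: int = 50

    def __post_init__(self) -> None:
        if self.source == self.recipient:
            raise ValueError("translocation source and recipient must differ")


# Demographic calibration shipped with the package. Annual adult survival
# follows from the ~7-year generation time of a fish maturing at 3 years
# (mean adult age 3 + s/(1−s) ≈ 7 at s = 0.8). The remaining free
# parameters (proportion of females breeding and its environmental SD,
# the breeding-male pool fraction, offspring per breeding female, and
# recruitment survival) were calibrated once, jointly, so that simulated
# populations are quasi-stationary at carrying capacity and the mean
# Ne/N ratio across reference scenarios is ≈ 0.17 (see docs/methods.md).
DEFAULT_CALIBRATION: dict[str, float] = {
    "adult_survival": 0.8,
    "p_female_breed": 0.5,
    "ev_sd": 0.25,
    "ev_survival_sd": 0.12,
    "ev_autocorr": 0.7,
    "male_pool_fraction": 1.0,
    "litter_mean": 4.0,
    "recruit_survival": 0.55,
}


@dataclass
class SimConfig:
    """Full parameterization of a scenario."""

    populations: list[PopulationInit]
    years: int = 100
    replicates: int = 500
    lethal_equivalents: float = 6.29
    lethal_fraction: float = 0.5
    alpha: int = 3  # age at maturity, years
    max_age: int = 26  # alpha + adult life span
    generation_time: float = 7.0
    adult_survival: float = DEFAULT_CALIBRATION["adult_survival"]
    p_female_breed: float = DEFAULT_CALIBRATION["p_female_breed"]
    ev_sd: float = DEFAULT_CALIBRATION["ev_sd"]
    ev_survival_sd: float = DEFAULT_CALIBRATION["ev_survival_sd"]
    ev_autocorr: float = DEFAULT_CALIBRATION["ev_autocorr"]
    male_pool_fraction: float = DEFAULT_CALIBRATION["male_pool_fraction"]
    litter_mean: float = DEFAULT_CALIBRATION["litter_mean"]
    recruit_survival: float = DEFAULT_CALIBRATION["recruit_survival"]
    translocation: TranslocationPlan | None = None
    n_marker_loci: int = 19
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("adult_survival", "p_female_breed", "male_pool_fraction",
                     "recruit_survival", "lethal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lethal_equivalents < 0:
            raise ValueError("lethal equivalents must be non-negative")
        if self.years <= 0 or self.replicates <= 0:
            raise ValueError("years and replicates must be positive")
        if self.max_age < self.alpha:
            raise ValueError("max_age must be at least alpha")
        if not self.populations:
            raise ValueError("at least one population required")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        if self.translocation is not None:
            for end in (self.translocation.source, self.translocation.recipient):
                if end not in names:
                    raise ValueError(f"translocation endpoint {end!r} not a population")

    @property
    def lethal_mean(self) -> float:
        """Mean recessive lethal alleles per diploid founder."""
        return self.lethal_equivalents * self.lethal_fraction

    @property
    def depression_b(self) -> float:
        """Non-lethal inbreeding-depression slope on recruitment survival."""
        return self.lethal_equivalents * (1.0 - self.lethal_fraction)


# ---------------------------------------------------------------------------
# Marker initialization
# ---------------------------------------------------------------------------

def marker_frequencies_for_he(
    n_loci: int,
    mean_alleles: float,
    target_he: float,
    rng: np.random.Generator,
    allele_step: int = 2,
    base_size: int = 100,
) -> list[np.ndarray]:
    """Per-locus allele frequencies with a given mean He and allele count.

    Allele counts per locus alternate between floor and ceil of
    `mean_alleles`; base frequencies are Dirichlet(1,...,1) draws, mixed
    toward fixation of the first allele by a weight found by bisection so
    the mean expected heterozygosity across loci equals `target_he`.
    Returns frequencies indexed by allele size ``base_size + allele_step·i``
    (the caller maps indices to sizes; here only the vectors matter).
    """
    if not 0 <= target_he < 1:
        raise ValueError("target He must be in [0, 1)")
    if mean_alleles < 1:
        raise ValueError("mean alleles per locus must be >= 1")
    lo_k, hi_k = math.floor(mean_alleles), math.ceil(mean_alleles)
    frac_hi = mean_alleles - lo_k
    counts = [hi_k if (i + 0.5) / n_loci <= frac_hi else lo_k for i in range(n_loci)]
    rng.shuffle(counts)
    base = [rng.dirichlet(np.ones(k)) if k > 1 else np.array([1.0]) for k in counts]

    def mean_he(w: float) -> float:
        tot = 0.0
        for f in base:
            p = w * np.eye(len(f))[0] + (1 - w) * f if len(f) > 1 else f
            tot += 1.0 - np.sum(p**2)
        return tot / n_loci

    he0 = mean_he(0.0)
    if he0 < target_he:
        raise ValueError(
            f"target He {target_he} unreachable: max {he0:.3f} for "
            f"{mean_alleles} alleles/locus; increase allele count"
        )
    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_he(mid) > target_he:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    out = []
    for f in base:
        if len(f) == 1:
            out.append(f.copy())
        else:
            p = w * np.eye(len(f))[0] + (1 - w) * f
            out.append(p / p.sum())
    return out


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

class MetapopState:
    """Slot-buffer state for all populations of one scenario.

    Dead slots are recycled for recruits; the kinship matrix row/column
    of a slot is valid only while both slots are alive.
    """

    def __init__(self, cfg: SimConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        # peak occupancy = K plus one year's recruit pulse before truncation
        recruit_frac = 0.5 * cfg.p_female_breed * cfg.litter_mean * cfg.recruit_survival
        caps = [
            int(p.carrying_capacity * (1.02 + 1.1 * recruit_frac)) + 48
            for p in cfg.populations
        ]
        cap = sum(caps)
        self.capacity = cap
        self.alive = np.zeros(cap, dtype=bool)
        self.pop = np.full(cap, -1, dtype=np.int16)
        self.age = np.zeros(cap, dtype=np.int16)
        self.female = np.zeros(cap, dtype=bool)
        self.fped = np.zeros(cap, dtype=np.float32)
        self.markers = np.zeros((cap, cfg.n_marker_loci, 2), dtype=np.int16)
        self.mt = np.zeros(cap, dtype=np.int16)
        self.lethals = np.full((cap, _LETHAL_WIDTH), _SENT, dtype=np.int32)
        self.kin = np.zeros((cap, cap), dtype=np.float32)
        self._next_lethal_id = 0
        self.pop_names = [p.name for p in cfg.populations]
        self.year = 0
        # stationary AR(1) environmental state, one per population
        self.env_z = rng.standard_normal(len(cfg.populations))
        self._pending_kin: list[tuple] = []

    # -- bookkeeping ---------------------------------------------------

    def pop_index(self, name: str) -> int:
        return self.pop_names.index(name)

    def living(self, pop_idx: int | None = None) -> np.ndarray:
        if pop_idx is None:
            return np.where(self.alive)[0]
        return np.where(self.alive & (self.pop == pop_idx))[0]

    def census(self, pop_idx: int) -> int:
        return int((self.alive & (self.pop == pop_idx)).sum())

    def _grow(self, extra: int) -> None:
        old = self.capacity
        new = old + max(extra, old // 4)
        for name in ("alive", "pop", "age", "female", "fped", "mt"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        self.pop[old:] = -1
        m = np.zeros((new, self.cfg.n_marker_loci, 2), dtype=np.int16)
        m[:old] = self.markers
        self.markers = m
        le = np.full((new, _LETHAL_WIDTH), _SENT, dtype=np.int32)
        le[:old] = self.lethals
        self.lethals = le
        k = np.zeros((new, new), dtype=np.float32)
        k[:old, :old] = self.kin
        self.kin = k
        self.capacity = new

    def _claim_slots(self, n: int) -> np.ndarray:
        free = np.where(~self.alive)[0]
        if free.size < n:
            self._grow(n - free.size)
            free = np.where(~self.alive)[0]
        return free[:n]

    # -- statistics ----------------------------------------------------

    def marker_he(self, pop_idx: int) -> float:
        """Mean expected heterozygosity (1 − Σp²) over marker loci."""
        idx = self.living(pop_idx)
        if idx.size == 0:
            return math.nan
        genes = self.markers[idx]  # (n, L, 2)
        he = 0.0
        for j in range(self.cfg.n_marker_loci):
            _, counts = np.unique(genes[:, j, :], return_counts=True)
            p = counts / counts.sum()
            he += 1.0 - np.sum(p**2)
        return he / self.cfg.n_marker_loci

    def mean_alleles(self, pop_idx: int) -> float:
        idx = self.living(pop_idx)
        if idx.size == 0:
            return math.nan
        genes = self.markers[idx]
        return float(
            np.mean([
                np.unique(genes[:, j, :]).size
                for j in range(self.cfg.n_marker_loci)
            ])
        )

    def n_haplotypes(self, pop_idx: int) -> int:
        idx = self.living(pop_idx)
        return int(np.unique(self.mt[idx]).size) if idx.size else 0

    def mean_lethals(self, pop_idx: int) -> float:
        idx = self.living(pop_idx)
        if idx.size == 0:
            return math.nan
        return float((self.lethals[idx] != _SENT).sum() / idx.size)

    def mean_f(self, pop_idx: int) -> float:
        idx = self.living(pop_idx)
        return float(self.fped[idx].mean()) if idx.size else math.nan


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _stable_age_distribution(cfg: SimConfig) -> np.ndarray:
    ages = np.arange(cfg.alpha, cfg.max_age + 1)
    w = cfg.adult_survival ** (ages - cfg.alpha)
    return w / w.sum()


def init_population(state: MetapopState, pop_idx: int) -> None:
    """Populate one population with founders at its initial size.

    Founders: stable age distribution over [alpha, max_age]; equal sex
    probability; Hardy–Weinberg marker genotypes from the configured
    allele frequencies; Poisson-distributed unique recessive lethal
    alleles (mean = LE × lethal_fraction per diploid); pedigree F = 0.
    """
    cfg, rng = state.cfg, state.rng
    pinit = cfg.populations[pop_idx]
    n = pinit.n0
    slots = state._claim_slots(n)
    state.alive[slots] = True
    state.pop[slots] = pop_idx
    ages = np.arange(cfg.alpha, cfg.max_age + 1)
    state.age[slots] = rng.choice(ages, size=n, p=_stable_age_distribution(cfg))
    state.female[slots] = rng.random(n) < 0.5
    state.fped[slots] = 0.0

    if pinit.marker_freqs is None:
        freqs = marker_frequencies_for_he(cfg.n_marker_loci, 5.0, 0.6, rng)
    else:
        freqs = pinit.marker_freqs
    if len(freqs) != cfg.n_marker_loci:
        raise ValueError(
            f"{len(freqs)} marker frequency vectors for {cfg.n_marker_loci} loci"
        )
    for j, f in enumerate(freqs):
        sizes = 100 + 2 * np.arange(len(f))
        state.markers[slots, j, 0] = rng.choice(sizes, size=n, p=f)
        state.markers[slots, j, 1] = rng.choice(sizes, size=n, p=f)

    mtf = pinit.mt_freqs if pinit.mt_freqs is not None else np.ones(1)
    state.mt[slots] = rng.choice(len(mtf), size=n, p=mtf) + 100 * pop_idx

    # unique recessive lethals, Poisson count per founder
    counts = rng.poisson(cfg.lethal_mean, size=n)
    counts = np.minimum(counts, _LETHAL_WIDTH)
    state.lethals[slots] = _SENT
    for i, (slot, c) in enumerate(zip(slots, counts)):
        if c:
            ids = state._next_lethal_id + np.arange(c)
            state.lethals[slot, :c] = ids
            state._next_lethal_id += c

    # founders unrelated, non-inbred: kinship 0 off-diagonal, 0.5 diagonal
    state.kin[np.ix_(slots, slots)] = 0.0
    state.kin[slots, slots] = 0.5


def init_state(cfg: SimConfig, rng: np.random.Generator) -> MetapopState:
    state = MetapopState(cfg, rng)
    for k in range(len(cfg.populations)):
        init_population(state, k)
    return state


# ---------------------------------------------------------------------------
# Annual cycle
# ---------------------------------------------------------------------------

def _breed_population(state: MetapopState, pop_idx: int, env_z: float = 0.0) -> np.ndarray:
    """One population's breeding + viability; returns recruited slot ids."""
    cfg, rng = state.cfg, state.rng
    idx = state.living(pop_idx)
    if idx.size == 0:
        return np.empty(0, dtype=int)
    females = idx[state.female[idx]]
    males = idx[~state.female[idx]]
    if females.size == 0 or males.size == 0:
        return np.empty(0, dtype=int)

    # environmental variation perturbs the proportion of females breeding
    p_breed = float(np.clip(cfg.p_female_breed + cfg.ev_sd * env_z, 0.0, 1.0))
    breeding_f = females[rng.random(females.size) < p_breed]
    if breeding_f.size == 0:
        return np.empty(0, dtype=int)
    pool_size = max(1, int(round(cfg.male_pool_fraction * males.size)))
    pool = rng.choice(males, size=pool_size, replace=False)

    litter = rng.poisson(cfg.litter_mean, size=breeding_f.size)
    n_off = int(litter.sum())
    if n_off == 0:
        return np.empty(0, dtype=int)
    mothers = np.repeat(breeding_f, litter)
    fathers = pool[rng.integers(0, pool.size, size=n_off)]

    # lethal transmission: each carried allele passes with probability 1/2
    tm = state.lethals[mothers]
    tm = np.where((tm != _SENT) & (rng.random(tm.shape) < 0.5), tm, _SENT)
    td = state.lethals[fathers]
    td = np.where((td != _SENT) & (rng.random(td.shape) < 0.5), td, _SENT)
    comb = np.sort(np.concatenate([tm, td], axis=1), axis=1)
    lethal_hom = ((comb[:, 1:] == comb[:, :-1]) & (comb[:, 1:] != _SENT)).any(axis=1)

    # recruitment survival with inbreeding depression on the non-lethal load
    f_off = state.kin[mothers, fathers].astype(float)
    p_recruit = cfg.recruit_survival * np.exp(-cfg.depression_b * f_off)
    recruit = (~lethal_hom) & (rng.random(n_off) < p_recruit)
    if not recruit.any():
        return np.empty(0, dtype=int)

    mothers, fathers = mothers[recruit], fathers[recruit]
    comb = comb[recruit, :_LETHAL_WIDTH]
    f_off = f_off[recruit]
    B = mothers.size
    slots = state._claim_slots(B)

    # kinship rows are expensive; defer them until after this year's
    # mortality and truncation so rows are only written for recruits that
    # survive to stand in next year's breeding pool (recruits never breed
    # in their recruitment year, and no other step reads kinship)
    state._pending_kin.append((slots, mothers, fathers, f_off))

    state.alive[slots] = True
    state.pop[slots] = pop_idx
    state.age[slots] = cfg.alpha
    state.female[slots] = rng.random(B) < 0.5
    state.fped[slots] = f_off
    state.lethals[slots] = comb

    # marker inheritance: one random allele per parent per locus
    L = cfg.n_marker_loci
    pick_m = rng.integers(0, 2, size=(B, L))
    pick_f = rng.integers(0, 2, size=(B, L))
    gm = state.markers[mothers]
    gf = state.markers[fathers]
    jj = np.arange(L)
    state.markers[slots, :, 0] = gm[np.arange(B)[:, None], jj, pick_m]
    state.markers[slots, :, 1] = gf[np.arange(B)[:, None], jj, pick_f]
    state.mt[slots] = state.mt[mothers]  # strictly maternal
    return slots


def step_year(state: MetapopState) -> None:
    """Advance the whole metapopulation by one year."""
    cfg, rng = state.cfg, state.rng
    n_pops = len(cfg.populations)
    # one environmental deviate per population per year drives breeding and
    # survival concordantly (a drought year suppresses both); AR(1)
    # autocorrelation makes droughts multi-year events
    rho = cfg.ev_autocorr
    state.env_z = rho * state.env_z + math.sqrt(1 - rho**2) * rng.standard_normal(n_pops)
    env_z = state.env_z
    recruits_by_pop = [_breed_population(state, k, env_z[k]) for k in range(n_pops)]

    # adult mortality and ageing (this year's recruits are exempt: they
    # enter at age alpha with juvenile survival already applied)
    living = np.where(state.alive)[0]
    new = np.concatenate(recruits_by_pop) if recruits_by_pop else np.empty(0, int)
    is_new = np.zeros(state.capacity, dtype=bool)
    if new.size:
        is_new[new.astype(int)] = True
    old = living[~is_new[living]]
    s_year = np.clip(cfg.adult_survival + cfg.ev_survival_sd * env_z, 0.0, 1.0)
    die = rng.random(old.size) >= s_year[state.pop[old]]
    state.alive[old[die]] = False
    survivors = old[~die]
    state.age[survivors] += 1
    too_old = survivors[state.age[survivors] > cfg.max_age]
    state.alive[too_old] = False

    # carrying-capacity truncation, uniform random
    for k, pinit in enumerate(cfg.populations):
        idx = state.living(k)
        K = pinit.carrying_capacity
        if idx.size > K:
            drop = rng.choice(idx, size=idx.size - K, replace=False)
            state.alive[drop] = False

    # deferred kinship rows for recruits that survived truncation
    for slots, mothers, fathers, f_off in state._pending_kin:
        keep = state.alive[slots]
        if keep.any():
            _kin_update(
                state.kin,
                slots[keep].astype(np.int64),
                mothers[keep].astype(np.int64),
                fathers[keep].astype(np.int64),
                f_off[keep].astype(np.float32),
            )
    state._pending_kin.clear()

    # translocation
    plan = cfg.translocation
    if plan is not None and plan.start_year <= state.year + 1 <= plan.stop_year:
        translocate(
            state,
            state.pop_index(plan.source),
            state.pop_index(plan.recipient),
            males=plan.males,
            females=plan.females,
        )
    state.year += 1


def translocate(
    state: MetapopState,
    source: int,
    recipient: int,
    males: int = 3,
    females: int = 3,
) -> int:
    """Move randomly chosen adults between populations; returns count moved.

    Pedigree, markers and lethal alleles move intact (populations share
    one kinship matrix, so relatedness to descendants of earlier
    migrants is preserved). Shortfalls move whatever is available.
    """
    if source == recipient:
        raise ValueError("source and recipient must differ")
    rng = state.rng
    idx = state.living(source)
    moved = 0
    for want, sel in ((males, ~state.female), (females, state.female)):
        avail = idx[sel[idx]]
        take = min(want, avail.size)
        if take > 0:
            chosen = rng.choice(avail, size=take, replace=False)
            state.pop[chosen] = recipient
            moved += take
    return moved


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSummary:
    """Per-population scenario summary over replicates (final-year statistics)."""

    population: str
    p_extinction: float
    mean_time_to_extinction: float  # NaN if no replicate went extinct
    mean_extant_n: float
    ne_final: float  # temporal Ne from the mean He trajectory of extant reps
    he_year0: float
    he_final: float
    alleles_year0: float
    alleles_final: float
    haplotypes_year0: float
    haplotypes_final: float
    lethals_year0: float
    lethals_final: float

    def as_report_row(self) -> dict[str, float]:
        return {
            "Probability of extinction": self.p_extinction,
            "Time to first extinction, years": self.mean_time_to_extinction,
            "Ne at Year 100": self.ne_final,
            "N (extant) at Year 100": self.mean_extant_n,
            "He at year 0": self.he_year0,
            "He at year 100": self.he_final,
            "Number of alleles at year 0": self.alleles_year0,
            "Number of alleles at year 100": self.alleles_final,
            "Number of haplotypes at year 0": self.haplotypes_year0,
            "Number of haplotypes at year 100": self.haplotypes_final,
            "Number of lethal alleles/individual at year 0": self.lethals_year0,
            "Number of lethal alleles/individual at year 100": self.lethals_final,
        }


_TRAJ_FIELDS = ("n", "he", "alleles", "haplotypes", "lethals", "mean_f")


def run_scenario(
    cfg: SimConfig,
    reps: int | None = None,
    seed: int | None = None,
    return_trajectories: bool = False,
):
    """Run independent replicates and summarize them per population.

    Returns a list of :class:`ScenarioSummary` (one per population), or
    ``(summaries, trajectories)`` where trajectories is a dict
    ``{pop_name: {field: (reps, years+1) array}}``.
    """
    reps = cfg.replicates if reps is None else reps
    if reps < 1:
        raise ValueError("at least one replicate required")
    seed = cfg.seed if seed is None else seed
    n_pops = len(cfg.populations)
    years = cfg.years
    traj = {
        p.name: {f: np.full((reps, years + 1), np.nan) for f in _TRAJ_FIELDS}
        for p in cfg.populations
    }
    ext_year = np.full((reps, n_pops), np.nan)

    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(child_seeds[r])
        state = init_state(cfg, rng)
        for k, p in enumerate(cfg.populations):
            t = traj[p.name]
            t["n"][r, 0] = state.census(k)
            t["he"][r, 0] = state.marker_he(k)
            t["alleles"][r, 0] = state.mean_alleles(k)
            t["haplotypes"][r, 0] = state.n_haplotypes(k)
            t["lethals"][r, 0] = state.mean_lethals(k)
            t["mean_f"][r, 0] = state.mean_f(k)
        for y in range(1, years + 1):
            step_year(state)
            for k, p in enumerate(cfg.populations):
                t = traj[p.name]
                n = state.census(k)
                t["n"][r, y] = n
                if n > 0:
                    t["he"][r, y] = state.marker_he(k)
                    t["alleles"][r, y] = state.mean_alleles(k)
                    t["haplotypes"][r, y] = state.n_haplotypes(k)
                    t["lethals"][r, y] = state.mean_lethals(k)
                    t["mean_f"][r, y] = state.mean_f(k)
                elif math.isnan(ext_year[r, k]):
                    ext_year[r, k] = y

    summaries = []
    for k, p in enumerate(cfg.populations):
        t = traj[p.name]
        extant = t["n"][:, years] > 0
        p_ext = float(1.0 - extant.mean())
        times = ext_year[:, k]
        mean_time = float(np.nanmean(times)) if np.isfinite(times).any() else math.nan
        he0 = float(np.nanmean(t["he"][:, 0]))
        if extant.any():
            he_final = float(np.nanmean(t["he"][extant, years]))
            mean_n = float(np.mean(t["n"][extant, years]))
            al_final = float(np.nanmean(t["alleles"][extant, years]))
            hap_final = float(np.nanmean(t["haplotypes"][extant, years]))
            let_final = float(np.nanmean(t["lethals"][extant, years]))
            est = temporal_ne(
                he0, he_final, years,
                LifeHistory(cfg.alpha, cfg.max_age - cfg.alpha,
                            cfg.generation_time),
            )
            ne_final = est.point
        else:
            he_final = mean_n = al_final = hap_final = let_final = math.nan
            ne_final = math.nan
        summaries.append(ScenarioSummary(
            population=p.name,
            p_extinction=p_ext,
            mean_time_to_extinction=mean_time,
            mean_extant_n=mean_n,
            ne_final=ne_final,
            he_year0=he0,
            he_final=he_final,
            alleles_year0=float(np.nanmean(t["alleles"][:, 0])),
            alleles_final=al_final,
            haplotypes_year0=float(np.nanmean(t["haplotypes"][:, 0])),
            haplotypes_final=hap_final,
            lethals_year0=float(np.nanmean(t["lethals"][:, 0])),
            lethals_final=let_final,
        ))
    if return_trajectories:
        return summaries, traj
    return summaries


def summarize_pair(
    do_nothing: ScenarioSummary, translocation: ScenarioSummary
) -> dict[str, float]:
    """Fold-change comparison of management scenarios for one population."""
    if do_nothing.population != translocation.population:
        raise ValueError("summaries refer to different populations")

    def ratio(a: float, b: float) -> float:
        if b == 0:
            return math.inf
        return a / b

    return {
        "extinction_fold_decrease": ratio(
            do_nothing.p_extinction, translocation.p_extinction
        ),
        "he_fold_increase": ratio(translocation.he_final, do_nothing.he_final),
        "alleles_fold_increase": ratio(
            translocation.alleles_final, do_nothing.alleles_final
        ),
        "n_fold_increase": ratio(
            translocation.mean_extant_n, do_nothing.mean_extant_n
        ),
        "lethals_fold_increase": ratio(
            translocation.lethals_final, do_nothing.lethals_final
        ),
    }


def rescue_onset_year(
    do_nothing_traj: dict[str, np.ndarray],
    translocation_traj: dict[str, np.ndarray],
) -> float:
    """First year the translocated population carries more lethal alleles.

    Genetic rescue shows up as a *larger* mean lethal-allele count under
    translocation than under inaction: immigrants reintroduce masked
    (heterozygous) lethals that inbreeding would otherwise have exposed
    and purged along with overall diversity. Expects the per-year
    trajectory dictionaries from :func:`run_scenario`; returns NaN if the
    translocated load never exceeds the do-nothing load.
    """
    dn = np.nanmean(do_nothing_traj["lethals"], axis=0)
    tr = np.nanmean(translocation_traj["lethals"], axis=0)
    above = np.where(tr > dn)[0]
    return float(above[0]) if above.size else math.nan
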