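"""Spatially explicit forward simulator of pollen and seed dispersal.

This is both the engine for marker-power studies and the package's
synthetic-data generator.  The model is a constant-density, overlapping-
generations life cycle on a rectangular arena with torus boundaries:

* each step, a fraction ``1 - overlap`` of adults dies (uniformly at
  random) and every vacated site is refilled by a new recruit at that site;
* the recruit's mother is drawn among the surviving adults with probability
  proportional to a bivariate-Gaussian seed kernel (axial sd ``sigma_seed``)
  centred on the site, the father among survivors (excluding the mother)
  proportional to a pollen kernel (axial sd ``sigma_pollen``) centred on
  the mother; the recruit inherits one random gene copy per parent and
  locus.  There is no mutation and no selfing.

The axial standard deviation of gene dispersal decomposes as
``sigma_g^2 = sigma_seed^2 + sigma_pollen^2 / 2`` (a pollen event moves one
gene copy); the seed:pollen ratio defaults to 1:10, in the range reported
for beech.  SGS strength is governed by the neighbourhood size
``Nb = 4 pi D sigma_g^2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, GeoGenotypes
from .sgs import DistanceClassSpec, sp_statistic

logger = logging.getLogger(__name__)

#: Beech SSR panel: allele counts of the four field loci.
DEFAULT_ALLELE_COUNTS = [25, 41, 26, 31]

DEFAULT_CHECKPOINTS = (1, 2, 4, 8, 16, 32, 48, 64)


def default_area_ha(density: float, sample_n: int = 90) -> float:
    """Arena area: twice the sampling window, and never fewer than ~150 adults."""
    return max(2.0 * sample_n / density, 150.0 / density)


@dataclass
class SimScenario:
    """Parameterization of one dispersal/density scenario."""

    sigma_g: float
    density: float  # adults per ha
    area_ha: float | None = None
    n_loci: int = 4
    alleles_per_locus: list[int] = field(default_factory=lambda: list(DEFAULT_ALLELE_COUNTS))
    init_freqs: AlleleFrequencies | None = None
    generations: int = 64
    overlap: float = 0.5
    record_at: tuple[int, ...] = DEFAULT_CHECKPOINTS
    sample_n: int = 90
    null_freq: float = 0.0
    seed: int | None = None
    kernel_mode: str = "gene"  # "gene" or "seed_pollen"
    seed_pollen_ratio: float = 0.1  # sigma_seed : sigma_pollen (composite mode)

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be positive")
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if self.area_ha is None:
            self.area_ha = default_area_ha(self.density, self.sample_n)
        if len(self.alleles_per_locus) != self.n_loci:
            if len(self.alleles_per_locus) == 4 and self.n_loci % 4 == 0:
                self.alleles_per_locus = self.alleles_per_locus * (self.n_loci // 4)
            else:
                raise ValueError("alleles_per_locus must have n_loci entries")
        if self.kernel_mode not in ("gene", "seed_pollen"):
            raise ValueError("kernel_mode must be 'gene' or 'seed_pollen'")
        if self.n_individuals < 2:
            raise ValueError("density x area must yield at least 2 individuals")

    @property
    def n_individuals(self) -> int:
        return int(round(self.density * self.area_ha))

    @property
    def side_m(self) -> float:
        return math.sqrt(self.area_ha * 1e4)

    @property
    def sigma_pollen(self) -> float:
        return self.sigma_g / math.sqrt(self.seed_pollen_ratio ** 2 + 0.5)

    @property
    def sigma_seed(self) -> float:
        return self.seed_pollen_ratio * self.sigma_pollen


def named_scenarios(**overrides) -> dict[str, SimScenario]:
    """The four reference scenarios: (sigma_g, density) combinations spanning
    unrealistically strong to nearly absent SGS, plus the two plot-like
    intermediates."""
    params = {
        "HIGH-SGS": (12.0, 20.0),
        "Fl-like": (12.0, 35.0),
        "Fh-like": (29.0, 50.0),
        "LOW-SGS": (72.0, 145.0),
    }
    return {name: SimScenario(sigma_g=s, density=d, **overrides)
            for name, (s, d) in params.items()}


def twenty_locus_scenario(s: SimScenario) -> SimScenario:
    """Five independent copies of the 4-locus panel (20-locus power mode)."""
    return replace(s, n_loci=20, alleles_per_locus=list(s.alleles_per_locus[:4]) * 5,
                   init_freqs=None)


@dataclass
class SimResult:
    records: pd.DataFrame  # replicate, generation, F1, bF, Sp, n_sampled
    snapshots: dict[int, GeoGenotypes]  # final population per replicate
    scenario: SimScenario
    n_reps: int


# ---------------------------------------------------------------------------
# life cycle
# ---------------------------------------------------------------------------

def _draw_init_freqs(s: SimScenario, rng: np.random.Generator) -> AlleleFrequencies:
    freqs = []
    for A in s.alleles_per_locus:
        p = rng.dirichlet(np.ones(A))
        freqs.append({a + 1: float(p[a]) for a in range(A)})
    names = [f"L{l + 1}" for l in range(s.n_loci)]
    n = s.n_individuals
    return AlleleFrequencies(names, freqs, np.full(s.n_loci, 2 * n),
                             np.full(s.n_loci, n))


def init_population(s: SimScenario, rng: np.random.Generator | None = None) -> GeoGenotypes:
    """Found the arena: uniform-random positions, genotypes drawn as two
    independent gene copies per locus from the initial allele frequencies
    (symmetric Dirichlet(1) profiles with the configured allele counts when
    none are supplied)."""
    rng = rng if rng is not None else np.random.default_rng(s.seed)
    n = s.n_individuals
    init = s.init_freqs if s.init_freqs is not None else _draw_init_freqs(s, rng)
    side = s.side_m
    x = rng.uniform(0, side, n)
    y = rng.uniform(0, side, n)
    geno = np.zeros((n, s.n_loci, 2), dtype=np.int64)
    for l in range(s.n_loci):
        alleles = np.array(sorted(init.freqs[l]))
        p = np.array([init.freqs[l][int(a)] for a in alleles])
        geno[:, l, :] = rng.choice(alleles, size=(n, 2), p=p / p.sum())
    ids = [f"g0_{i}" for i in range(n)]
    return GeoGenotypes(ids=ids, plot=np.array(["sim"] * n, dtype=object),
                        x=x, y=y, geno=geno, locus_names=list(init.locus_names))


def _torus_d2(ax, ay, bx, by, side: float) -> np.ndarray:
    dx = np.abs(ax[:, None] - bx[None, :])
    dy = np.abs(ay[:, None] - by[None, :])
    dx = np.minimum(dx, side - dx)
    dy = np.minimum(dy, side - dy)
    return dx ** 2 + dy ** 2


def _gumbel_pick(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from unnormalized log-weights."""
    finite = np.isfinite(logw).any(axis=1)
    if not finite.all():
        raise RuntimeError("no candidate parent with positive kernel weight")
    g = rng.gumbel(size=logw.shape)
    return np.argmax(logw + g, axis=1)


def step_generation(pop: GeoGenotypes, s: SimScenario,
                    rng: np.random.Generator, generation: int = 0) -> GeoGenotypes:
    """One life-cycle step: death, seed and pollen dispersal, replacement."""
    n = pop.n_ind
    n_die = int(round((1 - s.overlap) * n))
    dead = rng.choice(n, size=n_die, replace=False)
    alive = np.setdiff1d(np.arange(n), dead)
    side = s.side_m

    sx, sy = pop.x[alive], pop.y[alive]
    d2_sites = _torus_d2(pop.x[dead], pop.y[dead], sx, sy, side)
    if s.kernel_mode == "gene":
        # both parents drawn with the gene-dispersal kernel centred on the
        # vacated site: each inherited copy moves ~ Gaussian(sigma_g)
        logw = -d2_sites / (2 * s.sigma_g ** 2)
        try:
            mothers = _gumbel_pick(logw, rng)
        except RuntimeError:
            logger.warning("gene kernel degenerate; retrying with doubled sigma")
            logw = -d2_sites / (2 * (2 * s.sigma_g) ** 2)
            mothers = _gumbel_pick(logw, rng)
        logwf = logw.copy()
        logwf[np.arange(len(mothers)), mothers] = -np.inf  # no selfing
        fathers = _gumbel_pick(logwf, rng)
    else:
        # composite cycle: seed kernel site -> mother, pollen kernel
        # mother -> father
        sig_s, sig_p = s.sigma_seed, s.sigma_pollen
        try:
            mothers = _gumbel_pick(-d2_sites / (2 * sig_s ** 2), rng)
        except RuntimeError:
            logger.warning("seed kernel degenerate; retrying with doubled sigma")
            mothers = _gumbel_pick(-d2_sites / (2 * (2 * sig_s) ** 2), rng)
        d2_adults = _torus_d2(sx, sy, sx, sy, side)
        logwp = -d2_adults / (2 * sig_p ** 2)
        np.fill_diagonal(logwp, -np.inf)
        try:
            fathers = _gumbel_pick(logwp[mothers], rng)
        except RuntimeError:
            logger.warning("pollen kernel degenerate; retrying with doubled sigma")
            logwp = -d2_adults / (2 * (2 * sig_p) ** 2)
            np.fill_diagonal(logwp, -np.inf)
            fathers = _gumbel_pick(logwp[mothers], rng)

    L = pop.n_loci
    mg = pop.geno[alive][mothers]  # (n_die, L, 2)
    fg = pop.geno[alive][fathers]
    pick_m = rng.integers(0, 2, size=(n_die, L))
    pick_f = rng.integers(0, 2, size=(n_die, L))
    rows = np.arange(n_die)[:, None]
    cols = np.arange(L)[None, :]
    recruit = np.stack([mg[rows, cols, pick_m], fg[rows, cols, pick_f]], axis=2)

    geno = pop.geno.copy()
    geno[dead] = recruit
    ids = list(pop.ids)
    for j, i in enumerate(dead):
        ids[i] = f"g{generation}_{i}"
    return GeoGenotypes(ids=ids, plot=pop.plot.copy(), x=pop.x.copy(),
                        y=pop.y.copy(), geno=geno, locus_names=list(pop.locus_names))


def sample_window(pop: GeoGenotypes, s: SimScenario,
                  rng: np.random.Generator) -> GeoGenotypes:
    """Sample ``sample_n`` individuals from a centred square window whose
    area is chosen so the expected count equals ``sample_n`` at the scenario
    density (the 'Fh-like' compact sampling scheme); the window is padded
    with nearest individuals if underfull."""
    side = s.side_m
    half = min(side / 2, math.sqrt(s.sample_n / s.density * 1e4) / 2)
    cx = cy = side / 2
    inside = np.flatnonzero((np.abs(pop.x - cx) <= half) & (np.abs(pop.y - cy) <= half))
    if inside.size > s.sample_n:
        inside = rng.choice(inside, size=s.sample_n, replace=False)
    elif inside.size < s.sample_n:
        if s.sample_n >= pop.n_ind:
            logger.warning("sample_n >= population size; sampling everyone")
            inside = np.arange(pop.n_ind)
        else:
            d2c = (pop.x - cx) ** 2 + (pop.y - cy) ** 2
            inside = np.argsort(d2c)[: s.sample_n]
    return pop.subset(np.sort(inside))


def run_scenario(s: SimScenario, n_reps: int = 20, n_perm: int = 0,
                 keep_snapshots: bool = True) -> SimResult:
    """Run replicates of a scenario, measuring SGS at each checkpoint.

    At every checkpoint generation, ``sample_n`` central individuals are
    drawn and F_1, b_F and Sp computed (Loiselle kinship, 20 m first class).
    Permutation tests are off by default for speed (``n_perm=0``).
    """
    rows = []
    snapshots: dict[int, GeoGenotypes] = {}
    spec = DistanceClassSpec(mode="even_width", width_m=20.0)
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([0 if s.seed is None else s.seed, rep]))
        pop = init_population(s, rng)
        # nulls are injected on the sampled snapshot, never the truth
        checkpoints = set(s.record_at) & set(range(1, s.generations + 1))
        if s.generations == 0:
            checkpoints = set()
        todo = sorted(checkpoints)
        if s.generations == 0 or 0 in s.record_at:
            todo = [0] + todo

        def measure(gen: int, population: GeoGenotypes) -> None:
            samp = sample_window(population, s, rng)
            obs = inject_null_alleles(samp, s.null_freq, rng) if s.null_freq > 0 else samp
            summ = sp_statistic(obs, spec=spec, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)))
            rows.append({"replicate": rep, "generation": gen, "F1": summ.F1,
                         "bF": summ.bF, "Sp": summ.Sp, "n_sampled": obs.n_ind})

        if todo and todo[0] == 0:
            measure(0, pop)
        for gen in range(1, s.generations + 1):
            pop = step_generation(pop, s, rng, generation=gen)
            if gen in checkpoints:
                measure(gen, pop)
        if keep_snapshots:
            snapshots[rep] = pop
    return SimResult(records=pd.DataFrame(rows), snapshots=snapshots,
                     scenario=s, n_reps=n_reps)


def inject_null_alleles(pop: GeoGenotypes, null_freq, rng: np.random.Generator) -> GeoGenotypes:
    """Replace gene copies by nulls with per-locus probability ``null_freq``.

    A null/null genotype becomes missing (0, 0); a null/visible genotype
    an apparent homozygote for the visible allele.
    """
    q = np.broadcast_to(np.asarray(null_freq, dtype=float), (pop.n_loci,))
    if (q < 0).any() or (q >= 1).any():
        raise ValueError("null_freq must be in [0, 1)")
    geno = pop.geno.copy()
    is_null = rng.random(geno.shape) < q[None, :, None]
    a, b = geno[:, :, 0].copy(), geno[:, :, 1].copy()
    both = is_null[:, :, 0] & is_null[:, :, 1]
    only_a = is_null[:, :, 0] & ~both
    only_b = is_null[:, :, 1] & ~both
    a[only_a] = b[only_a]
    b[only_b] = a[only_b]
    a[both] = 0
    b[both] = 0
    out = np.stack([a, b], axis=2)
    return GeoGenotypes(ids=list(pop.ids), plot=pop.plot.copy(), x=pop.x.copy(),
                        y=pop.y.copy(), geno=out, locus_names=list(pop.locus_names))


def inject_all_null(pop: GeoGenotypes) -> GeoGenotypes:
    """Limit case null_freq -> 1: every genotype missing."""
    geno = np.zeros_like(pop.geno)
    return GeoGenotypes(ids=list(pop.ids), plot=pop.plot.copy(), x=pop.x.copy(),
                        y=pop.y.copy(), geno=geno, locus_names=list(pop.locus_names))


# ---------------------------------------------------------------------------
# non-spatial synthetic generators (planted-structure fixtures)
# ---------------------------------------------------------------------------

def sample_island_model(n_groups: int, n_per_group: int, theta: float,
                        alleles_per_locus: list[int] | None = None,
                        rng: np.random.Generator | None = None,
                        side_m: float = 100.0,
                        spatial_blocks: bool = False) -> tuple[GeoGenotypes, np.ndarray]:
    """Groups drawn from a Balding-Nichols island model at differentiation
    ``theta``: ancestral frequencies ~ Dirichlet(1); group frequencies ~
    Dirichlet(p_anc (1-theta)/theta); genotypes in Hardy-Weinberg within
    groups.  Coordinates are uniform over a square (``spatial_blocks``
    instead lays groups out in side-by-side vertical strips).

    Returns the dataset and the true group label per individual (0-based).
    """
    rng = rng if rng is not None else np.random.default_rng()
    alleles_per_locus = alleles_per_locus or DEFAULT_ALLELE_COUNTS
    L = len(alleles_per_locus)
    n = n_groups * n_per_group
    labels = np.repeat(np.arange(n_groups), n_per_group)
    geno = np.zeros((n, L, 2), dtype=np.int64)
    for l, A in enumerate(alleles_per_locus):
        p_anc = rng.dirichlet(np.ones(A))
        for k in range(n_groups):
            if theta > 0:
                pk = rng.dirichlet(p_anc * (1 - theta) / theta)
            else:
                pk = p_anc
            rows = labels == k
            geno[rows, l, :] = rng.choice(np.arange(1, A + 1), size=(n_per_group, 2), p=pk)
    if spatial_blocks:
        w = side_m / n_groups
        x = labels * w + rng.uniform(0, w, n)
        y = rng.uniform(0, side_m, n)
    else:
        x = rng.uniform(0, side_m, n)
        y = rng.uniform(0, side_m, n)
    g = GeoGenotypes(ids=[f"i{i}" for i in range(n)],
                     plot=np.array(["P1"] * n, dtype=object), x=x, y=y,
                     geno=geno, locus_names=[f"L{l + 1}" for l in range(L)])
    return g, labels


def sample_hierarchical_island(n_plots: int, clusters_per_plot: int,
                               n_per_cluster: int, f_plot_total: float,
                               f_clu_plot: float,
                               alleles_per_locus: list[int] | None = None,
                               rng: np.random.Generator | None = None
                               ) -> tuple[GeoGenotypes, np.ndarray, np.ndarray]:
    """Two-level Balding-Nichols hierarchy: plot frequencies differentiated
    from the ancestral pool at ``f_plot_total``, cluster frequencies from
    their plot at ``f_clu_plot``; Hardy-Weinberg within clusters.

    Returns (dataset, plot labels, cluster labels); cluster labels are
    globally unique and nested in plots.
    """
    rng = rng if rng is not None else np.random.default_rng()
    alleles_per_locus = alleles_per_locus or DEFAULT_ALLELE_COUNTS
    L = len(alleles_per_locus)
    n = n_plots * clusters_per_plot * n_per_cluster
    plot_lab = np.repeat(np.arange(n_plots), clusters_per_plot * n_per_cluster)
    clu_lab = np.repeat(np.arange(n_plots * clusters_per_plot), n_per_cluster)
    geno = np.zeros((n, L, 2), dtype=np.int64)
    for l, A in enumerate(alleles_per_locus):
        p_anc = rng.dirichlet(np.ones(A))
        for p in range(n_plots):
            pp = rng.dirichlet(p_anc * (1 - f_plot_total) / f_plot_total) \
                if f_plot_total > 0 else p_anc
            for c in range(clusters_per_plot):
                pc = rng.dirichlet(pp * (1 - f_clu_plot) / f_clu_plot) \
                    if f_clu_plot > 0 else pp
                rows = clu_lab == p * clusters_per_plot + c
                geno[rows, l, :] = rng.choice(np.arange(1, A + 1),
                                              size=(n_per_cluster, 2), p=pc)
    g = GeoGenotypes(ids=[f"i{i}" for i in range(n)],
                     plot=np.array([f"P{p}" for p in plot_lab], dtype=object),
                     x=rng.uniform(0, 100, n), y=rng.uniform(0, 100, n),
                     geno=geno, locus_names=[f"L{l + 1}" for l in range(L)])
    return g, plot_lab, clu_lab
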