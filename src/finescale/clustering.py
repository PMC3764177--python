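"""Bayesian assignment of individuals to within-plot genetic clusters.

A no-admixture finite-mixture Gibbs sampler: each cluster carries its own
per-locus allele frequencies with a symmetric Dirichlet(1) prior, mixing
weights have a Dirichlet prior, and individual labels are updated from
their multinomial full conditionals (genotype likelihood x prior).  Two
optional extensions match common field practice: a Potts interaction on a
k-nearest-neighbour graph for spatial smoothing, and a per-cluster,
per-locus null-allele frequency folded into the genotype likelihood
(apparent homozygote = true homozygote or null heterozygote; missing
genotype = null homozygote).

The number of clusters is selected by running an overfitted mixture at
``K_max`` with a sparse weight prior (Dirichlet alpha/K_max), under which
superfluous components empty out and the posterior number of *occupied*
clusters tracks the number of supported ones.  Each repetition reports the
median occupied count over its retained sweeps, and the highest median
across repetitions is chosen, with final labels taken from the repetition
and sweep that attain it at the best likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import GeoGenotypes

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)


@dataclass
class GibbsResult:
    """Posterior sample from one fixed-K run."""

    label_samples: np.ndarray  # (n_retained, n) int
    loglik: np.ndarray  # mixture log-likelihood per retained sweep
    occupied: np.ndarray  # occupied-cluster count per retained sweep
    K: int
    stationary: bool
    null_freq_samples: np.ndarray | None = None  # (n_retained, K, L)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..K per individual
    K: int
    rep_Ks: list[int]
    loglik: float
    settings: dict = field(default_factory=dict)


def _prepare(g: GeoGenotypes):
    """Per-locus allele index arrays: a1, a2 (n,) with -1 for missing."""
    alleles_per_locus = []
    a1 = np.empty((g.n_ind, g.n_loci), dtype=np.int64)
    a2 = np.empty((g.n_ind, g.n_loci), dtype=np.int64)
    for l in range(g.n_loci):
        vals = np.unique(g.geno[:, l, :])
        vals = vals[vals > 0]
        idx = {int(v): k for k, v in enumerate(vals)}
        alleles_per_locus.append(vals)
        for copy, arr in ((0, a1), (1, a2)):
            col = g.geno[:, l, copy]
            arr[:, l] = [idx.get(int(v), -1) for v in col]
    return alleles_per_locus, a1, a2


def genotype_loglik(a1: np.ndarray, a2: np.ndarray, log_freqs: list[np.ndarray],
                    null_freq: np.ndarray | None = None) -> np.ndarray:
    """(n, K) log-likelihood of every individual under every cluster.

    ``log_freqs[l]`` is (K, A_l) log allele frequencies.  Without a null
    model: Hardy-Weinberg genotype probabilities (2 p_a p_b for
    heterozygotes, p_a^2 for homozygotes), missing loci contribute 0.
    With ``null_freq`` (K, L): visible frequencies are rescaled by
    (1 - q), apparent homozygotes get p_a^2 + 2 p_a q, and missing
    genotypes q^2.
    """
    n, L = a1.shape
    K = log_freqs[0].shape[0]
    ll = np.zeros((n, K))
    for l in range(L):
        lf = log_freqs[l]
        typed = a1[:, l] >= 0
        i1 = np.where(typed, a1[:, l], 0)
        i2 = np.where(typed, a2[:, l], 0)
        if null_freq is None:
            contrib = lf[:, i1].T + lf[:, i2].T
            contrib[typed & (a1[:, l] != a2[:, l])] += _LOG2
            ll += np.where(typed[:, None], contrib, 0.0)
        else:
            q = null_freq[:, l]  # (K,)
            p = np.exp(lf) * (1.0 - q)[:, None]
            p1 = p[:, i1].T  # (n, K)
            p2 = p[:, i2].T
            hom = typed & (a1[:, l] == a2[:, l])
            het = typed & ~hom
            contrib = np.zeros((n, K))
            contrib[het] = np.log(2.0 * p1[het] * p2[het])
            contrib[hom] = np.log(p1[hom] ** 2 + 2.0 * p1[hom] * q[None, :].repeat(n, 0)[hom])
            miss = ~typed
            contrib[miss] = 2.0 * np.log(np.maximum(q, 1e-12))[None, :].repeat(n, 0)[miss]
            ll += contrib
    return ll


def _knn_graph(g: GeoGenotypes, k: int) -> list[np.ndarray]:
    D = squareform(pdist(g.coords()))
    np.fill_diagonal(D, np.inf)
    k = min(k, g.n_ind - 1)
    return [np.argsort(D[i])[:k] for i in range(g.n_ind)]


def _sample_freqs(a1, a2, labels, alleles_per_locus, K, rng):
    """Dirichlet(1 + cluster allele counts) draw of log frequencies."""
    log_freqs = []
    for l, vals in enumerate(alleles_per_locus):
        A = len(vals)
        counts = np.ones((K, A))
        typed = a1[:, l] >= 0
        for arr in (a1, a2):
            np.add.at(counts, (labels[typed], arr[typed, l]), 1.0)
        draw = rng.gamma(counts)
        draw /= draw.sum(axis=1, keepdims=True)
        log_freqs.append(np.log(np.maximum(draw, 1e-300)))
    return log_freqs


def gibbs_cluster(g: GeoGenotypes, K: int, n_sweeps: int | None = None,
                  thin: int = 2, burn_in: int | None = None,
                  alpha: float = 0.1, spatial: bool = False,
                  potts_beta: float = 0.6, k_neighbors: int = 10,
                  null_allele_model: bool = False,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> GibbsResult:
    """Posterior sampling of cluster labels at fixed K.

    Labels are updated sequentially from their full conditionals with the
    cluster allele frequencies integrated out (Dirichlet-multinomial
    posterior predictive), which mixes across cluster births and deaths and
    carries the marginal-likelihood penalty that empties superfluous
    components; per-sweep frequency draws from Dirichlet(1 + counts) feed
    the likelihood trace and the optional null-allele model.  ``alpha`` is
    the total Dirichlet mass on the mixing weights (alpha/K per component:
    small values give a sparse, overfitted-mixture prior).  The sweep
    budget auto-scales with dataset size when ``n_sweeps`` is None.  A
    coarse stationarity check compares label-entropy between the two
    halves of the retained trace and flags (never fails) non-mixing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n, L = g.n_ind, g.n_loci
    if n_sweeps is None:
        n_sweeps = max(150, min(600, 30000 // max(n, 1)))
    if burn_in is None:
        burn_in = n_sweeps // 2
    alleles_per_locus, a1, a2 = _prepare(g)
    A_l = np.array([len(v) for v in alleles_per_locus])
    labels = rng.integers(0, K, size=n)  # dispersed start; merging is the easy direction
    neigh = _knn_graph(g, k_neighbors) if spatial and K > 1 else None
    q = np.full((K, L), 0.05) if null_allele_model else None

    # per-locus cluster allele counts for the collapsed predictive
    counts = [np.ones((K, A)) for A in A_l]  # Dirichlet(1) prior as pseudo-counts
    tot = [np.full(K, float(A)) for A in A_l]
    sizes = np.zeros(K)
    for i in range(n):
        _add(i, labels[i], a1, a2, counts, tot, sizes, +1)

    retained_labels, logliks, occs, qs = [], [], [], []
    ak = alpha / K
    for sweep in range(n_sweeps):
        order = rng.permutation(n)
        gumb = rng.gumbel(size=(n, K))
        for i in order:
            _add(i, labels[i], a1, a2, counts, tot, sizes, -1)
            logp = np.log(ak + sizes)
            for l in range(L):
                x, y = a1[i, l], a2[i, l]
                if x < 0:
                    continue
                c, t = counts[l], tot[l]
                if x == y:
                    logp += np.log(c[:, x]) + np.log(c[:, x] + 1) \
                        - np.log(t) - np.log(t + 1)
                else:
                    logp += _LOG2 + np.log(c[:, x]) + np.log(c[:, y]) \
                        - np.log(t) - np.log(t + 1)
            if neigh is not None:
                logp += potts_beta * np.bincount(labels[neigh[i]], minlength=K)
            labels[i] = np.argmax(logp + gumb[i])
            _add(i, labels[i], a1, a2, counts, tot, sizes, +1)

        if q is not None or (sweep >= burn_in and (sweep - burn_in) % thin == 0):
            log_freqs = _sample_freqs(a1, a2, labels, alleles_per_locus, K, rng)
            wdraw = rng.gamma(ak + sizes)
            logw = np.log(np.maximum(wdraw / wdraw.sum(), 1e-300))
            ll = genotype_loglik(a1, a2, log_freqs, null_freq=q)
            if q is not None:
                q = _update_null(q, a1, a2, labels, log_freqs, ll, rng)
            if sweep >= burn_in and (sweep - burn_in) % thin == 0:
                mix = np.logaddexp.reduce(ll + logw, axis=1).sum()
                retained_labels.append(labels.copy())
                logliks.append(mix)
                occs.append(len(np.unique(labels)))
                if q is not None:
                    qs.append(q.copy())

    lab = np.array(retained_labels)
    occ = np.array(occs)
    llk = np.array(logliks)
    half = len(llk) // 2
    stationary = True
    if half >= 5:
        ent = [_label_entropy(lab[:half]), _label_entropy(lab[half:])]
        stationary = abs(ent[0] - ent[1]) < 0.5
        if not stationary:
            logger.warning("gibbs_cluster: label-entropy drift %.2f vs %.2f "
                           "(possible non-mixing)", ent[0], ent[1])
    return GibbsResult(label_samples=lab, loglik=llk, occupied=occ, K=K,
                       stationary=stationary,
                       null_freq_samples=np.array(qs) if qs else None)


def _add(i: int, k: int, a1, a2, counts, tot, sizes, delta: int) -> None:
    """Move individual i in or out of cluster k's sufficient statistics."""
    sizes[k] += delta
    for l in range(len(counts)):
        x, y = a1[i, l], a2[i, l]
        if x < 0:
            continue
        counts[l][k, x] += delta
        counts[l][k, y] += delta
        tot[l][k] += 2 * delta


def _label_entropy(lab: np.ndarray) -> float:
    _, counts = np.unique(lab, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _update_null(q, a1, a2, labels, log_freqs, ll_current, rng):
    """Metropolis update of the per-cluster, per-locus null frequency."""
    K, L = q.shape
    prop = np.clip(q + rng.normal(0, 0.03, size=q.shape), 1e-4, 0.95)
    for l in range(L):
        for k in range(K):
            rows = labels == k
            if not rows.any():
                q[k, l] = prop[k, l]  # prior is uniform; free move
                continue
            cur = _null_locus_ll(a1[rows, l], a2[rows, l], log_freqs[l][k], q[k, l])
            new = _null_locus_ll(a1[rows, l], a2[rows, l], log_freqs[l][k], prop[k, l])
            if np.log(rng.random()) < new - cur:
                q[k, l] = prop[k, l]
    return q


def _null_locus_ll(i1, i2, lf, qv) -> float:
    p = np.exp(lf) * (1 - qv)
    typed = i1 >= 0
    j1 = np.where(typed, i1, 0)
    j2 = np.where(typed, i2, 0)
    hom = typed & (i1 == i2)
    het = typed & ~hom
    out = 0.0
    out += np.log(2 * p[j1[het]] * p[j2[het]]).sum()
    out += np.log(p[j1[hom]] ** 2 + 2 * p[j1[hom]] * qv).sum()
    out += 2 * np.log(max(qv, 1e-12)) * int((~typed).sum())
    return float(out)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

def select_k(g: GeoGenotypes, K_max: int = 20, reps: int = 10,
             seed: int | None = None, spatial: bool = False,
             null_allele_model: bool = False, alpha: float = 0.1,
             n_sweeps: int | None = None, thin: int = 2) -> ClusterAssignment:
    """Repetition-based choice of the number of clusters.

    Each repetition runs the overfitted sampler at ``K_max`` and reports
    the median occupied-cluster count over its retained sweeps; the chosen
    K is the highest of these medians.  Final labels come from the
    repetition attaining the chosen K, at the retained sweep with that
    occupancy and the best likelihood, relabelled to 1..K.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    rep_Ks: list[int] = []
    results: list[GibbsResult] = []
    for r in range(reps):
        res = gibbs_cluster(g, K=K_max, alpha=alpha, spatial=spatial,
                            null_allele_model=null_allele_model,
                            n_sweeps=n_sweeps, thin=thin,
                            rng=np.random.default_rng(children[r]))
        rep_Ks.append(int(np.ceil(np.median(res.occupied))))
        results.append(res)
    chosen = max(rep_Ks)
    best_rep, best_sweep, best_ll = None, None, -np.inf
    for r, res in enumerate(results):
        if rep_Ks[r] != chosen:
            continue
        cand = np.flatnonzero(res.occupied == chosen)
        if cand.size == 0:
            cand = np.flatnonzero(res.occupied == res.occupied.max())
        i = cand[np.argmax(res.loglik[cand])]
        if res.loglik[i] > best_ll:
            best_rep, best_sweep, best_ll = r, i, float(res.loglik[i])
    raw = results[best_rep].label_samples[best_sweep]
    labels = _relabel(raw)
    K = int(labels.max())
    return ClusterAssignment(labels=labels, K=K, rep_Ks=rep_Ks, loglik=best_ll,
                             settings={"K_max": K_max, "reps": reps,
                                       "spatial": spatial, "alpha": alpha,
                                       "null_allele_model": null_allele_model,
                                       "seed": seed})


def _relabel(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary label values to consecutive 1..K (order of appearance)."""
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def coassignment_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pairs whose co-assignment (same/different cluster)
    matches the truth; label-permutation invariant."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same_hat = labels[iu[0]] == labels[iu[1]]
    same_true = truth[iu[0]] == truth[iu[1]]
    return float((same_hat == same_true).mean())
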