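"""Spatial genetic structure: correlograms, the Sp statistic, and
between-plot correlogram heterogeneity tests.

The workflow mirrors the classical SSR analysis of forest stands: pairwise
relatedness is binned into distance classes (20 m even-width classes, or
seven even-count classes), significance is assessed by permuting individual
locations (1000 shuffles) and by bootstrapping pairwise comparisons within
classes, and the intensity of structure is summarized by

    Sp = -b_F / (1 - F_1)

with ``F_1`` the mean kinship in the first (0-20 m) class and ``b_F`` the
regression slope of kinship on (log-)distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import AlleleFrequencies, GeoGenotypes, allele_frequencies
from .relatedness import double_centre, loiselle_kinship, smouse_peakall_d2

logger = logging.getLogger(__name__)

ESTIMATORS = ("smouse_peakall_r", "loiselle_F")


@dataclass
class DistanceClassSpec:
    """Distance-class definition.

    ``even_width`` partitions (0, max] into classes of ``width_m`` metres
    (first class closed at 0); ``even_count`` splits all pairs into
    ``n_classes`` classes of near-equal pair counts by distance rank, ties
    broken by stable pair order.
    """

    mode: str = "even_width"
    width_m: float = 20.0
    n_classes: int = 7

    def __post_init__(self) -> None:
        if self.mode not in ("even_width", "even_count"):
            raise ValueError(f"unknown distance-class mode {self.mode!r}")
        if self.width_m <= 0 or self.n_classes < 1:
            raise ValueError("width_m must be > 0 and n_classes >= 1")


def build_classes(distances: np.ndarray, spec: DistanceClassSpec) -> tuple[np.ndarray, np.ndarray]:
    """Assign every pair distance to a class.

    Returns ``(classes, edges)``: integer class per pair and the class
    edges (length n_classes + 1, edges[0] = 0).  Intervals are left-open /
    right-closed except the first, which includes 0.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    if spec.mode == "even_width":
        w = spec.width_m
        k = max(1, int(np.ceil(d.max() / w))) if d.max() > 0 else 1
        edges = np.arange(k + 1) * w
        classes = np.searchsorted(edges[1:], d, side="left")
        classes = np.minimum(classes, k - 1)
    else:
        k = min(spec.n_classes, d.size)
        order = np.argsort(d, kind="stable")
        sizes = np.full(k, d.size // k)
        sizes[: d.size % k] += 1
        classes = np.empty(d.size, dtype=np.int64)
        edges = np.zeros(k + 1)
        start = 0
        for j, s in enumerate(sizes):
            chunk = order[start : start + s]
            classes[chunk] = j
            edges[j + 1] = d[chunk].max()
            start += s
        edges[-1] = max(edges[-1], d.max())
    if np.bincount(classes, minlength=len(edges) - 1).min() == 0:
        logger.warning("empty distance class(es) in spec %s", spec)
    return classes, edges


@dataclass
class Correlogram:
    edges: np.ndarray
    mean_dist: np.ndarray
    n_pairs: np.ndarray
    estimate: np.ndarray
    perm_lo: np.ndarray
    perm_hi: np.ndarray
    perm_median: np.ndarray
    boot_lo: np.ndarray
    boot_hi: np.ndarray
    estimator: str
    n_perm: int
    n_boot: int

    @property
    def n_classes(self) -> int:
        return len(self.n_pairs)


@dataclass
class SGSSummary:
    """Sp-statistic summary of one plot (F_1, b_F and Sp with their SEs
    and permutation p-values)."""

    F1: float
    bF: float
    Sp: float
    F1_se: float
    bF_se: float
    Sp_se: float
    p_F1: float
    p_bF: float
    n_pairs_first: int
    n_zero_dist: int
    log_distance: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class HeterogeneityResult:
    t2: np.ndarray
    p_class: np.ndarray
    omega: float
    p_omega: float
    n_resamples: int
    classes_used: np.ndarray
    edges: np.ndarray


def sp_value(F1: float, bF: float) -> float:
    """The Sp statistic, Sp = -b_F / (1 - F_1)."""
    if F1 == 1.0:
        return np.nan
    return -bF / (1.0 - F1)


# ---------------------------------------------------------------------------
# class-level estimates
# ---------------------------------------------------------------------------

def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _class_r(c: np.ndarray, pi: np.ndarray, pj: np.ndarray,
             classes: np.ndarray, k: int) -> np.ndarray:
    """Smouse-Peakall autocorrelation r per class: the class sum of
    off-diagonal covariances over the summed self-covariances of the
    individuals involved in the class's pairs."""
    numer = np.bincount(classes, weights=c[pi, pj], minlength=k)
    n = c.shape[0]
    cnt = np.zeros((k, n))
    np.add.at(cnt, (classes, pi), 1.0)
    np.add.at(cnt, (classes, pj), 1.0)
    denom = (cnt > 0) @ np.diag(c).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = numer / denom
    r[np.bincount(classes, minlength=k) == 0] = np.nan
    return r


def _class_mean(values: np.ndarray, valid: np.ndarray,
                classes: np.ndarray, k: int) -> np.ndarray:
    w = np.where(valid, values, 0.0)
    s = np.bincount(classes, weights=w, minlength=k)
    m = np.bincount(classes, weights=valid.astype(float), minlength=k)
    with np.errstate(invalid="ignore"):
        return np.where(m > 0, s / np.where(m == 0, 1, m), np.nan)


def _estimates(estimator: str, classes: np.ndarray, k: int, *, c=None,
               pi=None, pj=None, fvals=None, fvalid=None) -> np.ndarray:
    if estimator == "smouse_peakall_r":
        return _class_r(c, pi, pj, classes, k)
    return _class_mean(fvals, fvalid, classes, k)


def correlogram(g: GeoGenotypes, estimator: str = "smouse_peakall_r",
                spec: DistanceClassSpec | None = None, n_perm: int = 1000,
                n_boot: int = 1000, seed: int | None = None,
                ref: AlleleFrequencies | None = None) -> Correlogram:
    """Distance-class correlogram with permutation envelope and bootstrap CI.

    The permutation null shuffles individual locations while keeping
    genotypes fixed (so the multiset of pairwise relatedness values is
    unchanged); the bootstrap resamples pairwise comparisons within each
    class.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    spec = spec or DistanceClassSpec()
    rng = np.random.default_rng(seed)
    n = g.n_ind
    D = squareform(pdist(g.coords()))
    pi, pj = _pair_indices(n)
    dists = D[pi, pj]
    classes, edges = build_classes(dists, spec)
    k = len(edges) - 1

    kw: dict = {}
    if estimator == "smouse_peakall_r":
        d2, _ = smouse_peakall_d2(g)
        kw["c"] = double_centre(d2)
        kw["pi"], kw["pj"] = pi, pj
        pair_vals = kw["c"][pi, pj]
        pair_valid = np.ones_like(pair_vals, dtype=bool)
    else:
        pm = loiselle_kinship(g, ref=ref)
        pair_vals, pair_valid = pm.condensed()
        kw["fvals"], kw["fvalid"] = pair_vals, pair_valid

    est = _estimates(estimator, classes, k, **kw)
    n_pairs = np.bincount(classes, minlength=k)
    mean_dist = _class_mean(dists, np.ones_like(dists, dtype=bool), classes, k)

    # permutation envelope: relabel locations, re-bin the same genetic values
    perm_est = np.empty((n_perm, k))
    for p in range(n_perm):
        perm = rng.permutation(n)
        dp = D[perm[pi], perm[pj]]
        cl_p, _ = build_classes(dp, spec) if spec.mode == "even_count" else (
            np.minimum(np.searchsorted(edges[1:], dp, side="left"), k - 1), edges)
        perm_est[p] = _estimates(estimator, cl_p, k, **kw)
    if n_perm:
        perm_lo = np.nanpercentile(perm_est, 2.5, axis=0)
        perm_hi = np.nanpercentile(perm_est, 97.5, axis=0)
        perm_med = np.nanmedian(perm_est, axis=0)
    else:
        perm_lo = perm_hi = perm_med = np.full(k, np.nan)

    # bootstrap CI over pairwise comparisons within class
    boot_lo = np.full(k, np.nan)
    boot_hi = np.full(k, np.nan)
    for j in range(k):
        sel = np.flatnonzero((classes == j) & pair_valid)
        if sel.size == 0 or n_boot == 0:
            continue
        vals = pair_vals[sel]
        draws = rng.integers(0, sel.size, size=(n_boot, sel.size))
        means = vals[draws].mean(axis=1)
        if estimator == "smouse_peakall_r":
            # resample the numerator; normalization held at its observed value
            scale = est[j] / vals.mean() if vals.mean() != 0 else np.nan
            means = means * scale
        boot_lo[j] = np.percentile(means, 2.5)
        boot_hi[j] = np.percentile(means, 97.5)

    return Correlogram(edges=edges, mean_dist=mean_dist, n_pairs=n_pairs,
                       estimate=est, perm_lo=perm_lo, perm_hi=perm_hi,
                       perm_median=perm_med, boot_lo=boot_lo, boot_hi=boot_hi,
                       estimator=estimator, n_perm=n_perm, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Sp statistic
# ---------------------------------------------------------------------------

def _f1_bf(fv: np.ndarray, valid: np.ndarray, dists: np.ndarray,
           first: float, log_distance: bool) -> tuple[float, float]:
    in_first = valid & (dists <= first)
    F1 = fv[in_first].mean() if in_first.any() else np.nan
    pos = valid & (dists > 0)
    xs = np.log(dists[pos]) if log_distance else dists[pos]
    ys = fv[pos]
    xm, ym = xs.mean(), ys.mean()
    denom = ((xs - xm) ** 2).sum()
    bF = ((xs - xm) * (ys - ym)).sum() / denom if denom > 0 else np.nan
    return float(F1), float(bF)


def sp_statistic(g: GeoGenotypes, spec: DistanceClassSpec | None = None,
                 n_perm: int = 1000, seed: int | None = None,
                 log_distance: bool = True,
                 ref: AlleleFrequencies | None = None) -> SGSSummary:
    """F_1, b_F and Sp with locus-jackknife SEs and permutation p-values.

    ``F_1`` is the mean Loiselle kinship over pairs in the first distance
    class (0 to ``spec.width_m``, default 20 m); ``b_F`` the least-squares
    slope of pairwise kinship on ln(distance) (``log_distance=False``
    switches to linear distance).  Zero-distance pairs are excluded from
    the regression.  One-sided permutation tests shuffle individual
    locations: F_1 against 'greater', b_F against 'less'.
    """
    spec = spec or DistanceClassSpec()
    if g.n_ind < 3:
        raise ValueError("need at least three individuals")
    rng = np.random.default_rng(seed)
    n = g.n_ind
    D = squareform(pdist(g.coords()))
    pi, pj = _pair_indices(n)
    dists = D[pi, pj]
    first = spec.width_m if spec.mode == "even_width" else None
    if first is None:
        _, edges = build_classes(dists, spec)
        first = edges[1]

    if ref is None:
        ref = allele_frequencies(g)
    # per-locus numerator/denominator pieces for the jackknife
    num_l = np.zeros((g.n_loci, len(pi)))
    den_l = np.zeros((g.n_loci, len(pi)))
    for l in range(g.n_loci):
        sub = GeoGenotypes(ids=g.ids, plot=g.plot, x=g.x, y=g.y,
                           geno=g.geno[:, [l], :], locus_names=[g.locus_names[l]])
        ref_l = AlleleFrequencies([ref.locus_names[l]], [ref.freqs[l]],
                                  ref.n_copies[[l]], ref.n_typed[[l]],
                                  [e for e in ref.empty_loci if e == ref.locus_names[l]])
        pm = loiselle_kinship(sub, ref=ref_l)
        v, ok = pm.condensed()
        den1 = sum(p * (1 - p) for p in ref.freqs[l].values())
        num_l[l] = np.where(ok, v * den1, 0.0)
        den_l[l] = np.where(ok, den1, 0.0)
    num, den = num_l.sum(axis=0), den_l.sum(axis=0)
    valid = den > 0
    fv = np.divide(num, den, out=np.zeros_like(num), where=valid)

    n_zero = int((valid & (dists == 0)).sum())
    if n_zero:
        logger.info("excluding %d zero-distance pair(s) from the slope regression", n_zero)
    F1, bF = _f1_bf(fv, valid, dists, first, log_distance)
    flags = []
    if F1 == 1.0:
        flags.append("F1 == 1: Sp undefined")
    Sp = sp_value(F1, bF)

    # delete-one-locus jackknife
    L = g.n_loci
    if L > 1:
        jF1, jbF, jSp = np.empty(L), np.empty(L), np.empty(L)
        for l in range(L):
            nl, dl = num - num_l[l], den - den_l[l]
            okl = dl > 0
            fl = np.divide(nl, dl, out=np.zeros_like(nl), where=okl)
            jF1[l], jbF[l] = _f1_bf(fl, okl, dists, first, log_distance)
            jSp[l] = sp_value(jF1[l], jbF[l])

        def jse(v: np.ndarray) -> float:
            return float(np.sqrt((L - 1) / L * ((v - v.mean()) ** 2).sum()))

        F1_se, bF_se, Sp_se = jse(jF1), jse(jbF), jse(jSp)
    else:
        F1_se = bF_se = Sp_se = np.nan

    # permutation tests (one-sided)
    if n_perm:
        ge = le = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dp = D[perm[pi], perm[pj]]
            pF1, pbF = _f1_bf(fv, valid, dp, first, log_distance)
            ge += pF1 >= F1
            le += pbF <= bF
        p_F1 = (1 + ge) / (n_perm + 1)
        p_bF = (1 + le) / (n_perm + 1)
    else:
        p_F1 = p_bF = np.nan

    return SGSSummary(F1=F1, bF=bF, Sp=Sp, F1_se=F1_se, bF_se=bF_se,
                      Sp_se=Sp_se, p_F1=p_F1, p_bF=p_bF,
                      n_pairs_first=int((valid & (dists <= first)).sum()),
                      n_zero_dist=n_zero, log_distance=log_distance, flags=flags)


# ---------------------------------------------------------------------------
# correlogram heterogeneity between two plots
# ---------------------------------------------------------------------------

def heterogeneity_test(gA: GeoGenotypes, gB: GeoGenotypes,
                       spec: DistanceClassSpec | None = None,
                       estimator: str = "smouse_peakall_r",
                       n_resample: int = 9999, n_boot: int = 1000,
                       seed: int | None = None) -> HeterogeneityResult:
    """Nonparametric heterogeneity test between two plot correlograms.

    Per class k, ``t2_k = (r_Ak - r_Bk)^2 / (v_Ak + v_Bk)`` with variances
    from within-class pair bootstraps; the overall statistic is
    ``omega = sum_k t2_k``.  The null pools the genotypes of the two plots
    and redistributes them at random over the fixed location slots of each
    plot (a re-split at the original sizes), recomputing class estimates
    each resample.  Classes empty in either plot are skipped.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if gA.locus_names != gB.locus_names:
        raise ValueError("the two plots must share the same loci")
    spec = spec or DistanceClassSpec()
    rng = np.random.default_rng(seed)
    nA, nB = gA.n_ind, gB.n_ind

    pooled = GeoGenotypes(
        ids=[f"A:{i}" for i in gA.ids] + [f"B:{i}" for i in gB.ids],
        plot=np.concatenate([gA.plot, gB.plot]),
        x=np.concatenate([gA.x, gB.x]), y=np.concatenate([gA.y, gB.y]),
        geno=np.concatenate([gA.geno, gB.geno], axis=0),
        locus_names=list(gA.locus_names),
    )

    # fixed location scaffolds and shared class edges
    piA, pjA = _pair_indices(nA)
    piB, pjB = _pair_indices(nB)
    dA = squareform(pdist(gA.coords()))[piA, pjA]
    dB = squareform(pdist(gB.coords()))[piB, pjB]
    if spec.mode == "even_width":
        _, edges = build_classes(np.concatenate([dA, dB]), spec)
    else:
        _, edges = build_classes(np.concatenate([dA, dB]), spec)
    k = len(edges) - 1
    clA = np.minimum(np.searchsorted(edges[1:], dA, side="left"), k - 1)
    clB = np.minimum(np.searchsorted(edges[1:], dB, side="left"), k - 1)

    if estimator == "smouse_peakall_r":
        d2_pool, _ = smouse_peakall_d2(pooled)
        fv_pool = None
    else:
        d2_pool = None
        pm = loiselle_kinship(pooled)

    def group_estimates(idxA: np.ndarray, idxB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for idx, (ppi, ppj), cl in ((idxA, (piA, pjA), clA), (idxB, (piB, pjB), clB)):
            if estimator == "smouse_peakall_r":
                c = double_centre(d2_pool[np.ix_(idx, idx)])
                out.append(_class_r(c, ppi, ppj, cl, k))
            else:
                sub = pooled.subset(idx)
                pmx = loiselle_kinship(sub)
                v, ok = pmx.condensed()
                out.append(_class_mean(v, ok, cl, k))
        return out[0], out[1]

    idA0 = np.arange(nA)
    idB0 = np.arange(nA, nA + nB)
    rA, rB = group_estimates(idA0, idB0)

    # bootstrap variances of the class estimates (pair resampling)
    def boot_var(idx, ppi, ppj, cl) -> np.ndarray:
        if estimator == "smouse_peakall_r":
            c = double_centre(d2_pool[np.ix_(idx, idx)])
            vals = c[ppi, ppj]
            base = _class_r(c, ppi, ppj, cl, k)
        else:
            v, ok = loiselle_kinship(pooled.subset(idx)).condensed()
            vals = np.where(ok, v, np.nan)
            base = None
        out = np.full(k, np.nan)
        for j in range(k):
            sel = np.flatnonzero((cl == j) & np.isfinite(vals))
            if sel.size < 2 or n_boot == 0:
                continue
            draws = rng.integers(0, sel.size, size=(n_boot, sel.size))
            means = vals[sel][draws].mean(axis=1)
            if estimator == "smouse_peakall_r":
                mu = vals[sel].mean()
                means = means * (base[j] / mu if mu != 0 else np.nan)
            out[j] = means.var(ddof=1)
        return out

    vA = boot_var(idA0, piA, pjA, clA)
    vB = boot_var(idB0, piB, pjB, clB)

    used = np.isfinite(rA) & np.isfinite(rB) & np.isfinite(vA) & np.isfinite(vB) \
        & ((vA + vB) > 0)
    if not used.all():
        logger.info("heterogeneity test: %d class(es) skipped", int((~used).sum()))
    t2 = np.full(k, np.nan)
    t2[used] = (rA[used] - rB[used]) ** 2 / (vA[used] + vB[used])
    omega = float(np.nansum(t2[used]))

    ge_class = np.zeros(k)
    ge_omega = 0
    for _ in range(n_resample):
        perm = rng.permutation(nA + nB)
        pA, pB = group_estimates(perm[:nA], perm[nA:])
        t2n = np.full(k, np.nan)
        t2n[used] = (pA[used] - pB[used]) ** 2 / (vA[used] + vB[used])
        ge_class[used] += t2n[used] >= t2[used]
        ge_omega += np.nansum(t2n[used]) >= omega
    p_class = np.full(k, np.nan)
    if n_resample:
        p_class[used] = (1 + ge_class[used]) / (n_resample + 1)
        p_omega = (1 + ge_omega) / (n_resample + 1)
    else:
        p_omega = np.nan

    return HeterogeneityResult(t2=t2, p_class=p_class, omega=omega,
                               p_omega=float(p_omega), n_resamples=n_resample,
                               classes_used=used, edges=edges)
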