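"""Weir-Cockerham F-statistics: two-level theta among clusters, an EM
null-allele frequency estimator with the ENA-corrected theta, and
hierarchical fixation indices from a nested analysis of variance of
allele frequencies.

Pooling across alleles and loci is always ratio-of-sums on variance
components (the Weir & Cockerham 1984 convention, as in Fstat/hierfstat);
negative components are retained, not truncated.  The hierarchical indices
(Total > Plot > Cluster > Individual > gene copy) satisfy

    (1 - F_IndTotal) = (1 - F_IndClu) (1 - F_CluPlot) (1 - F_PlotTotal)

exactly on the pooled components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GeoGenotypes

logger = logging.getLogger(__name__)


@dataclass
class ThetaResult:
    theta: float
    theta_per_locus: np.ndarray
    p_value: float | None = None
    theta_ena: float | None = None
    theta_ena_per_locus: np.ndarray | None = None
    null_freq: np.ndarray | None = None  # (n_groups, L)
    n_perm: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class HierFResult:
    f_plot_total: float
    f_clu_plot: float
    f_ind_clu: float
    f_ind_total: float
    p_plot_total: float | None
    p_clu_plot: float | None
    p_ind_clu: float | None
    components: np.ndarray  # pooled (plot, cluster, individual, error)
    components_per_locus: np.ndarray  # (L, 4)
    n_perm: int = 0
    flags: list[str] = field(default_factory=list)


def _group_index(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv, list(uniq)


# ---------------------------------------------------------------------------
# two-level Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _locus_tables(g: GeoGenotypes, inv: np.ndarray, n_groups: int, l: int):
    """Allele counts (r, A), heterozygote-carrier counts (r, A) and typed
    sample sizes (r,) for locus l; A indexes the sorted distinct alleles."""
    typed = ~g.missing[:, l]
    a1 = g.geno[:, l, 0]
    a2 = g.geno[:, l, 1]
    alleles = np.unique(np.concatenate([a1[typed], a2[typed]]))
    A = alleles.size
    aidx = {int(a): i for i, a in enumerate(alleles)}
    counts = np.zeros((n_groups, A))
    hets = np.zeros((n_groups, A))
    n_i = np.zeros(n_groups)
    for i in np.flatnonzero(typed):
        gi = inv[i]
        k1, k2 = aidx[int(a1[i])], aidx[int(a2[i])]
        counts[gi, k1] += 1
        counts[gi, k2] += 1
        n_i[gi] += 1
        if k1 != k2:
            hets[gi, k1] += 1
            hets[gi, k2] += 1
    return counts, hets, n_i, alleles


def wc84_components(p: np.ndarray, h: np.ndarray, n: np.ndarray):
    """Per-allele Weir-Cockerham (1984) variance components (a, b, c).

    ``p`` (r, A) allele frequencies per group, ``h`` (r, A) frequencies of
    heterozygotes carrying the allele, ``n`` (r,) sample sizes in
    individuals.  Groups with n == 0 are ignored; with fewer than two
    usable groups all components are zero.
    """
    use = n > 0
    if use.sum() < 2:
        return np.zeros(p.shape[1]), np.zeros(p.shape[1]), np.zeros(p.shape[1])
    p, h, n = p[use], h[use], n[use]
    r = len(n)
    nbar = n.mean()
    nsum = n.sum()
    nc = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    pbar = (n[:, None] * p).sum(0) / nsum
    s2 = (n[:, None] * (p - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(0) / nsum
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _theta_sums(g: GeoGenotypes, inv: np.ndarray, n_groups: int):
    num = np.zeros(g.n_loci)
    den = np.zeros(g.n_loci)
    for l in range(g.n_loci):
        counts, hets, n_i, _ = _locus_tables(g, inv, n_groups, l)
        if (n_i > 0).sum() < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_i[:, None] > 0, counts / np.maximum(2 * n_i[:, None], 1), 0.0)
            h = np.where(n_i[:, None] > 0, hets / np.maximum(n_i[:, None], 1), 0.0)
        a, b, c = wc84_components(p, h, n_i)
        num[l] = a.sum()
        den[l] = (a + b + c).sum()
    return num, den


def wc_theta(g: GeoGenotypes, labels, n_perm: int = 1000,
             seed: int | None = None) -> ThetaResult:
    """Multilocus Weir-Cockerham theta among groups, ratio-of-sums pooled.

    Significance by randomizing genotypes among groups (group sizes kept),
    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    inv, uniq = _group_index(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two non-empty groups")
    num, den = _theta_sums(g, inv, len(uniq))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(den != 0, num / np.where(den == 0, 1, den), np.nan)
    theta = float(num.sum() / den.sum()) if den.sum() != 0 else np.nan

    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            nump, denp = _theta_sums(g, rng.permutation(inv), len(uniq))
            tp = nump.sum() / denp.sum() if denp.sum() != 0 else np.nan
            ge += tp >= theta
        p_value = (1 + ge) / (n_perm + 1)
    return ThetaResult(theta=theta, theta_per_locus=per_locus,
                       p_value=p_value, n_perm=n_perm)


# ---------------------------------------------------------------------------
# EM null-allele estimation and the ENA-corrected theta
# ---------------------------------------------------------------------------

@dataclass
class NullFreqResult:
    q: np.ndarray  # (n_groups, L)
    visible_freqs: list[list[dict[int, float]]]  # [group][locus] allele -> freq
    groups: list
    flags: list[str] = field(default_factory=list)


def _em_one(a1, a2, typed, max_iter: int = 1000, tol: float = 1e-8):
    """EM for the null-allele frequency at one locus in one group.

    Apparent homozygotes may be visible/null heterozygotes; missing
    genotypes are treated as null homozygotes.  Returns (q, freq dict,
    converged).
    """
    n_missing = int((~typed).sum())
    av1, av2 = a1[typed], a2[typed]
    alleles = np.unique(np.concatenate([av1, av2]))
    aidx = {int(a): i for i, a in enumerate(alleles)}
    A = alleles.size
    het_counts = np.zeros(A)
    hom_counts = np.zeros(A)
    for x, y in zip(av1, av2):
        if x == y:
            hom_counts[aidx[int(x)]] += 1
        else:
            het_counts[aidx[int(x)]] += 1
            het_counts[aidx[int(y)]] += 1
    n_tot = len(av1) + n_missing
    if n_tot == 0:
        return np.nan, {}, False
    copies = 2.0 * n_tot
    q = max(n_missing / n_tot, 0.01)
    p = np.full(A, (1 - q) / A) if A else np.array([])
    obs_p = (het_counts + 2 * hom_counts) / max(2 * len(av1), 1)
    p = obs_p * (1 - q) if A else p
    converged = False
    for _ in range(max_iter):
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(p + 2 * q > 0, 2 * q / (p + 2 * q), 0.0)  # null-carrier prob per apparent hom
        allele_copies = het_counts + hom_counts * (2 - w)
        null_copies = (hom_counts * w).sum() + 2 * n_missing
        q_new = null_copies / copies
        p_new = allele_copies / copies
        delta = abs(q_new - q) + np.abs(p_new - p).max(initial=0.0)
        q, p = q_new, p_new
        if delta < tol:
            converged = True
            break
    return float(q), {int(a): float(p[i]) for i, a in enumerate(alleles)}, converged


def em_null_freq(g: GeoGenotypes, labels, min_typed: int = 5) -> NullFreqResult:
    """Per locus x group null-allele frequency by EM (FreeNA-style contract).

    Groups with fewer than ``min_typed`` typed individuals at a locus are
    flagged; an all-missing locus x group is flagged and left NaN.
    """
    inv, uniq = _group_index(labels)
    G, L = len(uniq), g.n_loci
    q = np.full((G, L), np.nan)
    vis: list[list[dict[int, float]]] = [[{} for _ in range(L)] for _ in range(G)]
    flags: list[str] = []
    for gi in range(G):
        rows = inv == gi
        for l in range(L):
            typed = ~g.missing[rows, l]
            if typed.sum() == 0:
                flags.append(f"group {uniq[gi]} locus {g.locus_names[l]}: all missing")
                continue
            if typed.sum() < min_typed:
                flags.append(f"group {uniq[gi]} locus {g.locus_names[l]}: "
                             f"only {int(typed.sum())} typed individuals")
            qv, pv, ok = _em_one(g.geno[rows, l, 0], g.geno[rows, l, 1], typed)
            if not ok:
                flags.append(f"group {uniq[gi]} locus {g.locus_names[l]}: EM not converged")
            q[gi, l] = qv
            vis[gi][l] = pv
    return NullFreqResult(q=q, visible_freqs=vis, groups=uniq, flags=flags)


def theta_ena(g: GeoGenotypes, labels, n_perm: int = 0,
              seed: int | None = None) -> ThetaResult:
    """Theta with the ENA null-allele correction.

    The estimated null is treated as an additional allele: per group and
    locus, visible-allele frequencies come from the EM (summing to 1 - q)
    and the component sums run over visible alleles only.  With q = 0 the
    result equals :func:`wc_theta` exactly.
    """
    inv, uniq = _group_index(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two non-empty groups")
    base = wc_theta(g, labels, n_perm=n_perm, seed=seed)
    nulls = em_null_freq(g, labels)
    flags = list(nulls.flags)
    for gi in range(len(uniq)):
        for l in range(g.n_loci):
            if np.isfinite(nulls.q[gi, l]) and nulls.q[gi, l] >= 0.5:
                flags.append(f"group {uniq[gi]} locus {g.locus_names[l]}: "
                             f"null frequency {nulls.q[gi, l]:.2f} >= 0.5, unreliable")
    num = np.zeros(g.n_loci)
    den = np.zeros(g.n_loci)
    for l in range(g.n_loci):
        typed = ~g.missing[:, l]
        alleles = np.unique(g.geno[typed, l, :])
        alleles = alleles[alleles > 0]
        if alleles.size == 0:
            continue
        A = alleles.size
        aidx = {int(a): i for i, a in enumerate(alleles)}
        G = len(uniq)
        p = np.zeros((G, A))
        h = np.zeros((G, A))
        n_i = np.zeros(G)
        for gi in range(G):
            rows = np.flatnonzero(inv == gi)
            t = typed[rows]
            qv = nulls.q[gi, l] if np.isfinite(nulls.q[gi, l]) else 0.0
            qv = min(qv, 0.999)
            # EM frequencies (on the 1 - q scale) renormalized over the
            # visible alleles: theta is estimated on the visible-allele
            # frequency distribution, the null excluded from all sums
            for a, f in nulls.visible_freqs[gi][l].items():
                if a in aidx:
                    p[gi, aidx[a]] = f / (1.0 - qv) if qv < 1 else 0.0
            het_counts = np.zeros(A)
            hom_counts = np.zeros(A)
            for i in rows[t]:
                x, y = int(g.geno[i, l, 0]), int(g.geno[i, l, 1])
                if x != y:
                    het_counts[aidx[x]] += 1
                    het_counts[aidx[y]] += 1
                else:
                    hom_counts[aidx[x]] += 1
            # remove EM-inferred visible/null heterozygotes (apparent
            # homozygotes) from the visible-visible sample
            pv = np.array([nulls.visible_freqs[gi][l].get(int(a), 0.0)
                           for a in alleles])
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(pv + 2 * qv > 0, 2 * qv / (pv + 2 * qv), 0.0)
            n_vv = t.sum() - (hom_counts * w).sum()
            n_i[gi] = max(n_vv, 0.0)
            if n_vv > 0:
                h[gi] = het_counts / n_vv
        n_i_col = n_i[:, None]
        h = np.where(n_i_col > 0, h, 0.0)
        a_c, b_c, c_c = wc84_components(p, h, n_i)
        num[l] = a_c.sum()
        den[l] = (a_c + b_c + c_c).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(den != 0, num / np.where(den == 0, 1, den), np.nan)
    t_ena = float(num.sum() / den.sum()) if den.sum() != 0 else np.nan
    return ThetaResult(theta=base.theta, theta_per_locus=base.theta_per_locus,
                       p_value=base.p_value, theta_ena=t_ena,
                       theta_ena_per_locus=per_locus, null_freq=nulls.q,
                       n_perm=n_perm, flags=flags)


# ---------------------------------------------------------------------------
# hierarchical F-statistics (nested ANOVA of allele frequencies)
# ---------------------------------------------------------------------------

def _c_coef(n_units: np.ndarray, parent_sizes: np.ndarray) -> float:
    """C(G, eff) = sum_u n_u^2 / n_{G(u)} for eff units nested in G."""
    return float((n_units.astype(float) ** 2 / parent_sizes).sum())


def nested_components(allele_idx: np.ndarray, A: int,
                      levels: list[np.ndarray]) -> np.ndarray:
    """Moment variance components of allele indicators in a nested design.

    ``allele_idx`` (m,) gives the allele index of each gene copy;
    ``levels`` lists, coarse to fine, the unit label of each copy at every
    hierarchical level (e.g. [plot, cluster, individual]).  Returns an
    array (len(levels) + 1, A): one row per level effect plus the residual
    (between-copies-within-finest) component, per allele.

    The estimator equates observed sums of squares between strata to their
    expectations (Searle's unbalanced nested ANOVA), the same moment method
    behind the Weir-Cockerham estimators.
    """
    m = allele_idx.size
    S_levels = []  # per grouping: (sums (units, A), sizes, inverse)
    for lab in levels:
        uniq, inv = np.unique(lab, return_inverse=True)
        sizes = np.bincount(inv).astype(float)
        sums = np.zeros((uniq.size, A))
        np.add.at(sums, (inv, allele_idx), 1.0)
        S_levels.append((sums, sizes, inv))

    tot_counts = np.bincount(allele_idx, minlength=A).astype(float)
    T_total = tot_counts ** 2 / m
    T_levels = [(sums ** 2 / sizes[:, None]).sum(axis=0) for sums, sizes, _ in S_levels]
    T_copies = tot_counts  # indicator^2 summed

    Ts = [T_total] + T_levels + [T_copies]
    n_strata = len(levels) + 1
    SS = np.array([Ts[s + 1] - Ts[s] for s in range(n_strata)])  # (strata, A)

    # C(G, eff) values; grouping index 0 = total, 1..n = levels, n+1 = copies
    sizes_of = [np.array([float(m)])] + [lv[1] for lv in S_levels] + [np.ones(m)]
    inv_of = [np.zeros(m, dtype=int)] + [lv[2] for lv in S_levels] + [np.arange(m)]

    def C(gi: int, ei: int) -> float:
        if ei <= gi:
            return float(m)
        n_units = sizes_of[ei]
        # parent group (under grouping gi) of each eff unit
        first = np.zeros(len(n_units), dtype=int)
        first[inv_of[ei][::-1]] = np.arange(m)[::-1]  # first copy index per unit
        parents = inv_of[gi][first]
        return _c_coef(n_units, sizes_of[gi][parents])

    M = np.zeros((n_strata, n_strata))
    for s in range(n_strata):  # stratum between grouping s+1, within grouping s
        for e in range(n_strata):  # effect at grouping e+1 (last = residual)
            M[s, e] = C(s + 1, e + 1) - C(s, e + 1)
    comps = np.linalg.solve(M, SS)  # (effects, A)
    return comps


def _hier_components(g: GeoGenotypes, plot_inv: np.ndarray,
                     clu_inv: np.ndarray) -> np.ndarray:
    """(L, 4) variance components (plot, cluster, individual, residual)
    summed over alleles, per locus."""
    out = np.zeros((g.n_loci, 4))
    ind = np.arange(g.n_ind)
    single_plot = np.unique(plot_inv).size < 2
    for l in range(g.n_loci):
        typed = ~g.missing[:, l]
        rows = np.flatnonzero(typed)
        if rows.size < 2:
            continue
        copies_allele = np.concatenate([g.geno[rows, l, 0], g.geno[rows, l, 1]])
        alleles, aidx = np.unique(copies_allele, return_inverse=True)
        if alleles.size < 2:
            continue  # monomorphic locus: zero contribution
        if single_plot:
            # degenerate plot level: drop the stratum, its component is 0
            lv = [np.concatenate([x[rows], x[rows]]) for x in (clu_inv, ind)]
            comps = nested_components(aidx, alleles.size, lv)
            out[l, 1:] = comps.sum(axis=1)
        else:
            lv = [np.concatenate([x[rows], x[rows]])
                  for x in (plot_inv, clu_inv, ind)]
            comps = nested_components(aidx, alleles.size, lv)
            out[l] = comps.sum(axis=1)
    return out


def _f_from_components(c: np.ndarray) -> tuple[float, float, float, float]:
    sp, sc, si, se = c
    total = sp + sc + si + se
    f_plot_total = sp / total
    f_clu_plot = sc / (sc + si + se)
    f_ind_clu = si / (si + se)
    f_ind_total = (sp + sc + si) / total
    return f_plot_total, f_clu_plot, f_ind_clu, f_ind_total


def hier_f(g: GeoGenotypes, plot_labels, cluster_labels, n_perm: int = 1000,
           seed: int | None = None) -> HierFResult:
    """Hierarchical F-statistics over Total > Plot > Cluster > Individual.

    Clusters must be nested in plots.  Significance per level permutes the
    units one level below: whole clusters among plots (F_PlotTotal),
    individuals among clusters within plots (F_CluPlot), and gene copies
    among individuals within clusters (F_IndClu).
    """
    plot_inv, plots = _group_index(plot_labels)
    clu_inv, clus = _group_index(cluster_labels)
    flags: list[str] = []
    if len(plots) < 2:
        # merged/degenerate plot level: F_CluPlot reduces to the two-level
        # theta among clusters, plot component fixed at zero
        flags.append("single plot: plot-level component fixed at 0")
    # nesting check + flag single-cluster plots
    clu_plot = {}
    for c, p in zip(clu_inv, plot_inv):
        if c in clu_plot and clu_plot[c] != p:
            raise ValueError("clusters must be nested within plots")
        clu_plot[c] = p
    per_plot = np.bincount(np.array([clu_plot[c] for c in sorted(clu_plot)]),
                           minlength=len(plots))
    for pi, npc in enumerate(per_plot):
        if npc < 2:
            flags.append(f"plot {plots[pi]} has a single cluster")

    per_locus = _hier_components(g, plot_inv, clu_inv)
    pooled = per_locus.sum(axis=0)
    fpt, fcp, fic, fit = _f_from_components(pooled)

    p_pt = p_cp = p_ic = None
    if n_perm:
        rng = np.random.default_rng(seed)
        ge = np.zeros(3)
        clu_ids = np.array(sorted(clu_plot))
        clu_parent = np.array([clu_plot[c] for c in clu_ids])
        for _ in range(n_perm):
            # F_PlotTotal: permute whole clusters among plots
            new_parent = rng.permutation(clu_parent)
            pmap = dict(zip(clu_ids, new_parent))
            plot_perm = np.array([pmap[c] for c in clu_inv])
            f1, _, _, _ = _f_from_components(
                _hier_components(g, plot_perm, clu_inv).sum(axis=0))
            ge[0] += f1 >= fpt
            # F_CluPlot: permute individuals among clusters within plots
            clu_perm = clu_inv.copy()
            for pi in range(len(plots)):
                rows = np.flatnonzero(plot_inv == pi)
                clu_perm[rows] = clu_inv[rows][rng.permutation(rows.size)]
            _, f2, _, _ = _f_from_components(
                _hier_components(g, plot_inv, clu_perm).sum(axis=0))
            ge[1] += f2 >= fcp
            # F_IndClu: permute gene copies among individuals within clusters
            gperm = _permute_copies_within(g, clu_inv, rng)
            _, _, f3, _ = _f_from_components(
                _hier_components(gperm, plot_inv, clu_inv).sum(axis=0))
            ge[2] += f3 >= fic
        p_pt, p_cp, p_ic = (1 + ge) / (n_perm + 1)

    return HierFResult(f_plot_total=fpt, f_clu_plot=fcp, f_ind_clu=fic,
                       f_ind_total=fit, p_plot_total=p_pt, p_clu_plot=p_cp,
                       p_ind_clu=p_ic, components=pooled,
                       components_per_locus=per_locus, n_perm=n_perm,
                       flags=flags)


def _permute_copies_within(g: GeoGenotypes, clu_inv: np.ndarray,
                           rng: np.random.Generator) -> GeoGenotypes:
    """Shuffle gene copies among typed individuals within each cluster,
    per locus (the null for F_IndClu)."""
    geno = g.geno.copy()
    for l in range(g.n_loci):
        typed = ~g.missing[:, l]
        for c in np.unique(clu_inv):
            rows = np.flatnonzero((clu_inv == c) & typed)
            if rows.size < 2:
                continue
            pool = geno[rows, l, :].ravel()
            pool = pool[rng.permutation(pool.size)]
            geno[rows, l, :] = pool.reshape(rows.size, 2)
    return GeoGenotypes(ids=list(g.ids), plot=g.plot.copy(), x=g.x.copy(),
                        y=g.y.copy(), geno=geno, locus_names=list(g.locus_names))
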