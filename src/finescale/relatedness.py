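"""Pairwise relatedness estimators for codominant markers.

Two estimators are provided, matching the two spatial-autocorrelation
traditions for SSR data:

* the Loiselle et al. (1995) kinship coefficient ``F_ij`` — a correlation of
  allele-frequency deviations between two individuals relative to a
  reference allele-frequency profile, with a small-sample bias term;
* the Smouse & Peakall (1999) multivariate genotypic covariance — squared
  codominant genotypic distances summed over loci and double-centred, whose
  off-diagonal cells drive the multilocus autocorrelation coefficient ``r``.

Both operate pairwise-complete over loci: a locus missing in either member
of a pair is dropped from that pair's sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import AlleleFrequencies, GeoGenotypes, allele_frequencies


@dataclass
class PairMatrix:
    """Symmetric individual-by-individual estimator matrix.

    ``values[i, j]`` is the estimate for the pair (i, j); ``mask[i, j]`` is
    True where no shared typed locus exists (entry undefined).  The diagonal
    carries self-values for the covariance estimator and is masked for
    kinship use.
    """

    values: np.ndarray
    mask: np.ndarray
    estimator: str
    ref: AlleleFrequencies | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i<j) values and validity as flat arrays."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu], ~self.mask[iu]


def _dosage_arrays(g: GeoGenotypes, ref: AlleleFrequencies):
    """Per locus: (alleles, dosage matrix n x A with allele frequencies per
    individual, i.e. dosage/2) restricted to alleles present in ``ref``."""
    out = []
    for l in range(g.n_loci):
        alleles = ref.alleles(l)
        A = alleles.size
        idx = {a: k for k, a in enumerate(alleles)}
        P = np.zeros((g.n_ind, A))
        for copy in (0, 1):
            col = g.geno[:, l, copy]
            for i, a in enumerate(col):
                if a > 0 and a in idx:
                    P[i, idx[a]] += 0.5
        out.append((alleles, P))
    return out


def loiselle_kinship(g: GeoGenotypes, ref: AlleleFrequencies | None = None) -> PairMatrix:
    """Loiselle et al. (1995) kinship coefficient for every pair.

    For pair (i, j),

        F_ij = sum_l sum_a [ (p_ila - pbar_la)(p_jla - pbar_la)
                             + pbar_la (1 - pbar_la) / (n_l - 1) ]
               / sum_l sum_a pbar_la (1 - pbar_la)

    where p_ila is individual i's allele-a frequency (dosage/2) at locus l,
    pbar_la the reference frequency and n_l the number of typed individuals
    at locus l in the reference set.  Loci missing in either individual are
    excluded from both sums; pairs with no shared typed locus are masked.
    """
    if ref is None:
        ref = allele_frequencies(g)
    n = g.n_ind
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    typed = ~g.missing  # (n, L)
    for l, (alleles, P) in enumerate(_dosage_arrays(g, ref)):
        if alleles.size == 0:
            continue
        pbar = np.array([ref.freqs[l][int(a)] for a in alleles])
        het = pbar * (1.0 - pbar)
        n_l = int(ref.n_typed[l])
        bias = het.sum() / (n_l - 1) if n_l > 1 else 0.0
        D = P - pbar  # typed rows meaningful only
        C = D @ D.T + bias
        ok = np.outer(typed[:, l], typed[:, l])
        num += np.where(ok, C, 0.0)
        den += np.where(ok, het.sum(), 0.0)
    mask = den == 0
    values = np.divide(num, den, out=np.zeros_like(num), where=~mask)
    return PairMatrix(values=values, mask=mask, estimator="loiselle_F", ref=ref)


# ---------------------------------------------------------------------------
# Smouse & Peakall genotypic distance / covariance
# ---------------------------------------------------------------------------

def _locus_d2(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Pairwise squared genotypic distance at one locus.

    Codominant single-locus distances (unordered genotypes):
    identical 0; hom vs het sharing the allele 1; het vs het sharing one
    allele 1; het vs het sharing none 2; hom vs het sharing none 3;
    hom vs different hom 4.  Rows with a1 == 0 are missing (caller masks).
    """
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    is_hom = lo == hi
    # pairwise allele matches between the two sorted genotypes
    m_ll = lo[:, None] == lo[None, :]
    m_lh = lo[:, None] == hi[None, :]
    m_hl = hi[:, None] == lo[None, :]
    m_hh = hi[:, None] == hi[None, :]
    identical = m_ll & m_hh
    hom_i = is_hom[:, None]
    hom_j = is_hom[None, :]
    share_any = m_ll | m_lh | m_hl | m_hh
    d2 = np.empty(identical.shape, dtype=float)
    both_hom = hom_i & hom_j
    one_hom = hom_i ^ hom_j
    no_hom = ~(hom_i | hom_j)
    d2[both_hom] = np.where(identical[both_hom], 0.0, 4.0)
    d2[one_hom] = np.where(share_any[one_hom], 1.0, 3.0)
    # het vs het: 0 identical, 1 one shared, 2 none shared
    shared_count = (m_ll | m_lh).astype(int) + (m_hl | m_hh).astype(int)
    d2[no_hom] = (2 - shared_count)[no_hom]
    d2[identical] = 0.0
    return d2


def smouse_peakall_d2(g: GeoGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Multilocus squared genotypic distance matrix and its validity mask.

    Distances are summed over pairwise-complete loci and rescaled by
    L / L_shared so pairs typed at fewer loci remain on the full-locus
    scale.  Returns ``(d2, mask)`` with mask True where no locus is shared.
    """
    n, L = g.n_ind, g.n_loci
    total = np.zeros((n, n))
    shared = np.zeros((n, n))
    typed = ~g.missing
    for l in range(L):
        d2 = _locus_d2(g.geno[:, l, 0], g.geno[:, l, 1])
        ok = np.outer(typed[:, l], typed[:, l])
        total += np.where(ok, d2, 0.0)
        shared += ok
    mask = shared == 0
    with np.errstate(invalid="ignore"):
        d2 = np.where(mask, 0.0, total * (L / np.where(shared == 0, 1, shared)))
    np.fill_diagonal(mask, False)
    return d2, mask


def double_centre(d2: np.ndarray) -> np.ndarray:
    """Gower double-centring: c_ij = -1/2 (d2_ij - row_i - col_j + grand)."""
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row - col + grand)


def smouse_peakall_cov(g: GeoGenotypes) -> PairMatrix:
    """Double-centred multilocus genotypic covariance matrix.

    The diagonal ``c_ii`` is defined (it scales the autocorrelation
    coefficient r); row and column sums are zero by construction.
    """
    if g.n_ind < 2:
        raise ValueError("need at least two individuals")
    d2, mask = smouse_peakall_d2(g)
    c = double_centre(d2)
    return PairMatrix(values=c, mask=mask, estimator="smouse_peakall_cov", ref=None)
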