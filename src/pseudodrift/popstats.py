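"""Population-genetic statistics: heterozygosity, F_ST, HWE, inbreeding, Mantel.

These are the statistics used to argue that a population is small,
isolated and drifting: reduced heterozygosity, elevated differentiation
(two F_ST estimators), an exact Hardy-Weinberg test per locus, per-individual
inbreeding coefficients, and Mantel tests / correlograms for isolation by
distance.

Conventions
-----------
* Wright's F_ST uses unweighted population means: H_T = 2*pbar*(1-pbar)
  with pbar the plain mean of population frequencies, H_S the plain mean
  of 2*p_k*(1-p_k), F_ST = (H_T - H_S)/H_T (0 where H_T = 0).
* Weir & Cockerham's theta is the 1984 variance-components estimator for
  diploid data; the global value is ratio-of-sums across loci.
* The HWE test is the exact conditional test on genotype counts given
  allele counts (no mid-p adjustment).
* Mantel p-values are one-sided permutation p-values with joint row/column
  permutation; the correlogram tests each geographic distance class via
  its binary membership matrix under the same scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = [
    "PopAlleleFreqs",
    "MantelResult",
    "heterozygosity",
    "pop_allele_freqs",
    "wright_fst",
    "pairwise_fst_matrix",
    "weir_cockerham_fst",
    "hwe_exact_test",
    "hwe_exact_distribution",
    "inbreeding_f",
    "mantel",
    "fst_rank",
]


@dataclass
class PopAlleleFreqs:
    """Per-population, per-locus alternate-allele frequency and sample size."""

    populations: list[str]
    loci: list[str]
    freqs: np.ndarray  # (n_pops, n_loci), NaN where a population has no calls
    sizes: np.ndarray  # (n_pops, n_loci) individuals genotyped

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        ok = np.isnan(self.freqs) | ((self.freqs >= 0) & (self.freqs <= 1))
        if not ok.all():
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class MantelResult:
    r: float
    p_value: float
    permutations: int
    classes: list[dict] = field(default_factory=list)


def pop_allele_freqs(m: GenotypeMatrix) -> PopAlleleFreqs:
    """Tabulate per-population allele frequencies and per-locus sample sizes."""
    if m.populations is None:
        raise ValueError("genotype matrix has no population labels")
    pops = sorted(set(m.populations))
    freqs = np.full((len(pops), m.n_loci), np.nan)
    sizes = np.zeros((len(pops), m.n_loci))
    for i, pop in enumerate(pops):
        sub = m.codes[m.populations == pop]
        called = ~np.isnan(sub)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freqs[i] = np.nansum(sub, axis=0) / (2 * np.maximum(n, 1))
        freqs[i, n == 0] = np.nan
        sizes[i] = n
    return PopAlleleFreqs(pops, list(m.loci), freqs, sizes)


# ------------------------------------------------------------ heterozygosity


def heterozygosity(m: GenotypeMatrix) -> dict:
    """Observed and expected heterozygosity per locus plus means over loci.

    H_obs is the fraction of called genotypes that are heterozygous;
    H_exp = 2p(1-p) from the within-sample allele frequency.  Loci with no
    calls are excluded from the means.
    """
    called = m.called()
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        h_obs = np.where(n > 0, np.nansum(m.codes == 1, axis=0) / np.maximum(n, 1), np.nan)
        p = m.allele_freqs()
        h_exp = 2 * p * (1 - p)
    return {
        "h_obs": h_obs,
        "h_exp": h_exp,
        "mean_h_obs": float(np.nanmean(h_obs)),
        "mean_h_exp": float(np.nanmean(h_exp)),
    }


# ------------------------------------------------------------------- F_ST


def wright_fst(freqs: PopAlleleFreqs, pops=None) -> dict:
    """Wright's F_ST from population allele frequencies (unweighted means)."""
    idx = (
        np.arange(len(freqs.populations))
        if pops is None
        else np.array([freqs.populations.index(p) for p in pops])
    )
    if idx.size < 2:
        raise ValueError("F_ST needs at least two populations")
    p = freqs.freqs[idx]
    pbar = np.nanmean(p, axis=0)
    h_t = 2 * pbar * (1 - pbar)
    h_s = np.nanmean(2 * p * (1 - p), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1), 0.0)
    fst[np.isnan(h_t) | np.isnan(h_s)] = np.nan
    return {"per_locus": fst, "mean": float(np.nanmean(fst))}


def pairwise_fst_matrix(freqs: PopAlleleFreqs) -> np.ndarray:
    """Symmetric matrix of multilocus pairwise Wright's F_ST (genetic distance)."""
    k = len(freqs.populations)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = wright_fst(freqs, [freqs.populations[i], freqs.populations[j]])["mean"]
            out[i, j] = out[j, i] = f
    return out


def weir_cockerham_fst(m: GenotypeMatrix, pops=None) -> dict:
    """Weir & Cockerham (1984) theta for diploid biallelic data.

    Per locus, the among-population (a), among-individuals-within-population
    (b) and within-individual (c) variance components are computed from
    sample sizes, allele frequencies and observed heterozygote frequencies;
    theta = a/(a+b+c) per locus and ratio-of-sums across loci.  Populations
    with fewer than two called individuals at a locus are excluded there;
    loci with a zero denominator are reported as undefined.
    """
    if m.populations is None:
        raise ValueError("genotype matrix has no population labels")
    labels = sorted(set(m.populations)) if pops is None else list(pops)
    if len(labels) < 2:
        raise ValueError("theta needs at least two populations")
    groups = [m.codes[m.populations == lab] for lab in labels]
    L = m.n_loci
    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    excluded: list[str] = []
    for j in range(L):
        ns, ps, hs = [], [], []
        for g in groups:
            col = g[:, j]
            col = col[~np.isnan(col)]
            if col.size < 2:
                continue
            ns.append(col.size)
            ps.append(col.mean() / 2)
            hs.append(np.mean(col == 1))
        r = len(ns)
        if r < 2:
            excluded.append(m.loci[j])
            continue
        n = np.array(ns, dtype=float)
        p = np.array(ps)
        h = np.array(hs)
        nbar = n.mean()
        nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
        pbar = (n * p).sum() / n.sum()
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / n.sum()
        a[j] = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b[j] = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c[j] = hbar / 2
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    defined = ~np.isnan(denom) & (denom != 0)
    theta[~defined] = np.nan
    undefined = [m.loci[j] for j in range(L) if not defined[j]]
    global_theta = float(np.nansum(a[defined]) / np.nansum(denom[defined]))
    return {
        "per_locus": theta,
        "global": global_theta,
        "components": {"a": a, "b": b, "c": c},
        "undefined_loci": undefined,
        "excluded_loci": excluded,
    }


def fst_rank(per_locus: np.ndarray, locus_index: int) -> int:
    """1-based rank (1 = most differentiated) of one locus among per-locus F_ST."""
    v = per_locus[locus_index]
    if np.isnan(v):
        raise ValueError("focal locus has undefined F_ST")
    return int(1 + np.nansum(per_locus > v))


# -------------------------------------------------------------- HWE exact


def hwe_exact_distribution(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of heterozygote counts given allele counts.

    Returns (possible het counts, probabilities).  With n diploid
    individuals and n_alt alternate alleles among 2n, heterozygote counts
    share the parity of n_alt; P(n_het) follows the standard conditional
    (Levene/Haldane) distribution.
    """
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_alt = (n_alt - hets) // 2
    hom_ref = (n_ref - hets) // 2
    logp = (
        hets * math.log(2)
        + gammaln(n + 1)
        - gammaln(hom_ref + 1)
        - gammaln(hets + 1)
        - gammaln(hom_alt + 1)
        + gammaln(n_alt + 1)
        + gammaln(n_ref + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    return hets, p / p.sum()


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test p-value on one locus's genotype counts.

    p is the total probability of heterozygote configurations no more
    likely than the observed one, conditional on the allele counts.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = n_het + 2 * n_hom_alt
    hets, probs = hwe_exact_distribution(n, n_alt)
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# -------------------------------------------------------------- inbreeding


def inbreeding_f(
    m: GenotypeMatrix,
    ref_freqs: np.ndarray | None = None,
    ref_n: np.ndarray | float | None = None,
) -> np.ndarray:
    """Per-individual inbreeding coefficient F = (O_hom - E_hom)/(L - E_hom).

    E_hom sums 1 - 2p(1-p) * 2n/(2n-1) over the individual's called loci
    (the sample-size-corrected expected homozygosity).  Defaults: reference
    frequencies and per-locus sample sizes from the matrix itself.
    Individuals whose called loci are all uninformative get NaN.
    """
    p = m.allele_freqs() if ref_freqs is None else np.asarray(ref_freqs, dtype=float)
    if p.shape != (m.n_loci,):
        raise ValueError("ref_freqs must give one frequency per locus")
    if ref_n is None:
        n = m.called().sum(axis=0).astype(float)
    else:
        n = np.broadcast_to(np.asarray(ref_n, dtype=float), (m.n_loci,))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n > 0.5, 2 * n / np.maximum(2 * n - 1, 1), 1.0)
        e_hom_locus = 1 - 2 * p * (1 - p) * corr
    called = m.called()
    obs_hom = ((m.codes == 0) | (m.codes == 2)).sum(axis=1).astype(float)
    e_hom = np.where(called, e_hom_locus[None, :], 0.0).sum(axis=1)
    l_called = called.sum(axis=1).astype(float)
    denom = l_called - e_hom
    out = np.full(m.n_samples, np.nan)
    ok = np.abs(denom) > 1e-12
    out[ok] = (obs_hom[ok] - e_hom[ok]) / denom[ok]
    return out


# ------------------------------------------------------------------ Mantel


def _lower(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def _check_distance(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return d


def mantel(
    d_gen: np.ndarray,
    d_geo: np.ndarray,
    permutations: int = 999,
    classes: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel test (and optional correlogram) between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    permutation p-value is (1 + #{r_perm >= r_obs}) / (permutations + 1)
    under joint row/column permutation of ``d_geo``.  With ``classes`` (bin
    edges over geographic distance), each class is tested by correlating
    ``d_gen`` with the binary within-class membership matrix under the
    same scheme.
    """
    d_gen = _check_distance(d_gen, "d_gen")
    d_geo = _check_distance(d_geo, "d_geo")
    if d_gen.shape != d_geo.shape:
        raise ValueError("distance matrices must be conformable")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = d_gen.shape[0]
    x = _lower(d_gen)
    if np.std(x) == 0:
        raise ValueError("d_gen is constant; Mantel r is undefined")

    def corr_with(mat: np.ndarray) -> tuple[float, float]:
        y = _lower(mat)
        if np.std(y) == 0:
            return np.nan, np.nan
        r_obs = float(np.corrcoef(x, y)[0, 1])
        xc = (x - x.mean()) / x.std()
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            yp = _lower(mat[np.ix_(perm, perm)])
            r_p = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
            if r_p >= r_obs - 1e-12:
                count += 1
        return r_obs, (1 + count) / (permutations + 1)

    r_obs, p = corr_with(d_geo)
    result = MantelResult(r=r_obs, p_value=p, permutations=permutations)
    if classes is not None:
        edges = np.asarray(classes, dtype=float)
        for lo, hi in zip(edges[:-1], edges[1:]):
            member = ((d_geo > lo) & (d_geo <= hi)).astype(float)
            np.fill_diagonal(member, 0.0)
            r_c, p_c = corr_with(member)
            result.classes.append(
                {"lower": float(lo), "upper": float(hi), "r": r_c, "p_value": p_c}
            )
    return result
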