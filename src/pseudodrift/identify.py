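"""Individual identification from noninvasive genotype data.

A noninvasive survey yields many samples (feces, hair, saliva) from an
unknown, smaller number of animals.  This module turns a filtered SNP
genotype matrix into unique individuals:

1. ``apply_filters`` — the locus/sample filter cascade (missingness, minor
   allele count, monomorphism, Hardy-Weinberg outliers, per-sample call
   counts), iterated to a fixed point;
2. ``estimate_relatedness`` — pairwise PI-HAT (method-of-moments IBD from
   identity-by-state sharing, PLINK-style, with sample-size-corrected
   moment estimators);
3. ``cluster_individuals`` — single-linkage clustering of high-PI-HAT
   pairs into recapture groups, with an ambiguous zone whose pairs have
   one member dropped;
4. ``probability_of_identity`` — the PID / PID-sibs statistics quantifying
   the marker panel's power to distinguish individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix
from .popstats import hwe_exact_test

__all__ = [
    "FilterSpec",
    "RelatednessMatrix",
    "IndividualAssignment",
    "apply_filters",
    "estimate_relatedness",
    "cluster_individuals",
    "probability_of_identity",
]


@dataclass
class FilterSpec:
    """Locus/sample filter thresholds.

    Defaults follow the noninvasive-panel cascade: drop loci missing in
    >10% of samples, monomorphic loci, singletons (MAC < 2) and loci out
    of HWE at alpha in two or more populations; then drop samples called
    at fewer than 50 loci.
    """

    max_locus_missingness: float = 0.10
    min_loci_per_sample: int = 50
    min_minor_allele_count: int = 2
    drop_monomorphic: bool = True
    hwe_alpha: float = 0.05
    hwe_min_pops_failing: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.max_locus_missingness <= 1:
            raise ValueError("max_locus_missingness must lie in [0, 1]")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must lie in (0, 1)")


@dataclass
class RelatednessMatrix:
    """Symmetric PI-HAT matrix with a per-pair reliability mask."""

    samples: list[str]
    pi_hat: np.ndarray
    unreliable: np.ndarray  # True where a pair shares < min co-called loci

    def __post_init__(self) -> None:
        self.pi_hat = np.asarray(self.pi_hat, dtype=float)
        n = len(self.samples)
        if self.pi_hat.shape != (n, n):
            raise ValueError("PI-HAT matrix shape does not match samples")
        if not np.allclose(self.pi_hat, self.pi_hat.T, equal_nan=True):
            raise ValueError("PI-HAT matrix must be symmetric")


@dataclass
class IndividualAssignment:
    assignment: dict[str, int]
    dropped: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(set(self.assignment.values()))


# ---------------------------------------------------------------- filtering


def apply_filters(
    m: GenotypeMatrix, spec: FilterSpec | None = None
) -> tuple[GenotypeMatrix, list[dict]]:
    """Apply the locus/sample filter cascade until stable.

    Locus filters run first (missingness, minor allele count, monomorphism,
    HWE per population), the sample call-count filter last; because sample
    removal changes locus statistics, the cascade repeats until no further
    removal occurs.  Returns the filtered matrix and a report listing each
    removal with its reason.
    """
    spec = spec or FilterSpec()
    report: list[dict] = []
    current = m
    while True:
        removed_any = False
        # --- locus filters, recomputed on the current matrix
        drop: dict[int, str] = {}
        miss = current.locus_missingness()
        freqs = current.allele_freqs()
        called = current.called().sum(axis=0)
        alt = np.nansum(current.codes, axis=0)
        mac = np.minimum(alt, 2 * called - alt)
        for j in range(current.n_loci):
            if miss[j] > spec.max_locus_missingness:
                drop[j] = "missingness"
            elif called[j] == 0 or (spec.drop_monomorphic and freqs[j] in (0.0, 1.0)):
                drop[j] = "monomorphic"
            elif mac[j] < spec.min_minor_allele_count:
                drop[j] = "minor allele count"
        if current.populations is not None:
            pops = sorted(set(current.populations))
            for j in range(current.n_loci):
                if j in drop:
                    continue
                failing = 0
                for pop in pops:
                    col = current.codes[current.populations == pop, j]
                    col = col[~np.isnan(col)]
                    if col.size == 0:
                        continue
                    counts = [int((col == k).sum()) for k in (0, 1, 2)]
                    if hwe_exact_test(*counts) < spec.hwe_alpha:
                        failing += 1
                if failing >= spec.hwe_min_pops_failing:
                    drop[j] = "HWE"
        if drop:
            removed_any = True
            for j, reason in sorted(drop.items()):
                report.append({"item": current.loci[j], "kind": "locus", "reason": reason})
            keep = [j for j in range(current.n_loci) if j not in drop]
            current = current.subset(locus_idx=keep)
        # --- sample filter last
        called_per_sample = current.called().sum(axis=1)
        bad = np.flatnonzero(called_per_sample < spec.min_loci_per_sample)
        if bad.size:
            removed_any = True
            for i in bad:
                report.append(
                    {"item": current.samples[i], "kind": "sample", "reason": "few called loci"}
                )
            keep_s = [i for i in range(current.n_samples) if i not in set(bad)]
            current = current.subset(sample_idx=keep_s)
        if not removed_any:
            break
        if current.n_loci == 0 or current.n_samples == 0:
            warnings.warn("all data removed by filtering", stacklevel=2)
            break
    return current, report


# -------------------------------------------------------------- relatedness


def _ibd_expectations(p: np.ndarray, allele_count: np.ndarray | None):
    """Per-locus P(IBS class | IBD state) from reference allele frequencies.

    With a finite reference sample the plain moments (powers of p) are
    biased; the unbiased estimators replace each monomial by a ratio of
    falling factorials of allele counts (X = p*a alt copies among a).
    Without a reference size the large-sample forms are used.
    """
    q = 1 - p
    if allele_count is None:
        e00 = 2 * p**2 * q**2
        e01 = 4 * (p**3 * q + q**3 * p)
        e02 = p**4 + q**4 + 4 * p**2 * q**2
        e11 = 2 * p**2 * q + 2 * q**2 * p
        e12 = p**3 + q**3 + p**2 * q + q**2 * p
    else:
        a = allele_count
        X, Y = p * a, q * a

        def ff(z, k):
            out = np.ones_like(z)
            for i in range(k):
                out = out * (z - i)
            return out

        d3, d4 = ff(a, 3), ff(a, 4)
        e00 = 2 * ff(X, 2) * ff(Y, 2) / d4
        e01 = 4 * (ff(X, 3) * Y + ff(Y, 3) * X) / d4
        e02 = (ff(X, 4) + ff(Y, 4) + 4 * ff(X, 2) * ff(Y, 2)) / d4
        e11 = 2 * (ff(X, 2) * Y + ff(Y, 2) * X) / d3
        e12 = (ff(X, 3) + ff(Y, 3) + ff(X, 2) * Y + ff(Y, 2) * X) / d3
    return e00, e01, e02, e11, e12


def estimate_relatedness(
    m: GenotypeMatrix,
    ref_freqs: np.ndarray | None = None,
    ref_n: int | None = None,
    min_co_called: int = 10,
) -> RelatednessMatrix:
    """Pairwise PI-HAT by method-of-moments IBD estimation.

    Observed identity-by-state counts per pair are combined with their
    expected probabilities under IBD states 0/1/2 (from reference allele
    frequencies) to solve for P(IBD=z); PI-HAT = P(IBD=2) + P(IBD=1)/2,
    clamped to [0, 1].  ``ref_freqs`` should come from an external
    reference panel; by default the within-sample frequencies are used,
    which biases PI-HAT downward for small, related samples (a warning is
    emitted).  Pairs sharing fewer than ``min_co_called`` loci are flagged
    unreliable.
    """
    if ref_freqs is None:
        warnings.warn(
            "using within-sample allele frequencies as the PI-HAT reference; "
            "estimates are biased when the sample is small or related",
            stacklevel=2,
        )
        ref_freqs = m.allele_freqs()
        if ref_n is None:
            ref_n = m.n_samples
    p = np.asarray(ref_freqs, dtype=float)
    if p.shape != (m.n_loci,):
        raise ValueError("ref_freqs must give one frequency per locus")
    informative = ~np.isnan(p) & (p > 0) & (p < 1)
    allele_count = None
    if ref_n is not None:
        a = 2.0 * ref_n
        if a < 4:
            raise ValueError("reference sample must contain at least 2 individuals")
        allele_count = np.full(m.n_loci, a)
    e00, e01, e02, e11, e12 = _ibd_expectations(
        np.where(informative, p, 0.5), allele_count
    )
    codes = m.codes
    n = m.n_samples
    pi = np.eye(n)
    unreliable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        gi = codes[i]
        for j in range(i + 1, n):
            gj = codes[j]
            co = ~np.isnan(gi) & ~np.isnan(gj) & informative
            L = int(co.sum())
            if L < min_co_called:
                unreliable[i, j] = unreliable[j, i] = True
            if L == 0:
                pi[i, j] = pi[j, i] = np.nan
                continue
            diff = np.abs(gi[co] - gj[co])
            n0 = float((diff == 2).sum())
            n1 = float((diff == 1).sum())
            n2 = float((diff == 0).sum())
            s00, s01, s02 = e00[co].sum(), e01[co].sum(), e02[co].sum()
            s11, s12 = e11[co].sum(), e12[co].sum()
            P0 = n0 / s00 if s00 > 0 else 0.0
            P1 = (n1 - P0 * s01) / s11 if s11 > 0 else 0.0
            P2 = (n2 - P0 * s02 - P1 * s12) / L
            # bound to the probability simplex
            P0, P1, P2 = (max(0.0, v) for v in (P0, P1, P2))
            total = P0 + P1 + P2
            if total > 0:
                P0, P1, P2 = P0 / total, P1 / total, P2 / total
            val = min(1.0, max(0.0, P2 + 0.5 * P1))
            pi[i, j] = pi[j, i] = val
    return RelatednessMatrix(list(m.samples), pi, unreliable)


# ---------------------------------------------------------------- clustering


def cluster_individuals(
    r: RelatednessMatrix,
    recapture_threshold: float = 0.78,
    ambiguous_low: float = 0.6,
    missing_counts: np.ndarray | None = None,
) -> IndividualAssignment:
    """Cluster samples into individuals by relatedness thresholds.

    Pairs with PI-HAT above ``recapture_threshold`` are recaptures of one
    individual (single linkage, so chained recaptures merge).  Cross-cluster
    pairs in the ambiguous zone (ambiguous_low, recapture_threshold] cannot
    be ruled recaptures, so the pair member with more missing data (ties:
    the lexicographically later id) is dropped.  Remaining samples become
    singleton individuals.
    """
    if not ambiguous_low < recapture_threshold:
        raise ValueError("ambiguous_low must be below recapture_threshold")
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(r.samples)
    pi = np.where(np.isnan(r.pi_hat), -1.0, r.pi_hat)
    adj = csr_matrix(pi > recapture_threshold)
    _, labels = connected_components(adj, directed=False)

    missing = (
        np.zeros(n) if missing_counts is None else np.asarray(missing_counts, dtype=float)
    )
    dropped: set[int] = set()
    iu, ju = np.triu_indices(n, k=1)
    amb = (pi[iu, ju] > ambiguous_low) & (pi[iu, ju] <= recapture_threshold)
    for i, j in zip(iu[amb], ju[amb]):
        if labels[i] == labels[j] or i in dropped or j in dropped:
            continue
        if missing[i] > missing[j]:
            victim = i
        elif missing[j] > missing[i]:
            victim = j
        else:
            victim = i if r.samples[i] > r.samples[j] else j
        dropped.add(victim)

    kept = [i for i in range(n) if i not in dropped]
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i in kept:
        lab = labels[i]
        if lab not in relabel:
            relabel[lab] = len(relabel)
        assignment[r.samples[i]] = relabel[lab]
    return IndividualAssignment(
        assignment=assignment, dropped=[r.samples[i] for i in sorted(dropped)]
    )


# ----------------------------------------------------- probability of identity


def probability_of_identity(freqs: np.ndarray) -> tuple[float, float]:
    """Multilocus PID and PID-sibs for a biallelic marker panel.

    Per locus with allele frequencies (p, q): PID = p^4 + q^4 + (2pq)^2
    (probability two random individuals share a genotype) and
    PID-sibs = 0.25 + 0.5*(p^2+q^2) + 0.5*(p^2+q^2)^2 - 0.25*(p^4+q^4);
    across loci the per-locus values multiply.  Fixed loci contribute 1
    (uninformative).
    """
    p = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    q = 1 - p
    sum2 = p**2 + q**2
    sum4 = p**4 + q**4
    pid = sum4 + (2 * p * q) ** 2
    pid_sibs = 0.25 + 0.5 * sum2 + 0.5 * sum2**2 - 0.25 * sum4
    return float(np.prod(pid)), float(np.prod(pid_sibs))
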