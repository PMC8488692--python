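"""Synthetic genotype data with known ground truth.

Real noninvasive surveys cannot be redistributed, so every pipeline input
is emulated here with controlled structure:

* Hardy-Weinberg populations with specified allele frequencies;
* pedigrees with Mendelian transmission and known kinship classes, for
  validating relatedness estimators;
* noisy noninvasive replicate calls with per-method failure rates and
  allelic dropout (a heterozygote observed as a random homozygote —
  dropout never manufactures heterozygotes);
* multi-population landscapes with isolation by distance, where population
  allele frequencies diverge on the logit scale with spatial correlation
  exp(-d/decay).

Default method failure rates are one minus the empirical success rates of
the three genotyping assays (Sanger 0.52, amplicon NGS 0.60, AS-PCR 0.68).
The allelic-dropout default of 0.1 is a round placeholder typical of fecal
DNA panels, not an estimate from any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import GenotypeCall, SampleCallSet
from .genotypes import GenotypeMatrix

__all__ = [
    "SynthConfig",
    "PedigreeSpec",
    "generate_hwe_population",
    "generate_pedigree_genotypes",
    "simulate_noninvasive_calls",
    "add_genotyping_noise",
    "generate_recapture_dataset",
    "generate_ibd_landscape",
]

DEFAULT_METHOD_FAILURE = {"sanger": 1 - 0.52, "ngs": 1 - 0.60, "aspcr": 1 - 0.68}


@dataclass
class SynthConfig:
    """Knobs for synthetic genotype generation."""

    n_individuals: int = 100
    n_loci: int = 44
    allele_freqs: np.ndarray | float = 0.5
    dropout_rate: float = 0.1
    method_failure_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_FAILURE)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("need at least one individual and one locus")
        freqs = np.broadcast_to(
            np.asarray(self.allele_freqs, dtype=float), (self.n_loci,)
        ).copy()
        bad = np.flatnonzero(~((freqs >= 0) & (freqs <= 1)))
        if bad.size:
            raise ValueError(
                f"allele frequency out of [0, 1] at locus index {bad[0]} "
                f"({freqs[bad[0]]!r})"
            )
        self.allele_freqs = freqs
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        for m, f in self.method_failure_rates.items():
            if not 0 <= f <= 1:
                raise ValueError(f"failure rate for {m!r} must lie in [0, 1]")


@dataclass
class PedigreeSpec:
    """A two-or-more-generation pedigree built from founder mating pairs.

    ``matings`` maps (parent_a, parent_b) founder indices to an offspring
    count.  Non-founders always have exactly two parents; the graph is
    acyclic by construction.
    """

    n_founders: int = 4
    matings: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 1, 2), (2, 3, 2)]
    )

    def __post_init__(self) -> None:
        for a, b, k in self.matings:
            if not (0 <= a < self.n_founders and 0 <= b < self.n_founders):
                raise ValueError("mating parents must be founder indices")
            if a == b:
                raise ValueError("selfing is not modelled")
            if k < 1:
                raise ValueError("offspring count must be >= 1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_hwe_population(config: SynthConfig, rng=None) -> GenotypeMatrix:
    """Genotypes drawn independently under Hardy-Weinberg proportions.

    Each locus is Binomial(2, p) alternate-allele counts, i.e. genotype
    probabilities (q^2, 2pq, p^2).
    """
    rng = _rng(config.seed if rng is None else rng)
    codes = rng.binomial(
        2, config.allele_freqs[None, :], size=(config.n_individuals, config.n_loci)
    ).astype(float)
    samples = [f"S{i:04d}" for i in range(config.n_individuals)]
    loci = [f"L{j:04d}" for j in range(config.n_loci)]
    return GenotypeMatrix(samples, loci, codes)


def generate_pedigree_genotypes(
    spec: PedigreeSpec, allele_freqs, seed=None
) -> tuple[GenotypeMatrix, dict[tuple[str, str], str]]:
    """Founders under HWE, offspring by Mendelian transmission.

    Returns the genotype matrix and the true pairwise kinship class for
    every sample pair: "parent-offspring", "full-sib" or "unrelated"
    (founders are mutually unrelated; half-sib and grandparent classes are
    not produced by this spec and fall under "unrelated" only if truly
    unrelated — other related pairs are labelled "other").
    """
    rng = _rng(seed)
    p = np.atleast_1d(np.asarray(allele_freqs, dtype=float))
    L = p.size
    # allele-level representation: (individual, locus, 2)
    alleles: list[np.ndarray] = []
    names: list[str] = []
    parents: dict[int, tuple[int, int] | None] = {}
    for f in range(spec.n_founders):
        alleles.append(rng.random((L, 2)) < p[:, None])
        names.append(f"F{f}")
        parents[f] = None
    for a, b, k in spec.matings:
        for c in range(k):
            idx = len(alleles)
            ga = alleles[a][np.arange(L), rng.integers(0, 2, L)]
            gb = alleles[b][np.arange(L), rng.integers(0, 2, L)]
            alleles.append(np.stack([ga, gb], axis=1))
            names.append(f"O{a}x{b}-{c}")
            parents[idx] = (a, b)
    codes = np.array([al.sum(axis=1) for al in alleles], dtype=float)
    m = GenotypeMatrix(names, [f"L{j:04d}" for j in range(L)], codes)

    def kin(i: int, j: int) -> str:
        pi, pj = parents[i], parents[j]
        if pi is not None and j in pi or pj is not None and i in pj:
            return "parent-offspring"
        if pi is not None and pj is not None and set(pi) == set(pj):
            return "full-sib"
        if pi is None and pj is None:
            return "unrelated"
        related = False
        anc_i = set(pi or ()) | {i}
        anc_j = set(pj or ()) | {j}
        related = bool((set(pi or ()) & set(pj or ())) or (anc_i & anc_j) - {i, j})
        return "other" if related else "unrelated"

    labels = {
        (names[i], names[j]): kin(i, j)
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return m, labels


def simulate_noninvasive_calls(
    truth: GenotypeMatrix,
    config: SynthConfig,
    locus: int = 0,
    rng=None,
) -> list[SampleCallSet]:
    """Per-method replicate calls at one variant site, with failure and dropout.

    For each sample and method the true genotype is reported except that
    the call is missing with the method's failure probability, and a true
    heterozygote is observed as either homozygote (equal odds) with
    probability ``dropout_rate``.  Homozygotes are never mis-reported.
    """
    rng = _rng(config.seed if rng is None else rng)
    code_to_call = {0: GenotypeCall.HOM_REF, 1: GenotypeCall.HET, 2: GenotypeCall.HOM_ALT}
    out = []
    for i, sid in enumerate(truth.samples):
        g = truth.codes[i, locus]
        calls: dict[str, GenotypeCall] = {}
        for method, fail in config.method_failure_rates.items():
            if np.isnan(g) or rng.random() < fail:
                calls[method] = GenotypeCall.MISSING
            elif g == 1 and rng.random() < config.dropout_rate:
                calls[method] = (
                    GenotypeCall.HOM_REF if rng.random() < 0.5 else GenotypeCall.HOM_ALT
                )
            else:
                calls[method] = code_to_call[int(g)]
        out.append(SampleCallSet(sid, calls))
    return out


def add_genotyping_noise(
    truth: GenotypeMatrix,
    dropout_rate: float,
    failure_rate: float,
    rng=None,
) -> GenotypeMatrix:
    """Matrix-level noise model: missing calls plus allelic dropout.

    Every cell independently fails (missing) with ``failure_rate``; a
    surviving heterozygote is replaced by a random homozygote with
    ``dropout_rate``.  Dropout acts only on heterozygotes.
    """
    rng = _rng(rng)
    codes = truth.codes.copy()
    fail = rng.random(codes.shape) < failure_rate
    codes[fail] = np.nan
    het = codes == 1
    drop = het & (rng.random(codes.shape) < dropout_rate)
    codes[drop] = np.where(rng.random(codes.shape) < 0.5, 0.0, 2.0)[drop]
    return GenotypeMatrix(list(truth.samples), list(truth.loci), codes, truth.populations)


def generate_recapture_dataset(
    n_individuals: int,
    recaptures: list[int],
    config: SynthConfig,
    rng=None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, int]]:
    """A noninvasive survey: individuals sampled 1+ times with noisy calls.

    Returns (true individual matrix, per-sample noisy matrix, sample ->
    true individual map).  ``recaptures`` gives the number of samples per
    individual.
    """
    if len(recaptures) != n_individuals:
        raise ValueError("recaptures must list one count per individual")
    rng = _rng(config.seed if rng is None else rng)
    truth = generate_hwe_population(config, rng=rng)
    truth = truth.subset(sample_idx=np.arange(n_individuals))
    sample_codes, sample_ids, owner = [], [], {}
    for i in range(n_individuals):
        for k in range(recaptures[i]):
            sid = f"IND{i:03d}-R{k}"
            sample_ids.append(sid)
            owner[sid] = i
            sample_codes.append(truth.codes[i])
    samples = GenotypeMatrix(sample_ids, list(truth.loci), np.array(sample_codes))
    mean_fail = float(np.mean(list(config.method_failure_rates.values())))
    noisy = add_genotyping_noise(samples, config.dropout_rate, mean_fail, rng=rng)
    return truth, noisy, owner


def generate_ibd_landscape(
    n_pops: int,
    coords: np.ndarray | None,
    decay: float,
    n_per_pop: int = 20,
    n_loci: int = 50,
    sigma: float = 1.0,
    ancestral_freq_range: tuple[float, float] = (0.2, 0.8),
    seed=None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Spatially structured populations with isolation by distance.

    Population allele frequencies deviate from a common ancestral
    frequency by correlated Gaussian deviates on the logit scale, with
    correlation exp(-d/decay) between populations at distance d; genotypes
    are drawn under HWE within populations.  Returns the labelled genotype
    matrix and the pairwise geographic distance matrix.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    rng = _rng(seed)
    if coords is None:
        coords = rng.uniform(0, 100, size=(n_pops, 2))
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != n_pops:
        raise ValueError("coords must give one point per population")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = sigma**2 * np.exp(-d / decay)
    # jitter for numerical positive-definiteness
    cov = cov + 1e-9 * np.eye(n_pops)
    chol = np.linalg.cholesky(cov)
    lo, hi = ancestral_freq_range
    anc = rng.uniform(lo, hi, size=n_loci)
    z = np.log(anc / (1 - anc))[None, :] + chol @ rng.standard_normal((n_pops, n_loci))
    freqs = 1 / (1 + np.exp(-z))
    codes = np.concatenate(
        [rng.binomial(2, freqs[k][None, :], size=(n_per_pop, n_loci)) for k in range(n_pops)]
    ).astype(float)
    samples = [f"P{k}-S{i}" for k in range(n_pops) for i in range(n_per_pop)]
    pops = np.array([f"P{k}" for k in range(n_pops) for _ in range(n_per_pop)], dtype=object)
    m = GenotypeMatrix(samples, [f"L{j:04d}" for j in range(n_loci)], codes, pops)
    return m, d
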