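"""Biallelic SNP genotype matrices and their plain-text interchange formats.

The central container is :class:`GenotypeMatrix`: samples x loci, each cell
holding the count of the alternate allele (0, 1, 2) or NaN for a missing
call, with an optional population label per sample.  TSV is the interchange
format between pipeline stages; a minimal VCF reader (GT field only,
biallelic records) is provided for data arriving from variant callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

_VALID_CODES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of alternate-allele counts.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers (rows).
    loci : list of str
        Unique locus identifiers (columns).
    codes : ndarray of float, shape (n_samples, n_loci)
        0 = hom ref, 1 = het, 2 = hom alt, NaN = missing call.
    populations : ndarray of str, optional
        Population label per sample.
    """

    samples: list[str]
    loci: list[str]
    codes: np.ndarray
    populations: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus ids must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        valid = np.isnan(self.codes) | np.isin(self.codes, _VALID_CODES)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]!r} for sample "
                f"{self.samples[i]!r} at locus {self.loci[j]!r}"
            )
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
            if self.populations.shape != (len(self.samples),):
                raise ValueError("populations must give one label per sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return ~np.isnan(self.codes)

    def allele_freqs(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over called genotypes (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def sample_missing_counts(self) -> np.ndarray:
        return np.isnan(self.codes).sum(axis=1)

    def locus_missingness(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    def subset(
        self,
        sample_idx: np.ndarray | list[int] | None = None,
        locus_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        si = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=int)
        )
        li = (
            np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx, dtype=int)
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            codes=self.codes[np.ix_(si, li)],
            populations=None if self.populations is None else self.populations[si],
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Write rows=samples, columns=loci, codes 0/1/2/NA, optional population column."""
        df = pd.DataFrame(self.codes, index=self.samples, columns=self.loci)
        if self.populations is not None:
            df.insert(0, "population", self.populations)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(
            path, sep="\t", index_col="sample_id", na_values=["NA"], comment="#"
        )
        pops = None
        if "population" in df.columns:
            pops = df.pop("population").to_numpy(dtype=object)
        return cls(
            samples=[str(s) for s in df.index],
            loci=[str(c) for c in df.columns],
            codes=df.to_numpy(dtype=float),
            populations=pops,
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Minimal VCF import: biallelic records, GT field only, ./. as missing."""
        from cyvcf2 import VCF  # optional dependency, imported lazily

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        loci: list[str] = []
        rows: list[np.ndarray] = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue
            name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
            loci.append(name)
            g = rec.gt_types.astype(float)  # 0/1/2, 3 = unknown with gts012
            g[g == 3] = np.nan
            rows.append(g)
        codes = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
        return cls(samples=samples, loci=loci, codes=codes)


def write_distance_matrix(d: np.ndarray, ids: list[str], path) -> None:
    pd.DataFrame(d, index=ids, columns=ids).to_csv(path, sep="\t", index_label="id")


def read_distance_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="id", comment="#")
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
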