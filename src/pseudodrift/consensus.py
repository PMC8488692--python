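"""Consensus genotyping for noisy multi-method replicate calls.

Noninvasive samples (feces, shed hair, saliva) yield low-quality DNA, so a
single genotyping assay is unreliable: allelic dropout turns heterozygotes
into false homozygotes and assays frequently fail outright.  The remedy is
redundancy — genotype every sample with up to three independent methods
(Sanger sequencing, amplicon NGS, allele-specific PCR), re-run AS-PCR in
triplicate when the methods disagree (the multiple-tubes rule), and finally
reconcile recaptures of the same individual by majority.

The rules implemented here:

* ``sample_consensus`` — unanimous non-missing method calls win; a
  disagreement is resolved only by a unanimous AS-PCR triplicate, otherwise
  the sample call is missing and flagged.
* ``individual_genotype`` — the modal non-missing consensus over an
  individual's recaptures; ties are conservatively reported missing.
* ``allele_frequency`` — allele counting over final individual genotypes.
* ``hwe_predicted_frequency`` — sqrt(q) prediction of a recessive-allele
  frequency from phenotype census counts under Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

METHODS = ("sanger", "ngs", "aspcr")


class GenotypeCall(enum.Enum):
    """Genotype at a biallelic site; ``m`` denotes the mutant allele."""

    HOM_REF = "+/+"
    HET = "+/m"
    HOM_ALT = "m/m"
    MISSING = "x/x"

    @property
    def alt_count(self) -> int | None:
        return {"+/+": 0, "+/m": 1, "m/m": 2, "x/x": None}[self.value]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CALL_ALIASES = {
    "+/+": GenotypeCall.HOM_REF,
    "+/m": GenotypeCall.HET,
    "m/+": GenotypeCall.HET,
    "m/m": GenotypeCall.HOM_ALT,
    "x/x": GenotypeCall.MISSING,
    "": GenotypeCall.MISSING,
    "na": GenotypeCall.MISSING,
}


def parse_call(value, *, sample: str = "?", method: str = "?") -> GenotypeCall:
    """Parse a genotype string; case-insensitive, ``m/+`` normalizes to HET.

    Emphasis markers (``*``) and surrounding whitespace are stripped so that
    strings copied from formatted tables parse cleanly.
    """
    if isinstance(value, GenotypeCall):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return GenotypeCall.MISSING
    key = str(value).strip().strip("*").replace(" ", "").lower()
    try:
        return _CALL_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown genotype {value!r} for sample {sample!r}, method {method!r}"
        ) from None


@dataclass
class SampleCallSet:
    """Per-method genotype calls for one noninvasive sample.

    ``replicates`` holds AS-PCR replicate calls (multiple-tubes rule), used
    only when the primary methods disagree.
    """

    sample_id: str
    calls: dict[str, GenotypeCall]
    replicates: list[GenotypeCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = {
            m: parse_call(c, sample=self.sample_id, method=m)
            for m, c in self.calls.items()
        }
        self.replicates = [
            parse_call(c, sample=self.sample_id, method="aspcr-replicate")
            for c in self.replicates
        ]
        if not self.calls:
            raise ValueError(f"sample {self.sample_id!r}: no method was attempted")


@dataclass
class ConsensusRecord:
    sample_id: str
    consensus: GenotypeCall
    support: int
    flagged_conflict: bool


def sample_consensus(callset: SampleCallSet) -> ConsensusRecord:
    """Reduce one sample's method calls to a consensus genotype.

    Unanimity among non-missing method calls wins.  A disagreement falls
    back on the AS-PCR triplicate: exactly three unanimous non-missing
    replicates resolve it (flagged); anything else is reported missing and
    flagged.  All-missing input is missing, unflagged.
    """
    present = [c for c in callset.calls.values() if c is not GenotypeCall.MISSING]
    if not present:
        return ConsensusRecord(callset.sample_id, GenotypeCall.MISSING, 0, False)
    distinct = set(present)
    if len(distinct) == 1:
        return ConsensusRecord(callset.sample_id, present[0], len(present), False)
    reps = [c for c in callset.replicates if c is not GenotypeCall.MISSING]
    if len(callset.replicates) == 3 and len(reps) == 3 and len(set(reps)) == 1:
        resolved = reps[0]
        support = max(1, sum(c is resolved for c in present))
        return ConsensusRecord(callset.sample_id, resolved, support, True)
    return ConsensusRecord(callset.sample_id, GenotypeCall.MISSING, 0, True)


def individual_genotype(members: list[ConsensusRecord]) -> GenotypeCall:
    """Modal non-missing consensus across an individual's recaptures.

    A tie between modal genotypes is reported missing (no tie occurs in the
    study data; missing is the conservative resolution).
    """
    if not members:
        raise ValueError("individual has no member samples")
    counts = Counter(
        r.consensus for r in members if r.consensus is not GenotypeCall.MISSING
    )
    if not counts:
        return GenotypeCall.MISSING
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return GenotypeCall.MISSING
    return ranked[0][0]


def allele_frequency(genotypes: list[GenotypeCall]) -> tuple[float, dict[str, int]]:
    """Mutant-allele frequency and genotype counts over non-missing genotypes."""
    counts = Counter(g for g in genotypes if g is not GenotypeCall.MISSING)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all genotypes are missing")
    alt = counts[GenotypeCall.HET] + 2 * counts[GenotypeCall.HOM_ALT]
    tallies = {
        "hom_ref": counts[GenotypeCall.HOM_REF],
        "het": counts[GenotypeCall.HET],
        "hom_alt": counts[GenotypeCall.HOM_ALT],
    }
    return alt / (2 * n), tallies


def hwe_predicted_frequency(n_recessive_phenotype: int, n_total: int) -> float:
    """Recessive-allele frequency sqrt(n_recessive/n_total) predicted from census counts."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_recessive_phenotype <= n_total:
        raise ValueError("recessive count must lie in [0, n_total]")
    return float((n_recessive_phenotype / n_total) ** 0.5)


# ------------------------------------------------------------- TSV interface


def read_callsets(path) -> tuple[list[SampleCallSet], dict[str, list[str]]]:
    """Read a long-format call table.

    Columns: ``individual`` (optional grouping), ``sample_id``, ``method``,
    ``call``, ``replicate_index`` (0 or empty for the primary call of a
    method, 1..3 for AS-PCR replicates).  Returns the call sets in file
    order and the individual -> sample ids grouping (empty if no column).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "method", "call"}
    if not required.issubset(df.columns):
        raise ValueError(f"call table must have columns {sorted(required)}")
    if "replicate_index" not in df.columns:
        df["replicate_index"] = ""
    callsets: dict[str, SampleCallSet] = {}
    grouping: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        cs = callsets.get(sid)
        if cs is None:
            cs = callsets[sid] = SampleCallSet(sid, calls={"aspcr": "x/x"})
            cs.calls = {}
        method = row["method"].strip().lower()
        if method not in METHODS:
            raise ValueError(f"unknown method {row['method']!r} for sample {sid!r}")
        call = parse_call(row["call"], sample=sid, method=method)
        rep = str(row["replicate_index"]).strip()
        if rep not in ("", "0"):
            cs.replicates.append(call)
        else:
            cs.calls[method] = call
        if "individual" in df.columns and row["individual"]:
            grouping.setdefault(row["individual"], [])
            if sid not in grouping[row["individual"]]:
                grouping[row["individual"]].append(sid)
    for cs in callsets.values():
        if not cs.calls:
            raise ValueError(f"sample {cs.sample_id!r}: no primary method call")
    return list(callsets.values()), grouping


def similipal_calls_path():
    """Path to the packaged Similipal variant-site call table."""
    return resources.files("pseudodrift") / "data" / "similipal_taqpep_calls.tsv"


def consensus_pipeline(
    callsets: list[SampleCallSet], grouping: dict[str, list[str]]
) -> tuple[dict[str, ConsensusRecord], dict[str, GenotypeCall]]:
    """Run sample consensus then per-individual final genotypes."""
    records = {cs.sample_id: sample_consensus(cs) for cs in callsets}
    individuals = {
        ind: individual_genotype([records[s] for s in sids])
        for ind, sids in grouping.items()
    }
    return records, individuals
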