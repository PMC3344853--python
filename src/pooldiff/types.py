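"""Shared domain containers for the pooled SNP discovery pipeline.

Coordinates are 1-based inclusive throughout (pileup / VCF convention).
Pools are always identified by the strings ``"fast"`` and ``"slow"``:
the fast-growth pool is the numerator of the allelic-imbalance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
POOLS = ("fast", "slow")

#: Missing-genotype token used in every on-disk TSV.
MISSING = "NA"


class PooldiffError(Exception):
    """Base class for pipeline errors."""


class ParseError(PooldiffError):
    """A malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class UndefinedFrequencyError(PooldiffError):
    """Allele frequency requested where no usable reads/calls exist."""


class UndefinedScoreError(PooldiffError):
    """Imbalance score requested for a site with no variant signal."""


class DegenerateDesignError(PooldiffError):
    """Regression requested on a constant predictor."""


@dataclass(frozen=True)
class PoolEvidence:
    """Read evidence for one pool at one site."""

    depth: int
    counts: dict[str, int]
    meanq: dict[str, float]

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if sum(self.counts.values()) > self.depth:
            raise ValueError("sum of base counts exceeds depth")
        for base, n in self.counts.items():
            if n > 0 and self.meanq.get(base, -1.0) < 0:
                raise ValueError(f"base {base} has count>0 but no mean quality")

    @property
    def usable(self) -> int:
        """Reads assigned to one of A/C/G/T (N and indel reads excluded)."""
        return sum(self.counts.values())


@dataclass(frozen=True)
class SiteEvidence:
    """Per-site read counts and mean base qualities for both pools."""

    contig: str
    pos: int  # 1-based
    ref: str
    fast: PoolEvidence
    slow: PoolEvidence

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref not in BASES:
            raise ValueError(f"ref allele must be one of {BASES}, got {self.ref!r}")

    def pool(self, name: str) -> PoolEvidence:
        if name == "fast":
            return self.fast
        if name == "slow":
            return self.slow
        raise KeyError(name)

    @property
    def site_id(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass
class ImbalanceRecord:
    """A detected variant with pool frequencies and its imbalance class."""

    site: SiteEvidence
    variant_allele: str
    f_fast: float
    f_slow: float
    score: float  # f_fast / f_slow; may be +inf
    klass: str  # amplification | LOH | balanced
    stage_flags: set = field(default_factory=set)

    @property
    def site_id(self) -> str:
        return self.site.site_id


@dataclass
class FunnelReport:
    """Staged counts of the discovery funnel; weakly decreasing."""

    sites_examined: int = 0
    putative_snps: int = 0
    post_paralog_filter: int = 0
    imbalance_classified: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "sites_examined": self.sites_examined,
            "putative_snps": self.putative_snps,
            "post_paralog_filter": self.post_paralog_filter,
            "imbalance_classified": self.imbalance_classified,
        }


@dataclass
class MarkerInfo:
    """Metadata for one marker column of a genotype matrix."""

    marker_id: str
    a1: str
    a2: str
    genome: str = "nuclear"  # nuclear | mito

    def __post_init__(self):
        if self.genome not in ("nuclear", "mito"):
            raise ValueError(f"genome must be nuclear or mito, got {self.genome!r}")


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage calls (count of the A2 allele).

    ``calls`` is a float DataFrame indexed by sample id with marker-id
    columns; entries are 0.0/1.0/2.0 or NaN for missing.  Mitochondrial
    markers are haploid and must not carry het (1.0) calls after QC.
    """

    calls: pd.DataFrame
    markers: dict[str, MarkerInfo]

    def __post_init__(self):
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.calls.columns.duplicated().any():
            raise ValueError("duplicate marker ids")
        missing_meta = set(self.calls.columns) - set(self.markers)
        if missing_meta:
            raise ValueError(f"markers without metadata: {sorted(missing_meta)}")
        bad = ~(self.calls.isin([0.0, 1.0, 2.0]) | self.calls.isna())
        if bad.any().any():
            raise ValueError("dosage codes must be 0, 1, 2 or missing")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def mito_het_flags(self) -> list[tuple[str, str]]:
        """(sample, marker) pairs where a mito marker carries a het call."""
        flags = []
        for mid, info in self.markers.items():
            if info.genome != "mito" or mid not in self.calls.columns:
                continue
            het = self.calls.index[self.calls[mid] == 1.0]
            flags.extend((s, mid) for s in het)
        return flags

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        marker_ids = list(marker_ids)
        return GenotypeMatrix(
            calls=self.calls[marker_ids].copy(),
            markers={m: self.markers[m] for m in marker_ids},
        )


@dataclass
class PedigreeEntry:
    sample: str
    sire: Optional[str]
    dam: Optional[str]
    family: str
    generation: str = ""


@dataclass
class Pedigree:
    """Family structure: sample -> (sire, dam, family, generation)."""

    entries: dict[str, PedigreeEntry]

    def __post_init__(self):
        for sample, e in self.entries.items():
            if sample in (e.sire, e.dam):
                raise ValueError(f"sample {sample} is listed as its own parent")
        # no sample may be its own ancestor
        for sample in self.entries:
            seen = set()
            stack = [sample]
            while stack:
                cur = stack.pop()
                e = self.entries.get(cur)
                if e is None:
                    continue
                for parent in (e.sire, e.dam):
                    if parent is None:
                        continue
                    if parent == sample:
                        raise ValueError(f"sample {sample} is its own ancestor")
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)

    def families(self) -> dict[str, list[str]]:
        """family id -> offspring sample ids (samples with a family label)."""
        fams: dict[str, list[str]] = {}
        for sample, e in self.entries.items():
            if e.family:
                fams.setdefault(e.family, []).append(sample)
        return {f: sorted(v) for f, v in sorted(fams.items())}


@dataclass
class PhenotypeTable:
    """Body weights (grams) at evaluation times plus optional covariates.

    ``weights`` columns are named ``bw_<days>`` with strictly increasing
    day values; all weights are positive.
    """

    weights: pd.DataFrame  # samples x bw_<days>
    covariates: pd.DataFrame  # samples x covariate columns (may be empty)
    times: list[int]  # days post-hatch, strictly increasing

    def __post_init__(self):
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("evaluation times must be strictly increasing")
        w = self.weights.to_numpy(dtype=float)
        if np.any(w[~np.isnan(w)] <= 0):
            raise ValueError("body weights must be positive")


@dataclass
class AssociationResult:
    """Marker- or haplotype-trait regression summary."""

    marker: str
    trait: str
    n: int
    slope: float
    t: float
    p_asymptotic: float
    r2: float
    p_empirical: Optional[float] = None
    n_permutations: Optional[int] = None
    degenerate_se: bool = False


@dataclass
class HaplotypeTable:
    """Distinct mitochondrial haplotypes with frequencies and assignments."""

    marker_order: list[str]
    haplotypes: list[str]  # allele strings, one char per marker
    frequencies: list[float]
    assignments: dict[str, Optional[str]]  # sample -> haplotype string or None

    def __post_init__(self):
        for h in self.haplotypes:
            if len(h) != len(self.marker_order):
                raise ValueError("haplotype length must equal number of markers")
        if self.frequencies and abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
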