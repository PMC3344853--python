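"""Per-pool variant detection, pooled allele frequencies and allelic
imbalance scoring — the discovery funnel for two contrasted pools.

The funnel mirrors a pooled low-coverage RNA-Seq screen of a fast-growth
versus a slow-growth pool:

1. at every site, look for a variant in each pool under a three-part
   stringency rule (supporting reads, supporting fraction, base quality);
2. estimate the variant-allele frequency in each pool by counting reads;
3. score the allelic imbalance as the ratio fast/slow of those
   frequencies and classify it (amplification / loss of heterozygosity /
   balanced);
4. remove sites that look like collapsed paralogs rather than true SNPs.

Thresholds live in :class:`StringencyConfig`; the defaults are the
published stringency (>=4 variant reads, >20% variant fraction, mean
base quality >20; imbalance >5.0 amplification, <0.2 LOH).  All
inequalities except the read-count floor are strict.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

from .types import (
    BASES,
    FunnelReport,
    ImbalanceRecord,
    SiteEvidence,
    UndefinedFrequencyError,
    UndefinedScoreError,
)


@dataclass(frozen=True)
class StringencyConfig:
    """Detection and imbalance thresholds.

    Attributes
    ----------
    min_variant_reads : int
        Minimum reads calling the variant (inclusive: "at least 4").
    min_variant_fraction : float
        Variant reads / depth must strictly exceed this (">20%").
    min_quality : float
        Aggregated Phred base quality of variant-supporting reads must
        strictly exceed this (">20").
    quality_agg : str
        How per-read qualities are aggregated: ``"mean"`` (default) or
        ``"min"``.  Site evidence stores the per-base mean, so ``min``
        only differs when the caller supplies min-aggregated evidence.
    amp_threshold, loh_threshold : float
        Imbalance classification cut-offs (strict: score >5.0 is an
        amplification, <0.2 loss of heterozygosity).
    paralog_fraction_window : (float, float)
        Variant-fraction band in both pools that, combined with excess
        depth, marks a collapsed-paralog suspect.
    paralog_depth_multiplier : float
        Depth must exceed this multiple of the median site depth for
        paralog rule (b).
    require_both_pools : bool
        If True a putative SNP must pass detection in both pools rather
        than at least one.
    """

    min_variant_reads: int = 4
    min_variant_fraction: float = 0.20
    min_quality: float = 20.0
    quality_agg: str = "mean"
    amp_threshold: float = 5.0
    loh_threshold: float = 0.2
    paralog_fraction_window: tuple[float, float] = (0.3, 0.7)
    paralog_depth_multiplier: float = 3.0
    require_both_pools: bool = False

    def __post_init__(self):
        if not 0 < self.min_variant_fraction < 1:
            raise ValueError("min_variant_fraction must be in (0, 1)")
        if not self.loh_threshold < 1 < self.amp_threshold:
            raise ValueError("need loh_threshold < 1 < amp_threshold")
        if self.quality_agg not in ("mean", "min"):
            raise ValueError("quality_agg must be 'mean' or 'min'")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["paralog_fraction_window"] = list(self.paralog_fraction_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StringencyConfig":
        d = dict(d)
        if "paralog_fraction_window" in d:
            d["paralog_fraction_window"] = tuple(d["paralog_fraction_window"])
        return cls(**d)


def detect_variant(
    site: SiteEvidence, pool: str, cfg: StringencyConfig = StringencyConfig()
) -> tuple[bool, Optional[str]]:
    """Apply the three-part stringency rule to one pool at one site.

    The candidate variant allele is the non-reference base with the most
    reads in that pool (ties broken alphabetically).  It passes iff

    * supporting reads >= ``min_variant_reads``,
    * supporting reads / depth  > ``min_variant_fraction``, and
    * aggregated base quality   > ``min_quality``.

    Returns ``(passed, variant_allele)``; a pool with no coverage or no
    non-reference base returns ``(False, None)`` rather than raising.
    """
    ev = site.pool(pool)
    if ev.depth == 0:
        return False, None  # no_coverage
    candidates = [
        (b, ev.counts.get(b, 0)) for b in BASES if b != site.ref and ev.counts.get(b, 0) > 0
    ]
    if not candidates:
        return False, None
    # highest count wins; alphabetical tie-break is given by BASES order
    allele, count = max(candidates, key=lambda bc: (bc[1], -ord(bc[0])))
    quality = ev.meanq[allele]
    passed = (
        count >= cfg.min_variant_reads
        and count / ev.depth > cfg.min_variant_fraction
        and quality > cfg.min_quality
    )
    return passed, allele


def pool_allele_frequency(site: SiteEvidence, allele: str, pool: str) -> float:
    """Variant-allele frequency in one pool by counting reads.

    Frequency = reads carrying ``allele`` / usable A,C,G,T reads.
    Raises :class:`UndefinedFrequencyError` when the pool has no usable
    reads.
    """
    ev = site.pool(pool)
    total = sum(ev.counts.get(b, 0) for b in BASES)
    if total == 0:
        raise UndefinedFrequencyError(
            f"no usable reads for pool {pool!r} at {site.site_id}"
        )
    return ev.counts.get(allele, 0) / total


def imbalance_score(f_fast: float, f_slow: float) -> float:
    """Allelic-imbalance score: f_fast / f_slow.

    Returns +inf when the slow pool frequency is zero and the fast pool
    frequency is positive (the strongest possible amplification).  Both
    zero is undefined — the site carries no variant.
    """
    for name, f in (("f_fast", f_fast), ("f_slow", f_slow)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name}={f} outside [0, 1]")
    if f_fast == 0.0 and f_slow == 0.0:
        raise UndefinedScoreError("both pool frequencies are zero")
    if f_slow == 0.0:
        return math.inf
    return f_fast / f_slow


def classify_imbalance(score: float, cfg: StringencyConfig = StringencyConfig()) -> str:
    """Classify a score: amplification (> amp), LOH (< loh), else balanced.

    Boundaries are excluded: a score of exactly 5.0 or exactly 0.2 is
    balanced.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    if score > cfg.amp_threshold:
        return "amplification"
    if score < cfg.loh_threshold:
        return "LOH"
    return "balanced"


def _site_depth(rec: ImbalanceRecord) -> int:
    return rec.site.fast.depth + rec.site.slow.depth


def paralog_filter(
    records: Sequence[ImbalanceRecord],
    dh_het_sites: Optional[Iterable[str]] = None,
    median_depth: Optional[float] = None,
    cfg: StringencyConfig = StringencyConfig(),
) -> tuple[list[ImbalanceRecord], list[ImbalanceRecord]]:
    """Flag records that look like collapsed paralogs.

    A record is flagged when

    (a) its site id appears in ``dh_het_sites`` — self-variants of the
        doubled-haploid reference individual, which being fully
        homozygous can only show heterozygosity through paralog
        collapse; or
    (b) both pools carry the variant at a fraction inside
        ``paralog_fraction_window`` (default [0.3, 0.7], the signature
        of a fixed difference between two collapsed loci) AND the
        combined site depth exceeds ``paralog_depth_multiplier`` times
        the median site depth.

    Returns (kept, flagged); flagged records get the ``paralog_suspect``
    stage flag so they can be written to a side file.
    """
    dh = set(dh_het_sites or ())
    if median_depth is None:
        depths = [_site_depth(r) for r in records]
        median_depth = statistics.median(depths) if depths else 0.0
    lo, hi = cfg.paralog_fraction_window
    kept, flagged = [], []
    for rec in records:
        suspect = rec.site_id in dh
        if not suspect:
            in_window = lo <= rec.f_fast <= hi and lo <= rec.f_slow <= hi
            deep = _site_depth(rec) > cfg.paralog_depth_multiplier * median_depth
            suspect = in_window and deep
        if suspect:
            rec.stage_flags.add("paralog_suspect")
            flagged.append(rec)
        else:
            kept.append(rec)
    return kept, flagged


def discover(
    evidence: Iterable[SiteEvidence],
    cfg: StringencyConfig = StringencyConfig(),
    dh_het_sites: Optional[Iterable[str]] = None,
) -> tuple[list[ImbalanceRecord], FunnelReport, list[ImbalanceRecord]]:
    """Run the staged discovery funnel over sorted site evidence.

    For each site, variants are detected in both pools; a site is a
    putative SNP when detection passes in at least one pool (both, when
    ``cfg.require_both_pools``).  The variant allele is the detected
    allele; if both pools pass on different alleles the site is excluded
    with the ``discordant_allele`` flag.  Pool frequencies, the
    imbalance score and its class are then computed and the paralog
    filter applied.

    Returns ``(records, funnel, flagged)`` where ``records`` are the
    retained classified variants, ``funnel`` carries the staged counts
    and ``flagged`` the paralog suspects (side-file material).

    Raises ``ValueError`` if the evidence is not sorted by (contig, pos).
    """
    records: list[ImbalanceRecord] = []
    funnel = FunnelReport()
    last_key = None
    for site in evidence:
        key = (site.contig, site.pos)
        if last_key is not None and key <= last_key:
            raise ValueError(f"evidence not sorted by (contig, pos) at {key}")
        last_key = key
        funnel.sites_examined += 1

        pass_fast, allele_fast = detect_variant(site, "fast", cfg)
        pass_slow, allele_slow = detect_variant(site, "slow", cfg)
        if cfg.require_both_pools:
            is_putative = pass_fast and pass_slow
        else:
            is_putative = pass_fast or pass_slow
        if not is_putative:
            continue
        funnel.putative_snps += 1

        if pass_fast and pass_slow and allele_fast != allele_slow:
            # pools disagree on the top variant allele: exclude
            continue
        allele = allele_fast if pass_fast else allele_slow
        flags = set()
        if pass_fast:
            flags.add("detected_fast")
        if pass_slow:
            flags.add("detected_slow")

        try:
            f_fast = pool_allele_frequency(site, allele, "fast")
            f_slow = pool_allele_frequency(site, allele, "slow")
            score = imbalance_score(f_fast, f_slow)
        except (UndefinedFrequencyError, UndefinedScoreError):
            # the contrasting pool has no usable reads: cannot score
            continue
        records.append(
            ImbalanceRecord(
                site=site,
                variant_allele=allele,
                f_fast=f_fast,
                f_slow=f_slow,
                score=score,
                klass=classify_imbalance(score, cfg),
                stage_flags=flags,
            )
        )

    kept, flagged = paralog_filter(records, dh_het_sites=dh_het_sites, cfg=cfg)
    funnel.post_paralog_filter = len(kept)
    funnel.imbalance_classified = sum(
        1 for r in kept if r.klass in ("amplification", "LOH")
    )
    return kept, funnel, flagged
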