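"""Marker-level population-genetic statistics: QC, minor allele
frequency, the exact Hardy-Weinberg test, Mendelian-inheritance checks
and per-population polymorphism summaries.

The Hardy-Weinberg test is the biallelic conditional exact test: given
the observed allele totals, every possible heterozygote count is
enumerated, each table's probability under random union of gametes is
computed, and the P-value sums the probabilities of all tables as or
less probable than the observed one.  A Monte Carlo mode permutes the
allele vector instead and reports an empirical P, mirroring
simulation-based exact tests; markers that fail HWE are reported, never
auto-dropped (deviation may reflect directional selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, Pedigree, UndefinedFrequencyError


@dataclass
class MarkerSummary:
    marker: str
    completion: float
    n_called: int
    maf: float
    hwe_p: Optional[float]
    polymorphic: bool


def completion_rate(calls: pd.Series) -> float:
    """Fraction of samples with a non-missing call."""
    return float(calls.notna().mean())


def minor_allele_frequency(calls: pd.Series) -> float:
    """MAF from dosage calls: min(f, 1-f); exactly 0.5 on a tie."""
    called = calls.dropna()
    if called.empty:
        raise UndefinedFrequencyError("no called genotypes")
    f = float(called.sum()) / (2 * len(called))
    return min(f, 1.0 - f)


def is_monomorphic(calls: pd.Series) -> bool:
    called = calls.dropna()
    return called.empty or called.nunique() == 1 and called.iloc[0] in (0.0, 2.0)


def qc_filter(
    gm: GenotypeMatrix, min_completion: float = 0.70
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Drop markers with completion < ``min_completion`` or monomorphic calls.

    Returns the filtered matrix and {marker: reason} for dropped markers.
    Idempotent: filtering a filtered matrix drops nothing further.
    """
    if gm.calls.empty:
        raise ValueError("empty genotype matrix")
    dropped: dict[str, str] = {}
    kept = []
    for mid in gm.marker_ids:
        col = gm.calls[mid]
        if completion_rate(col) < min_completion:
            dropped[mid] = "low_completion"
        elif is_monomorphic(col):
            dropped[mid] = "monomorphic"
        else:
            kept.append(mid)
    return gm.subset_markers(kept), dropped


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg
# ---------------------------------------------------------------------------


def _log_table_prob(n_aa_major: int, n_het: int, n_aa_minor: int) -> float:
    """Log probability of a genotype table conditional on allele counts."""
    n = n_aa_major + n_het + n_aa_minor
    n_a = 2 * n_aa_major + n_het
    n_b = 2 * n_aa_minor + n_het
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_aa_major + 1)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_aa_minor + 1)
        + n_het * math.log(2.0)
        + math.lgamma(n_a + 1)
        + math.lgamma(n_b + 1)
        - math.lgamma(2 * n + 1)
    )


def hwe_exact(
    n_aa: int,
    n_ab: int,
    n_bb: int,
    mode: str = "exact",
    k: int = 20_000,
    seed: Optional[int] = None,
) -> float:
    """Exact (or Monte Carlo) Hardy-Weinberg P for a biallelic marker.

    Parameters
    ----------
    n_aa, n_ab, n_bb : genotype counts (hom, het, hom).
    mode : ``"exact"`` enumerates every heterozygote count compatible
        with the observed allele totals and sums the probabilities of
        tables as or less probable than the observed one; ``"mc"``
        permutes the allele vector ``k`` times and reports the
        add-one empirical P.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    obs_het = n_ab
    if rare == 0:
        return 1.0  # monomorphic: single possible table

    if mode == "exact":
        obs_lp = _log_table_prob(n_aa, n_ab, n_bb)
        p = 0.0
        # het count shares the parity of the rare-allele total
        for het in range(rare % 2, rare + 1, 2):
            hom_rare = (rare - het) // 2
            hom_common = n - het - hom_rare
            lp = _log_table_prob(hom_common, het, hom_rare)
            if lp <= obs_lp + 1e-12:
                p += math.exp(lp)
        return min(p, 1.0)

    if mode == "mc":
        rng = np.random.default_rng(seed)
        alleles = np.concatenate([np.zeros(n_a, dtype=np.int8), np.ones(n_b, dtype=np.int8)])
        obs_lp = _log_table_prob(n_aa, n_ab, n_bb)
        hits = 0
        for _ in range(k):
            rng.shuffle(alleles)
            pairs = alleles.reshape(n, 2)
            het = int((pairs[:, 0] != pairs[:, 1]).sum())
            hom_b = int((pairs.sum(axis=1) == 2).sum())
            hom_a = n - het - hom_b
            if _log_table_prob(hom_a, het, hom_b) <= obs_lp + 1e-12:
                hits += 1
        return (hits + 1) / (k + 1)

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

_GAMETES = {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}


def mendelian_check(
    gm: GenotypeMatrix, ped: Pedigree, check_mito: bool = False
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """Check offspring genotypes against their parents.

    Nuclear markers: the offspring dosage must be producible from one
    gamete of each genotyped parent.  Mitochondrial markers (optional):
    the offspring allele must equal the dam's (maternal inheritance).

    Returns ``(violations, skipped)`` where violations are
    (offspring, marker, kind) and skipped are (offspring, marker) trios
    with a missing parental genotype.
    """
    violations: list[tuple[str, str, str]] = []
    skipped: list[tuple[str, str]] = []
    calls = gm.calls
    for sample, entry in ped.entries.items():
        if sample not in calls.index:
            continue
        for mid in gm.marker_ids:
            info = gm.markers[mid]
            off = calls.at[sample, mid]
            if pd.isna(off):
                continue
            if info.genome == "mito":
                if not check_mito:
                    continue
                dam = entry.dam
                if dam is None or dam not in calls.index:
                    continue
                dam_g = calls.at[dam, mid]
                if pd.isna(dam_g):
                    skipped.append((sample, mid))
                    continue
                if off != dam_g:
                    violations.append((sample, mid, "maternal_mismatch"))
                continue
            sire, dam = entry.sire, entry.dam
            if sire is None or dam is None:
                continue
            if sire not in calls.index or dam not in calls.index:
                continue
            sire_g = calls.at[sire, mid]
            dam_g = calls.at[dam, mid]
            if pd.isna(sire_g) or pd.isna(dam_g):
                skipped.append((sample, mid))
                continue
            possible = {a + b for a in _GAMETES[sire_g] for b in _GAMETES[dam_g]}
            if off not in possible:
                violations.append((sample, mid, "impossible_genotype"))
    return violations, skipped


# ---------------------------------------------------------------------------
# polymorphism summary
# ---------------------------------------------------------------------------


def polymorphism_summary(
    gm: GenotypeMatrix, populations: dict[str, str]
) -> pd.DataFrame:
    """Per-population polymorphism: marker counts, mean MAF, minor allele.

    ``populations`` maps sample id -> population label; every genotyped
    sample must be labelled.  The per-marker minor allele identity is
    reported so that minor-allele flips between populations can be
    flagged (``flipped_vs`` lists populations disagreeing with the
    first population's minor allele for that marker).
    """
    unlabeled = set(gm.samples) - set(populations)
    if unlabeled:
        raise ValueError(f"unlabeled samples: {sorted(unlabeled)[:5]}")
    pops = sorted(set(populations.values()))
    rows = []
    minor_ids: dict[str, dict[str, Optional[str]]] = {}
    for pop in pops:
        members = [s for s in gm.samples if populations[s] == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no samples")
        sub = gm.calls.loc[members]
        mafs = []
        minor_ids[pop] = {}
        n_poly = 0
        for mid in gm.marker_ids:
            col = sub[mid].dropna()
            info = gm.markers[mid]
            if col.empty:
                minor_ids[pop][mid] = None
                continue
            f2 = float(col.sum()) / (2 * len(col))  # frequency of A2
            maf = min(f2, 1.0 - f2)
            if maf > 0:
                n_poly += 1
                mafs.append(maf)
                minor_ids[pop][mid] = info.a2 if f2 <= 0.5 else info.a1
            else:
                minor_ids[pop][mid] = None
        rows.append(
            {
                "population": pop,
                "n_samples": len(members),
                "n_polymorphic": n_poly,
                "mean_maf": float(np.mean(mafs)) if mafs else 0.0,
            }
        )
    summary = pd.DataFrame(rows)

    flips = []
    for mid in gm.marker_ids:
        seen = {p: minor_ids[p][mid] for p in pops if minor_ids[p][mid] is not None}
        alleles = set(seen.values())
        if len(alleles) > 1:
            flips.append({"marker": mid, "minor_by_population": seen})
    summary.attrs["minor_allele_flips"] = flips
    return summary


def marker_summaries(
    gm: GenotypeMatrix, hwe_seed: Optional[int] = None
) -> list[MarkerSummary]:
    """Convenience: per-marker completion, MAF and exact HWE P."""
    out = []
    for mid in gm.marker_ids:
        col = gm.calls[mid]
        called = col.dropna()
        if called.empty:
            out.append(MarkerSummary(mid, 0.0, 0, 0.0, None, False))
            continue
        maf = minor_allele_frequency(col)
        counts = called.value_counts()
        n_aa = int(counts.get(0.0, 0))
        n_ab = int(counts.get(1.0, 0))
        n_bb = int(counts.get(2.0, 0))
        info = gm.markers[mid]
        hwe_p = (
            hwe_exact(n_aa, n_ab, n_bb) if info.genome == "nuclear" else None
        )
        out.append(
            MarkerSummary(
                marker=mid,
                completion=completion_rate(col),
                n_called=len(called),
                maf=maf,
                hwe_p=hwe_p,
                polymorphic=maf > 0,
            )
        )
    return out
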