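"""Panel validation: compare pooled discovery calls against individual
genotypes of the 10+10 discovery fish.

Each discovered marker is re-examined in the genotyped panel and
classified as ``polymorphic`` (a true SNP: at least two genotypes
segregate), ``monomorphic`` (every called fish carries the same
homozygote — the pooled signal was an artifact or a fixed reference
difference) or ``failed`` (the genotyping assay produced no calls).
The validation rate is polymorphic / (polymorphic + monomorphic) over
successful assays, the quantity the pooled-sequencing screen is judged
by (~70% in the original study: 147 true SNPs of 211 successful assays).

Genotype-based allele frequencies are recomputed per panel and pushed
through the same imbalance score and thresholds as the pooled reads, so
pooled and genotype-based imbalance classes can be compared marker by
marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .discovery import StringencyConfig, classify_imbalance, imbalance_score
from .types import ImbalanceRecord, UndefinedFrequencyError


@dataclass
class PanelMarker:
    """Individual genotypes for one marker across both discovery panels.

    Calls are 2-character genotype strings over the marker's alleles
    (e.g. ``"AT"``); order within a string is irrelevant.  A failed
    assay carries no calls.
    """

    marker_id: str
    ref: str
    alt: str
    fast_calls: list[str] = field(default_factory=list)
    slow_calls: list[str] = field(default_factory=list)
    status: str = "ok"  # ok | failed

    def __post_init__(self):
        if self.status not in ("ok", "failed"):
            raise ValueError("status must be ok or failed")
        if self.status == "failed" and (self.fast_calls or self.slow_calls):
            raise ValueError("failed assays carry no calls")
        for panel in (self.fast_calls, self.slow_calls):
            if len(panel) > 10:
                raise ValueError("panel size exceeds 10 fish")


PanelGenotypes = dict[str, PanelMarker]


def genotype_frequency(calls: Sequence[str], allele: str) -> float:
    """Allele frequency from diploid calls: (2*hom + het) / (2*n_called)."""
    called = [c for c in calls if c and "N" not in c.upper()]
    if not called:
        raise UndefinedFrequencyError("all calls missing")
    count = sum(c.upper().count(allele.upper()) for c in called)
    return count / (2 * len(called))


def classify_validation(marker_id: str, panel: PanelGenotypes) -> str:
    """Classify one marker: failed, monomorphic or polymorphic.

    Monomorphic means every called genotype across both panels is the
    same homozygote.  Two different homozygotes with no het still count
    as polymorphic — the alleles segregate.
    """
    pm = panel[marker_id]
    if pm.status == "failed":
        return "failed"
    genotypes = {
        "".join(sorted(c.upper()))
        for c in (*pm.fast_calls, *pm.slow_calls)
        if c and "N" not in c.upper()
    }
    if not genotypes:
        return "failed"
    if len(genotypes) == 1:
        gt = next(iter(genotypes))
        if gt[0] == gt[1]:
            return "monomorphic"
    return "polymorphic"


def validation_report(
    records: Sequence[ImbalanceRecord],
    panel: PanelGenotypes,
    cfg: StringencyConfig = StringencyConfig(),
    require_imbalance: bool = False,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Join discovery calls with panel genotypes and summarise.

    Returns a per-marker frame (validation class, genotype-based pool
    frequencies, genotype-based imbalance score/class, agreement flag)
    and the overall validation rate polymorphic / (polymorphic +
    monomorphic) over successful assays.

    With ``require_imbalance`` only markers whose genotype-based class
    is amplification or LOH are retained in the output frame (the rate
    is computed before this filter).
    """
    joint = [rec for rec in records if rec.site_id in panel]
    if not joint:
        raise ValueError("no discovered marker is present in the panel")
    rows = []
    n_poly = n_mono = 0
    for rec in joint:
        pm = panel[rec.site_id]
        vclass = classify_validation(rec.site_id, panel)
        row = {
            "marker": rec.site_id,
            "pooled_class": rec.klass,
            "validation": vclass,
            "f_fast_geno": None,
            "f_slow_geno": None,
            "score_geno": None,
            "class_geno": None,
            "agreement": None,
        }
        if vclass == "polymorphic":
            n_poly += 1
        elif vclass == "monomorphic":
            n_mono += 1
        if vclass != "failed":
            try:
                ff = genotype_frequency(pm.fast_calls, rec.variant_allele)
                fs = genotype_frequency(pm.slow_calls, rec.variant_allele)
                row["f_fast_geno"] = ff
                row["f_slow_geno"] = fs
                if ff > 0 or fs > 0:
                    score = imbalance_score(ff, fs)
                    row["score_geno"] = score
                    row["class_geno"] = classify_imbalance(score, cfg)
                    row["agreement"] = row["class_geno"] == rec.klass
            except UndefinedFrequencyError:
                pass
        rows.append(row)
    rate = n_poly / (n_poly + n_mono) if (n_poly + n_mono) else None
    df = pd.DataFrame(rows)
    if require_imbalance:
        df = df[df["class_geno"].isin(["amplification", "LOH"])].reset_index(drop=True)
    return df, rate


def panel_from_truth(truth, records: Sequence[ImbalanceRecord]) -> PanelGenotypes:
    """Genotype the simulated discovery fish at the discovered sites.

    Builds the panel the validation stage would obtain by individually
    genotyping the 10+10 simulated fish (error-free assays).
    """
    panel: PanelGenotypes = {}
    for rec in records:
        i = truth.site_index(rec.site_id)
        ref = str(truth.ref[i])
        alt = str(truth.alt[i]) if truth.alt[i] != "." else ref
        def _calls(genos):
            out = []
            for g in genos:
                out.append({0: ref + ref, 1: ref + alt, 2: alt + alt}[int(g)])
            return out
        panel[rec.site_id] = PanelMarker(
            marker_id=rec.site_id,
            ref=ref,
            alt=alt,
            fast_calls=_calls(truth.genotypes_fast[i]),
            slow_calls=_calls(truth.genotypes_slow[i]),
        )
    return panel


def read_panel(source) -> PanelGenotypes:
    """Read panel genotypes TSV: marker, ref, alt, status, fast_calls, slow_calls
    (call lists comma-separated, ``.`` when empty)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    panel: PanelGenotypes = {}
    for row in df.itertuples(index=False):
        fast = [] if row.fast_calls in (".", "") else row.fast_calls.split(",")
        slow = [] if row.slow_calls in (".", "") else row.slow_calls.split(",")
        panel[row.marker] = PanelMarker(
            marker_id=row.marker,
            ref=row.ref,
            alt=row.alt,
            fast_calls=fast,
            slow_calls=slow,
            status=row.status,
        )
    return panel


def write_panel(panel: PanelGenotypes, dest) -> None:
    rows = [
        {
            "marker": pm.marker_id,
            "ref": pm.ref,
            "alt": pm.alt,
            "status": pm.status,
            "fast_calls": ",".join(pm.fast_calls) or ".",
            "slow_calls": ",".join(pm.slow_calls) or ".",
        }
        for pm in panel.values()
    ]
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)
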