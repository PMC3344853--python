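"""Synthetic pooled low-coverage sequencing with per-site ground truth.

The generator emulates the study design behind the discovery funnel: two
pools of 10 diploid full-sib fish sequenced at ~0.97X per fish, so each
pool sees a Poisson(~9.7) read depth per expressed site.  Three site
classes are simulated:

* ``true_snp`` — a real polymorphism; each pool's population allele
  frequency is an independent Beta draw, fish genotypes are
  Hardy-Weinberg draws at that frequency, and reads sample fish
  chromosomes uniformly (equal-mass pooling => equal expected read share
  per fish).
* ``monomorphic`` — no variation; only sequencing error can produce
  non-reference reads.
* ``paralog`` — two collapsed loci carrying a fixed difference: both
  pools emit the alternate base at a fixed fraction (default 0.5) with
  inflated depth (default 2x, two loci mapping to one reference
  position).

Simulation is site-level: read sequences are never materialised because
only per-site counts reach the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .discovery import StringencyConfig, classify_imbalance, imbalance_score
from .types import BASES, ImbalanceRecord, PoolEvidence, SiteEvidence


@dataclass(frozen=True)
class SimConfig:
    """Simulator settings; the defaults are the study conditions.

    Attributes
    ----------
    n_sites : int
        Number of reference sites to simulate.
    prop_true_snp, prop_paralog : float
        Site-class proportions; the remainder is monomorphic.
    beta_a, beta_b : float
        Beta(a, b) parameters for the per-pool population allele
        frequency of true SNPs (drawn independently per pool, so the
        two pools are genuinely divergent at many sites).
    n_fish_per_pool : int
        Diploid individuals per pool (10 in the study design).
    coverage_per_fish : float
        Expected per-fish read depth at a site (~0.97X in the study);
        pool depth is Poisson(n_fish * coverage).
    error_rate : float
        Per-base sequencing error probability; an erroneous read shows a
        uniformly chosen other base.
    quality_mean, quality_sd : float
        Per-read Phred base quality model (normal, clipped to [2, 41]).
    paralog_alt_fraction : float
        Fraction of reads showing the alternate base at a paralog site.
    paralog_depth_factor : float
        Depth multiplier at paralog sites (collapse of two expressed
        loci roughly doubles coverage).
    dh_detect_rate : float
        Fraction of paralog sites present in the doubled-haploid
        self-variant list (the reference individual does not expose
        every collapsed locus).
    seed : int
        Mandatory RNG seed; identical seeds give identical output.
    """

    n_sites: int = 10_000
    prop_true_snp: float = 0.05
    prop_paralog: float = 0.02
    beta_a: float = 0.7
    beta_b: float = 0.7
    n_fish_per_pool: int = 10
    coverage_per_fish: float = 0.97
    error_rate: float = 0.005
    quality_mean: float = 32.0
    quality_sd: float = 4.0
    paralog_alt_fraction: float = 0.5
    paralog_depth_factor: float = 2.0
    dh_detect_rate: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_true_snp", "prop_paralog", "error_rate", "dh_detect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.prop_true_snp + self.prop_paralog > 1.0:
            raise ValueError("class proportions exceed 1")
        if self.coverage_per_fish <= 0:
            raise ValueError("coverage must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth for one simulated panel.

    Arrays are indexed by site (0-based); positions on the single
    simulated contig are ``site index + 1``.
    """

    config: SimConfig
    contig: str
    klass: np.ndarray  # str: true_snp | monomorphic | paralog
    ref: np.ndarray  # str base per site
    alt: np.ndarray  # str base per site ('.' for monomorphic)
    p_fast: np.ndarray  # population alt frequency, fast pool
    p_slow: np.ndarray
    genotypes_fast: np.ndarray  # (n_sites, n_fish) alt-allele dosage 0/1/2
    genotypes_slow: np.ndarray
    dh_het_sites: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.klass)

    def site_id(self, i: int) -> str:
        return f"{self.contig}:{i + 1}"

    def site_index(self, site_id: str) -> int:
        contig, pos = site_id.rsplit(":", 1)
        if contig != self.contig:
            raise KeyError(f"unknown contig {contig!r}")
        i = int(pos) - 1
        if not 0 <= i < self.n_sites:
            raise KeyError(f"position {pos} outside simulated panel")
        return i


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Draw site classes, population frequencies and fish genotypes.

    Fish genotypes are Hardy-Weinberg draws (Binomial(2, p)) at the
    pool's population frequency, independently per pool.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    klass = rng.choice(
        np.array(["true_snp", "paralog", "monomorphic"]),
        size=n,
        p=[
            cfg.prop_true_snp,
            cfg.prop_paralog,
            1.0 - cfg.prop_true_snp - cfg.prop_paralog,
        ],
    )
    base_arr = np.array(BASES)
    ref_idx = rng.integers(0, 4, size=n)
    ref = base_arr[ref_idx]
    # alternate base: uniformly one of the three non-reference bases
    alt_shift = rng.integers(1, 4, size=n)
    alt = base_arr[(ref_idx + alt_shift) % 4]
    alt = np.where(klass == "monomorphic", ".", alt)

    is_snp = klass == "true_snp"
    p_fast = np.zeros(n)
    p_slow = np.zeros(n)
    p_fast[is_snp] = rng.beta(cfg.beta_a, cfg.beta_b, size=is_snp.sum())
    p_slow[is_snp] = rng.beta(cfg.beta_a, cfg.beta_b, size=is_snp.sum())
    is_para = klass == "paralog"
    p_fast[is_para] = cfg.paralog_alt_fraction
    p_slow[is_para] = cfg.paralog_alt_fraction

    nf = cfg.n_fish_per_pool
    genotypes_fast = np.zeros((n, nf), dtype=np.int8)
    genotypes_slow = np.zeros((n, nf), dtype=np.int8)
    genotypes_fast[is_snp] = rng.binomial(2, p_fast[is_snp, None], size=(is_snp.sum(), nf))
    genotypes_slow[is_snp] = rng.binomial(2, p_slow[is_snp, None], size=(is_snp.sum(), nf))

    dh_hits = np.flatnonzero(is_para)[
        rng.random(is_para.sum()) < cfg.dh_detect_rate
    ]
    contig = "sim"
    return SimTruth(
        config=cfg,
        contig=contig,
        klass=klass,
        ref=ref,
        alt=alt,
        p_fast=p_fast,
        p_slow=p_slow,
        genotypes_fast=genotypes_fast,
        genotypes_slow=genotypes_slow,
        dh_het_sites=[f"{contig}:{i + 1}" for i in dh_hits],
    )


def _pool_reads(
    rng: np.random.Generator,
    depth: int,
    ref: str,
    alt: str,
    alt_prob: float,
    cfg: SimConfig,
) -> PoolEvidence:
    """Emit one pool's evidence at one site given the per-read alt prob."""
    if depth == 0:
        return PoolEvidence(0, {}, {})
    is_alt = rng.random(depth) < alt_prob
    bases = np.where(is_alt, alt if alt != "." else ref, ref)
    # sequencing error: flip to a uniformly chosen other base
    if cfg.error_rate > 0:
        err = rng.random(depth) < cfg.error_rate
        if err.any():
            others = np.array(
                [[b for b in BASES if b != x] for x in bases[err]]
            )
            pick = rng.integers(0, 3, size=err.sum())
            bases[err] = others[np.arange(err.sum()), pick]
    quals = np.clip(
        rng.normal(cfg.quality_mean, cfg.quality_sd, size=depth), 2.0, 41.0
    )
    counts: dict[str, int] = {}
    meanq: dict[str, float] = {}
    for b in BASES:
        mask = bases == b
        c = int(mask.sum())
        if c:
            counts[b] = c
            meanq[b] = float(quals[mask].mean())
    return PoolEvidence(depth, counts, meanq)


def simulate_evidence(truth: SimTruth, cfg: Optional[SimConfig] = None) -> list[SiteEvidence]:
    """Generate read evidence from truth.

    Per pool and site: depth ~ Poisson(n_fish x coverage); each read
    samples a uniformly chosen fish chromosome (so the per-read alt
    probability is the pool *sample* frequency, mean dosage / 2);
    sequencing error flips the base with probability ``error_rate``.
    Paralog sites emit the alternate base at a fixed fraction in both
    pools with depth inflated by ``paralog_depth_factor``.

    The evidence RNG is seeded at ``cfg.seed + 1`` so that truth and
    reads are independent streams but both reproducible.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    lam = cfg.n_fish_per_pool * cfg.coverage_per_fish
    n = truth.n_sites
    sites: list[SiteEvidence] = []
    sample_f_fast = truth.genotypes_fast.mean(axis=1) / 2.0
    sample_f_slow = truth.genotypes_slow.mean(axis=1) / 2.0
    for i in range(n):
        is_para = truth.klass[i] == "paralog"
        lam_i = lam * (cfg.paralog_depth_factor if is_para else 1.0)
        d_fast = int(rng.poisson(lam_i))
        d_slow = int(rng.poisson(lam_i))
        if is_para:
            pf = ps = cfg.paralog_alt_fraction
        elif truth.klass[i] == "true_snp":
            pf, ps = sample_f_fast[i], sample_f_slow[i]
        else:
            pf = ps = 0.0
        fast = _pool_reads(rng, d_fast, truth.ref[i], truth.alt[i], pf, cfg)
        slow = _pool_reads(rng, d_slow, truth.ref[i], truth.alt[i], ps, cfg)
        sites.append(SiteEvidence(truth.contig, i + 1, str(truth.ref[i]), fast, slow))
    return sites


def simulate_family_panel(
    n_families: int = 40,
    n_offspring: int = 17,
    n_nuclear: int = 30,
    n_mito: int = 24,
    causal_marker_effect: float = 0.0008,
    causal_haplotype_effect: float = 0.0006,
    missing_rate: float = 0.02,
    seed: int = 0,
):
    """Simulate the genotyped association panel: full-sib families with
    nuclear and mitochondrial markers plus growth phenotypes.

    The design mirrors a three-generation growth panel: ``n_families``
    full-sib families of ``n_offspring`` fish each plus their parents.
    Nuclear markers are biallelic with MAF ~ Uniform(0.1, 0.5); parents
    are Hardy-Weinberg draws and offspring Mendelian.  The first marker
    is causal: each A2 copy adds ``causal_marker_effect`` to the
    individual growth rate (per-day log-scale).  Mitochondrial markers
    form three fixed 24-SNP haplotypes at frequencies 0.49/0.26/0.25,
    two of which differ only at marker positions 8 and 21; haplotype 3
    carries ``causal_haplotype_effect``.  Offspring inherit the dam's
    haplotype (maternal).  Body weights are recorded at 170, 218, 282
    and 372 days post-hatch via exponential growth with individual
    noise, so weights stay positive.

    Two QC stressors are built in: the last nuclear marker is
    monomorphic and the second-to-last has ~50% missing calls.

    Returns ``(GenotypeMatrix, Pedigree, PhenotypeTable)``.
    """
    import pandas as pd

    from .types import (
        GenotypeMatrix,
        MarkerInfo,
        Pedigree,
        PedigreeEntry,
        PhenotypeTable,
    )

    rng = np.random.default_rng(seed)
    nuc_ids = [f"SNP{i + 1}" for i in range(n_nuclear)]
    mito_ids = [f"mtSNP{i + 1}" for i in range(n_mito)]
    markers = {m: MarkerInfo(m, "A", "G", "nuclear") for m in nuc_ids}
    markers.update({m: MarkerInfo(m, "C", "T", "mito") for m in mito_ids})

    mafs = rng.uniform(0.1, 0.5, size=n_nuclear)
    if n_nuclear >= 1:
        mafs[-1] = 0.0  # monomorphic stressor

    # three mito haplotypes as 0/2 dosage strings; hap2 and hap3 differ
    # only at positions 8 and 21 (1-based)
    hap1 = (rng.random(n_mito) < 0.5).astype(float) * 2.0
    hap2 = hap1.copy()
    flip = rng.choice(n_mito, size=max(3, n_mito // 4), replace=False)
    hap2[flip] = 2.0 - hap2[flip]
    hap3 = hap2.copy()
    for pos in (8, 21):
        if pos <= n_mito:
            hap3[pos - 1] = 2.0 - hap3[pos - 1]
    haplotypes = [hap1, hap2, hap3]
    hap_freqs = [0.49, 0.26, 0.25]

    entries: dict[str, PedigreeEntry] = {}
    rows: dict[str, dict[str, float]] = {}
    pheno_rows: dict[str, dict[str, float]] = {}
    times = [170, 218, 282, 372]

    def grow(individual_rate: float) -> dict[str, float]:
        w0 = rng.lognormal(mean=np.log(14.0), sigma=0.08)  # grams at 170 d
        out = {}
        w = w0
        prev_t = times[0]
        out[f"bw_{times[0]}"] = w
        for t in times[1:]:
            g = individual_rate + rng.normal(0.0, 0.0008)
            w = w * np.exp(g * (t - prev_t))
            out[f"bw_{t}"] = w
            prev_t = t
        return out

    def draw_parent_genotypes():
        return rng.binomial(2, mafs).astype(float)

    def mendelian_child(sire_g, dam_g):
        def gamete(g):
            if g == 0.0:
                return 0.0
            if g == 2.0:
                return 1.0
            return float(rng.integers(0, 2))

        return np.array([gamete(s) + gamete(d) for s, d in zip(sire_g, dam_g)])

    def hap_index():
        return int(rng.choice(3, p=hap_freqs))

    base_rate = 0.012  # per-day log growth between measurements

    for f in range(n_families):
        fam = f"fam{f + 1}"
        sire, dam = f"{fam}_sire", f"{fam}_dam"
        sire_g = draw_parent_genotypes()
        dam_g = draw_parent_genotypes()
        sire_h = hap_index()
        dam_h = hap_index()
        fam_effect = rng.normal(0.0, 0.0005)
        for sample, nuc, hap in ((sire, sire_g, sire_h), (dam, dam_g, dam_h)):
            entries[sample] = PedigreeEntry(sample, None, None, "", "F0")
            rows[sample] = dict(zip(nuc_ids, nuc))
            rows[sample].update(dict(zip(mito_ids, haplotypes[hap])))
            rate = (
                base_rate
                + causal_marker_effect * nuc[0]
                + (causal_haplotype_effect if hap == 2 else 0.0)
                + rng.normal(0.0, 0.001)
            )
            pheno_rows[sample] = grow(rate)
        for k in range(n_offspring):
            kid = f"{fam}_off{k + 1}"
            entries[kid] = PedigreeEntry(kid, sire, dam, fam, "F1")
            nuc = mendelian_child(sire_g, dam_g)
            rows[kid] = dict(zip(nuc_ids, nuc))
            rows[kid].update(dict(zip(mito_ids, haplotypes[dam_h])))
            rate = (
                base_rate
                + fam_effect
                + causal_marker_effect * nuc[0]
                + (causal_haplotype_effect if dam_h == 2 else 0.0)
                + rng.normal(0.0, 0.001)
            )
            pheno_rows[kid] = grow(rate)

    calls = pd.DataFrame.from_dict(rows, orient="index")
    # missingness stressors: global dropout plus one nearly-dead marker
    mask = rng.random(calls.shape) < missing_rate
    if n_nuclear >= 2:
        low_col = calls.columns.get_loc(nuc_ids[-2])
        mask[:, low_col] |= rng.random(len(calls)) < 0.5
    calls = calls.mask(mask)

    gm = GenotypeMatrix(calls=calls, markers=markers)
    ped = Pedigree(entries=entries)
    weights = pd.DataFrame.from_dict(pheno_rows, orient="index")
    pheno = PhenotypeTable(
        weights=weights,
        covariates=pd.DataFrame(index=weights.index),
        times=times,
    )
    return gm, ped, pheno


def write_truth(truth: SimTruth, dest) -> None:
    """Write ground truth as TSV (config embedded as a ``#config=`` line)."""
    import json

    out = open(dest, "wt") if isinstance(dest, str) else dest
    out.write("#config=" + json.dumps(truth.config.as_dict()) + "\n")
    out.write("#dh_het_sites=" + ",".join(truth.dh_het_sites) + "\n")
    out.write("contig\tpos\tklass\tref\talt\tp_fast\tp_slow\tgt_fast\tgt_slow\n")
    for i in range(truth.n_sites):
        out.write(
            "\t".join(
                [
                    truth.contig,
                    str(i + 1),
                    str(truth.klass[i]),
                    str(truth.ref[i]),
                    str(truth.alt[i]),
                    f"{truth.p_fast[i]:.10g}",
                    f"{truth.p_slow[i]:.10g}",
                    ",".join(map(str, truth.genotypes_fast[i])),
                    ",".join(map(str, truth.genotypes_slow[i])),
                ]
            )
            + "\n"
        )
    if isinstance(dest, str):
        out.close()


def read_truth(source) -> SimTruth:
    """Read ground truth written by :func:`write_truth`."""
    import json

    stream = open(source, "rt") if isinstance(source, str) else source
    cfg = None
    dh: list[str] = []
    rows = []
    header_seen = False
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("#config="):
            cfg = SimConfig.from_dict(json.loads(line[len("#config=") :]))
            continue
        if line.startswith("#dh_het_sites="):
            payload = line[len("#dh_het_sites=") :]
            dh = payload.split(",") if payload else []
            continue
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        rows.append(line.split("\t"))
    if isinstance(source, str):
        stream.close()
    if cfg is None:
        raise ValueError("truth file lacks the #config= line")
    n = len(rows)
    truth = SimTruth(
        config=cfg,
        contig=rows[0][0] if rows else "sim",
        klass=np.array([r[2] for r in rows]),
        ref=np.array([r[3] for r in rows]),
        alt=np.array([r[4] for r in rows]),
        p_fast=np.array([float(r[5]) for r in rows]),
        p_slow=np.array([float(r[6]) for r in rows]),
        genotypes_fast=np.array(
            [[int(x) for x in r[7].split(",")] for r in rows], dtype=np.int8
        ).reshape(n, -1),
        genotypes_slow=np.array(
            [[int(x) for x in r[8].split(",")] for r in rows], dtype=np.int8
        ).reshape(n, -1),
        dh_het_sites=dh,
    )
    return truth


def evaluate_discovery(
    truth: SimTruth,
    records: Sequence[ImbalanceRecord],
    divergence_margin: float = 0.3,
    cfg: StringencyConfig = StringencyConfig(),
) -> dict:
    """Score a discovery run against ground truth.

    Returns a dict with

    * ``validation_rate`` — fraction of discovered sites whose truth
      class is ``true_snp`` (None when nothing was discovered);
    * ``sensitivity`` — fraction of true SNPs whose population pool
      frequencies differ by more than ``divergence_margin`` that were
      discovered;
    * ``false_discovery_count`` — discovered sites that are not true SNPs;
    * ``imbalance_class_accuracy`` — among discovered true SNPs, the
      fraction whose class matches the class implied by the population
      frequencies (None when no true SNP was discovered).
    """
    discovered_idx = []
    for rec in records:
        discovered_idx.append(truth.site_index(rec.site_id))  # raises on mismatch
    discovered_idx = np.asarray(discovered_idx, dtype=int)

    n_disc = len(discovered_idx)
    is_true = truth.klass[discovered_idx] == "true_snp" if n_disc else np.array([], bool)
    validation_rate = float(is_true.mean()) if n_disc else None
    false_discovery_count = int(n_disc - is_true.sum())

    divergent = (truth.klass == "true_snp") & (
        np.abs(truth.p_fast - truth.p_slow) > divergence_margin
    )
    n_divergent = int(divergent.sum())
    hit = np.zeros(truth.n_sites, dtype=bool)
    hit[discovered_idx] = True
    sensitivity = float(hit[divergent].mean()) if n_divergent else 0.0

    n_true_disc = 0
    n_class_ok = 0
    for rec, idx, ok in zip(records, discovered_idx, is_true):
        if not ok:
            continue
        n_true_disc += 1
        pf, ps = truth.p_fast[idx], truth.p_slow[idx]
        if pf == 0.0 and ps == 0.0:
            continue
        true_class = classify_imbalance(imbalance_score(pf, ps), cfg)
        if true_class == rec.klass:
            n_class_ok += 1
    accuracy = n_class_ok / n_true_disc if n_true_disc else None

    return {
        "n_discovered": n_disc,
        "validation_rate": validation_rate,
        "sensitivity": sensitivity,
        "n_divergent_true_snps": n_divergent,
        "false_discovery_count": false_discovery_count,
        "imbalance_class_accuracy": accuracy,
    }
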