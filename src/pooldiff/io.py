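"""Readers and writers for every on-disk format the pipeline touches.

Site evidence comes in two dialects:

* ``mpileup2`` — standard samtools-mpileup text with exactly two sample
  blocks, fast pool first, slow pool second (columns: contig, pos, ref,
  then depth/read-bases/base-qualities per pool).
* ``native_tsv`` — a headered TSV that carries the already-summarised
  per-base counts, so the simulator and the tests need no alignment step.
  Columns: contig, pos, ref, depth_fast, evidence_fast, depth_slow,
  evidence_slow, where an evidence field is a comma-separated list of
  ``base:count:meanq`` triples (``.`` when the pool saw no usable reads).

Genotypes are a dosage TSV whose marker columns are headed
``<marker>:<A1>/<A2>:<genome>``; dosage counts copies of A2 and missing
calls are the token ``NA``.  Mitochondrial markers are haploid: a het
call is accepted with a warning so QC can flag it downstream.
"""

from __future__ import annotations

import io as _io
import math
import re
import warnings
from typing import Iterable, Iterator, Optional, TextIO, Union

import numpy as np
import pandas as pd

from .types import (
    BASES,
    MISSING,
    GenotypeMatrix,
    ImbalanceRecord,
    MarkerInfo,
    ParseError,
    Pedigree,
    PedigreeEntry,
    PhenotypeTable,
    PoolEvidence,
    SiteEvidence,
)

DIALECTS = ("mpileup2", "native_tsv")

_EVIDENCE_HEADER = [
    "contig",
    "pos",
    "ref",
    "depth_fast",
    "evidence_fast",
    "depth_slow",
    "evidence_slow",
]


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return open(source, "rt")
    return source


# ---------------------------------------------------------------------------
# site evidence
# ---------------------------------------------------------------------------


def _decode_pileup_bases(bases: str, quals: str, ref: str, depth: int, line_no: int):
    """Decode one mpileup read-base string into per-base counts/qualities.

    Upper- and lower-case calls are merged (strand is ignored); indel,
    read-start (``^``), read-end (``$``), deletion placeholder (``*``)
    and reference-skip characters are consumed and dropped.  Every
    retained or dropped read consumes exactly one quality character, so
    the quality string length must equal the reported depth.
    """
    if depth == 0:
        return {}, {}
    counts: dict[str, int] = {}
    qsums: dict[str, float] = {}
    qi = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret is followed by mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = re.match(r"[+-](\d+)", bases[i:])
            if m is None:
                raise ParseError("malformed indel in read bases", line_no)
            i += 1 + len(m.group(1)) + int(m.group(1))
            continue
        if qi >= len(quals):
            raise ParseError("more read bases than quality characters", line_no)
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in ".,":
            allele = ref
        elif c.upper() in BASES:
            allele = c.upper()
        else:
            # N, deletion placeholder, reference skip: consumes a quality
            continue
        counts[allele] = counts.get(allele, 0) + 1
        qsums[allele] = qsums.get(allele, 0.0) + q
    if qi != len(quals):
        raise ParseError(
            f"quality string length {len(quals)} does not match decoded depth {qi}",
            line_no,
        )
    if qi != depth:
        raise ParseError(
            f"declared depth {depth} does not match decoded read count {qi}", line_no
        )
    meanq = {b: qsums[b] / counts[b] for b in counts}
    return counts, meanq


def _parse_mpileup2(stream: TextIO) -> Iterator[SiteEvidence]:
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(
                f"expected 9 tab-separated fields (two sample blocks), got {len(fields)}",
                line_no,
            )
        contig, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(f"position {pos_s!r} is not an integer", line_no)
        pools = {}
        for pool, off in (("fast", 3), ("slow", 6)):
            try:
                depth = int(fields[off])
            except ValueError:
                raise ParseError(f"depth {fields[off]!r} is not an integer", line_no)
            bases, quals = fields[off + 1], fields[off + 2]
            if depth == 0:
                counts, meanq = {}, {}
            else:
                counts, meanq = _decode_pileup_bases(bases, quals, ref, depth, line_no)
            pools[pool] = PoolEvidence(depth=depth, counts=counts, meanq=meanq)
        try:
            yield SiteEvidence(contig, pos, ref, pools["fast"], pools["slow"])
        except ValueError as exc:
            raise ParseError(str(exc), line_no)


def _format_evidence_field(ev: PoolEvidence) -> str:
    parts = [
        f"{b}:{ev.counts[b]}:{ev.meanq[b]:g}" for b in sorted(ev.counts) if ev.counts[b]
    ]
    return ",".join(parts) if parts else "."


def _parse_evidence_field(text: str, line_no: int):
    counts: dict[str, int] = {}
    meanq: dict[str, float] = {}
    if text == ".":
        return counts, meanq
    for triple in text.split(","):
        try:
            base, count_s, q_s = triple.split(":")
            counts[base] = int(count_s)
            meanq[base] = float(q_s)
        except ValueError:
            raise ParseError(f"malformed evidence triple {triple!r}", line_no)
    return counts, meanq


def _parse_native_tsv(stream: TextIO) -> Iterator[SiteEvidence]:
    header: Optional[list[str]] = None
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            if fields != _EVIDENCE_HEADER:
                raise ParseError(
                    f"expected header {_EVIDENCE_HEADER}, got {fields}", line_no
                )
            header = fields
            continue
        if len(fields) != 7:
            raise ParseError(f"expected 7 fields, got {len(fields)}", line_no)
        contig, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
            depth_fast = int(fields[3])
            depth_slow = int(fields[5])
        except ValueError as exc:
            raise ParseError(str(exc), line_no)
        cf, qf = _parse_evidence_field(fields[4], line_no)
        cs, qs = _parse_evidence_field(fields[6], line_no)
        try:
            yield SiteEvidence(
                contig,
                pos,
                ref,
                PoolEvidence(depth_fast, cf, qf),
                PoolEvidence(depth_slow, cs, qs),
            )
        except ValueError as exc:
            raise ParseError(str(exc), line_no)


def parse_site_evidence(
    source: Union[str, TextIO], dialect: str = "native_tsv"
) -> Iterator[SiteEvidence]:
    """Parse per-site two-pool read evidence from ``source``.

    Parameters
    ----------
    source : path or open text stream
    dialect : ``"mpileup2"`` or ``"native_tsv"``

    Yields
    ------
    SiteEvidence, one per input line.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    stream = _as_stream(source)
    parser = _parse_mpileup2 if dialect == "mpileup2" else _parse_native_tsv
    yield from parser(stream)


def write_site_evidence(sites: Iterable[SiteEvidence], dest: Union[str, TextIO]) -> None:
    """Write site evidence in the native TSV dialect."""
    out = open(dest, "wt") if isinstance(dest, str) else dest
    out.write("\t".join(_EVIDENCE_HEADER) + "\n")
    for s in sites:
        out.write(
            "\t".join(
                [
                    s.contig,
                    str(s.pos),
                    s.ref,
                    str(s.fast.depth),
                    _format_evidence_field(s.fast),
                    str(s.slow.depth),
                    _format_evidence_field(s.slow),
                ]
            )
            + "\n"
        )
    if isinstance(dest, str):
        out.close()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pooldiff
##INFO=<ID=AFF,Number=1,Type=Float,Description="Variant allele frequency in the fast-growth pool">
##INFO=<ID=AFS,Number=1,Type=Float,Description="Variant allele frequency in the slow-growth pool">
##INFO=<ID=AIS,Number=1,Type=Float,Description="Allelic imbalance score AFF/AFS (inf when AFS=0)">
##INFO=<ID=AIC,Number=1,Type=String,Description="Imbalance class: amplification, LOH or balanced">
##FILTER=<ID=paralog_suspect,Description="Site flagged by the paralog filter">
##FILTER=<ID=discordant_allele,Description="Pools disagree on the top variant allele">
"""


def _fmt_score(score: float) -> str:
    if math.isinf(score):
        return "inf"
    return f"{score:.6g}"


def write_vcf(
    records: Iterable[ImbalanceRecord],
    dest: Union[str, TextIO],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write discovered variants as VCF v4.2 text.

    ``records`` must be sorted by (contig, pos).  INFO keys: AFF and AFS
    (pool variant-allele frequencies), AIS (imbalance score, ``inf``
    allowed) and AIC (class).  FILTER carries stage flags.
    """
    out = open(dest, "wt") if isinstance(dest, str) else dest
    out.write(_VCF_HEADER)
    if contigs:
        for name, length in contigs.items():
            out.write(f"##contig=<ID={name},length={length}>\n")
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    last = None
    for rec in records:
        key = (rec.site.contig, rec.site.pos)
        if last is not None and key < last:
            raise ValueError(f"records not sorted by (contig, pos) at {key}")
        last = key
        filter_flags = sorted(
            f for f in rec.stage_flags if f in ("paralog_suspect", "discordant_allele")
        )
        filt = ";".join(filter_flags) if filter_flags else "PASS"
        info = (
            f"AFF={rec.f_fast:.6g};AFS={rec.f_slow:.6g};"
            f"AIS={_fmt_score(rec.score)};AIC={rec.klass}"
        )
        out.write(
            "\t".join(
                [
                    rec.site.contig,
                    str(rec.site.pos),
                    ".",
                    rec.site.ref,
                    rec.variant_allele,
                    ".",
                    filt,
                    info,
                ]
            )
            + "\n"
        )
    if isinstance(dest, str):
        out.close()


def read_vcf(source: Union[str, TextIO]) -> pd.DataFrame:
    """Read a pooldiff VCF back into a tidy frame (one row per variant)."""
    stream = _as_stream(source)
    rows = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError("VCF data line has fewer than 8 columns", line_no)
        info = dict(
            kv.split("=", 1) if "=" in kv else (kv, True)
            for kv in fields[7].split(";")
        )
        rows.append(
            {
                "contig": fields[0],
                "pos": int(fields[1]),
                "ref": fields[3],
                "alt": fields[4],
                "filter": fields[6],
                "f_fast": float(info["AFF"]),
                "f_slow": float(info["AFS"]),
                "score": float(info["AIS"]),
                "klass": info["AIC"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "filter",
            "f_fast",
            "f_slow",
            "score",
            "klass",
        ],
    )


# ---------------------------------------------------------------------------
# genotypes / pedigree / phenotypes
# ---------------------------------------------------------------------------

_MARKER_HEADER_RE = re.compile(
    r"^(?P<id>[^:]+):(?P<a1>[ACGT])/(?P<a2>[ACGT]):(?P<genome>nuclear|mito)$"
)


def read_genotypes(source: Union[str, TextIO]) -> GenotypeMatrix:
    """Read the dosage TSV (marker columns headed ``id:A1/A2:genome``)."""
    df = pd.read_csv(_as_stream(source), sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError("first column must be sample_id")
    markers: dict[str, MarkerInfo] = {}
    rename = {}
    for col in df.columns[1:]:
        m = _MARKER_HEADER_RE.match(col)
        if m is None:
            raise ParseError(f"malformed marker header {col!r}")
        mid = m.group("id")
        if mid in markers:
            raise ValueError(f"duplicate marker id {mid}")
        markers[mid] = MarkerInfo(mid, m.group("a1"), m.group("a2"), m.group("genome"))
        rename[col] = mid
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    calls = (
        df.rename(columns=rename)
        .set_index("sample_id")
        .replace(MISSING, np.nan)
        .astype(float)
    )
    gm = GenotypeMatrix(calls=calls, markers=markers)
    flagged = gm.mito_het_flags()
    if flagged:
        warnings.warn(
            f"{len(flagged)} het call(s) on mitochondrial (haploid) markers, "
            f"e.g. {flagged[0]}; flagged for QC",
            stacklevel=2,
        )
    return gm


def write_genotypes(gm: GenotypeMatrix, dest: Union[str, TextIO]) -> None:
    cols = {}
    for mid in gm.marker_ids:
        info = gm.markers[mid]
        cols[mid] = f"{mid}:{info.a1}/{info.a2}:{info.genome}"
    df = gm.calls.rename(columns=cols)
    out = df.map(lambda v: MISSING if pd.isna(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(dest, sep="\t")


def read_pedigree(source: Union[str, TextIO]) -> Pedigree:
    df = pd.read_csv(_as_stream(source), sep="\t", dtype=str).fillna(MISSING)
    required = {"sample_id", "sire_id", "dam_id", "family_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"pedigree TSV must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in pedigree")
    entries = {}
    for row in df.itertuples(index=False):
        entries[row.sample_id] = PedigreeEntry(
            sample=row.sample_id,
            sire=None if row.sire_id == MISSING else row.sire_id,
            dam=None if row.dam_id == MISSING else row.dam_id,
            family="" if row.family_id == MISSING else row.family_id,
            generation=getattr(row, "generation", ""),
        )
    return Pedigree(entries=entries)


def write_pedigree(ped: Pedigree, dest: Union[str, TextIO]) -> None:
    rows = [
        {
            "sample_id": e.sample,
            "sire_id": e.sire or MISSING,
            "dam_id": e.dam or MISSING,
            "family_id": e.family or MISSING,
            "generation": e.generation,
        }
        for e in ped.entries.values()
    ]
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)


def read_phenotypes(source: Union[str, TextIO]) -> PhenotypeTable:
    """Read the phenotype TSV: ``bw_<days>`` columns are body weights in
    grams; every other non-id column is carried as a covariate."""
    df = pd.read_csv(_as_stream(source), sep="\t")
    if df.columns[0] != "sample_id":
        raise ParseError("first column must be sample_id")
    df = df.set_index("sample_id")
    bw_cols = [c for c in df.columns if c.startswith("bw_")]
    times = []
    for c in bw_cols:
        try:
            times.append(int(c.split("_", 1)[1]))
        except ValueError:
            raise ParseError(f"malformed weight column {c!r} (expect bw_<days>)")
    order = np.argsort(times)
    bw_cols = [bw_cols[i] for i in order]
    times = sorted(times)
    weights = df[bw_cols].astype(float)
    if (weights.to_numpy() <= 0).any():
        raise ValueError("body weights must be positive")
    covars = df[[c for c in df.columns if not c.startswith("bw_")]]
    return PhenotypeTable(weights=weights, covariates=covars, times=times)


def write_phenotypes(pt: PhenotypeTable, dest: Union[str, TextIO]) -> None:
    df = pd.concat([pt.weights, pt.covariates], axis=1)
    df.index.name = "sample_id"
    df.to_csv(dest, sep="\t")


def read_fasta(path: str) -> dict[str, str]:
    """Reference FASTA as {contig: sequence} (used for VCF contig metadata)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
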