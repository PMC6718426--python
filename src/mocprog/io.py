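"""Readers and writers for the formats the pipeline touches.

Variants travel as VCF v4.2 (INFO keys ``DP, AD, VAFN, CALLERS, CQ, GENE,
POPAF, CLNPATH, HOTSPOT, EFFECT``) or as an equivalent tab-delimited table;
copy-number segments as a SEG-like TSV (sample, chrom, start, end, log2,
loh); case metadata as a CSV sample sheet. VCF positions are 1-based,
segments half-open 0-based; conversions happen here and nowhere else.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .genome import GenomeBuild
from .model import CaseRecord, CNSegment, SVBreakpointPair, VariantCall

log = logging.getLogger("mocprog")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mocprog
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=R,Type=Integer,Description="Ref,alt supporting reads">
##INFO=<ID=VAFN,Number=1,Type=Float,Description="Alt allele fraction in matched normal">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting the variant">
##INFO=<ID=CQ,Number=1,Type=String,Description="Consequence class: coding/splice/other">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=POPAF,Number=1,Type=Float,Description="Max population allele frequency (ExAC-minus-TCGA, ExAC-NFE, EVS)">
##INFO=<ID=CLNPATH,Number=0,Type=Flag,Description="ClinVar (potentially) pathogenic">
##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Known hotspot mutation">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Fine-grained effect (missense/nonsense/frameshift/splice/synonymous/other)">
##FILTER=<ID=caller_fail,Description="Failed default caller filters">
"""

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual", "depth", "alt_depth", "vaf_tumor",
    "vaf_normal", "callers", "passes_caller_filters", "consequence", "gene",
    "pop_af", "clinvar_pathogenic", "is_hotspot", "effect",
]


def write_variants_vcf(variants: list[VariantCall], path: str | Path,
                       build: GenomeBuild | None = None) -> None:
    path = Path(path)
    lines = [_VCF_HEADER]
    contigs = tuple(build.chrom_names) if build is not None else sorted(
        {v.chrom for v in variants})
    for c in contigs:
        length = f",length={build.length(c)}" if build is not None else ""
        lines.append(f"##contig=<ID={c}{length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in variants:
        info = [f"DP={v.depth}", f"AD={v.depth - v.alt_depth},{v.alt_depth}"]
        if v.vaf_normal is not None:
            info.append(f"VAFN={v.vaf_normal:.6g}")
        info.append("CALLERS=" + ",".join(sorted(v.callers)))
        info.append(f"CQ={v.consequence}")
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.pop_af is not None:
            info.append(f"POPAF={v.pop_af:.3g}")
        if v.clinvar_pathogenic:
            info.append("CLNPATH")
        if v.is_hotspot:
            info.append("HOTSPOT")
        if v.effect:
            info.append(f"EFFECT={v.effect}")
        qual = "." if v.qual is None else f"{v.qual:g}"
        filt = "PASS" if v.passes_caller_filters else "caller_fail"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t{filt}\t"
            + ";".join(info) + "\n"
        )
    path.write_text("".join(lines))


def _variant_from_cyvcf2(rec, idx: int) -> VariantCall:
    info = dict(rec.INFO)
    depth = info.get("DP")
    ad = info.get("AD")
    if depth is None or ad is None:
        raise ValueError(f"record {idx} ({rec.CHROM}:{rec.POS}): missing DP/AD")
    alt_depth = int(ad[1]) if isinstance(ad, tuple) else int(ad)
    vaf = alt_depth / depth if depth else 0.0
    callers = info.get("CALLERS", "")
    if isinstance(callers, tuple):
        callers = ",".join(callers)
    vafn = info.get("VAFN")
    return VariantCall(
        chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
        qual=rec.QUAL, depth=int(depth), alt_depth=alt_depth,
        vaf_tumor=vaf,
        vaf_normal=None if vafn is None else float(vafn),
        callers=frozenset(c for c in callers.split(",") if c),
        passes_caller_filters=rec.FILTER is None,
        consequence=info.get("CQ", "other"),
        gene=info.get("GENE"),
        pop_af=None if info.get("POPAF") is None else float(info["POPAF"]),
        clinvar_pathogenic=bool(info.get("CLNPATH", False)),
        is_hotspot=bool(info.get("HOTSPOT", False)),
        effect=info.get("EFFECT"),
    )


def _na(x) -> bool:
    return x is None or (isinstance(x, float) and pd.isna(x)) or x in (".", "", "NA")


def _parse_variants_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(["chrom", "pos", "ref", "alt", "depth", "alt_depth"]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        try:
            depth = int(d["depth"])
            alt_depth = int(d["alt_depth"])
            vaf = (float(d["vaf_tumor"]) if not _na(d.get("vaf_tumor"))
                   else (alt_depth / depth if depth else 0.0))
            out.append(VariantCall(
                chrom=str(d["chrom"]), pos=int(d["pos"]), ref=d["ref"], alt=d["alt"],
                qual=None if _na(d.get("qual")) else float(d["qual"]),
                depth=depth, alt_depth=alt_depth, vaf_tumor=vaf,
                vaf_normal=None if _na(d.get("vaf_normal")) else float(d["vaf_normal"]),
                callers=frozenset(
                    c for c in str(d.get("callers", "")).split(",") if c and c != "nan"),
                passes_caller_filters=bool(d.get("passes_caller_filters", True)),
                consequence=d.get("consequence", "other"),
                gene=None if _na(d.get("gene")) else d["gene"],
                pop_af=None if _na(d.get("pop_af")) else float(d["pop_af"]),
                clinvar_pathogenic=bool(d.get("clinvar_pathogenic", False)),
                is_hotspot=bool(d.get("is_hotspot", False)),
                effect=None if _na(d.get("effect")) else d["effect"],
            ))
        except (ValueError, KeyError, TypeError) as e:
            raise ValueError(f"{path} line {i}: {e}") from e
    return out


def parse_variants(path: str | Path, mode: str | None = None) -> list[VariantCall]:
    """Parse a VCF (or TSV fallback) into VariantCalls, in file order.

    ``mode`` is accepted for interface symmetry with the filter cascade;
    parsing itself is mode-independent. Absent annotations become ``None``.
    """
    path = Path(path)
    if path.suffix in (".tsv", ".txt", ".csv"):
        variants = _parse_variants_tsv(path)
    else:
        from cyvcf2 import VCF

        variants = []
        for idx, rec in enumerate(VCF(str(path)), start=1):
            try:
                variants.append(_variant_from_cyvcf2(rec, idx))
            except ValueError:
                raise
            except Exception as e:  # cyvcf2 raises plain Exceptions
                raise ValueError(f"{path} record {idx}: {e}") from e
    log.info("parsed %d variants from %s", len(variants), path)
    return variants


# ---------------------------------------------------------------- segments

def write_segments(segments_by_sample: dict[str, list[CNSegment]],
                   path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample", "chrom", "start", "end", "log2", "loh"])
        for sample, segs in segments_by_sample.items():
            for s in segs:
                w.writerow([sample, s.chrom, s.start, s.end,
                            f"{s.log2:.6g}", int(s.loh)])


def parse_segments_multi(path: str | Path,
                         build: GenomeBuild) -> dict[str, list[CNSegment]]:
    """Parse a multi-sample SEG-like TSV into per-sample segment lists.

    Rejects segments outside the build and overlapping same-chromosome
    segments within a sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if df.empty and "chrom" not in df.columns:
        return {}
    out: dict[str, list[CNSegment]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        chrom, start, end = str(d["chrom"]), int(d["start"]), int(d["end"])
        if chrom not in build:
            raise ValueError(f"{path} line {i}: chromosome {chrom!r} not in build")
        if start >= end:
            raise ValueError(f"{path} line {i}: start {start} >= end {end}")
        if end > build.length(chrom):
            raise ValueError(
                f"{path} line {i}: end {end} beyond {chrom} length "
                f"{build.length(chrom)}")
        seg = CNSegment(chrom, start, end, float(d["log2"]),
                        loh=bool(int(d.get("loh", 0))))
        out.setdefault(str(d.get("sample", "sample")), []).append(seg)
    for sample, segs in out.items():
        by_chrom: dict[str, list[CNSegment]] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, group in by_chrom.items():
            group = sorted(group, key=lambda s: s.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{path}: overlapping segments in {sample} on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")
    log.info("parsed segments for %d samples from %s", len(out), path)
    return out


def parse_segments(path: str | Path, build: GenomeBuild,
                   sample: str | None = None) -> list[CNSegment]:
    """Single-sample convenience over :func:`parse_segments_multi`."""
    multi = parse_segments_multi(path, build)
    if not multi:
        return []
    if sample is None:
        if len(multi) > 1:
            raise ValueError(f"{path} holds {len(multi)} samples; pass sample=")
        return next(iter(multi.values()))
    return multi[sample]


# ------------------------------------------------------------------- SVs

def write_svs(svs_by_sample: dict[str, list[SVBreakpointPair]],
              path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample", "chrom_a", "pos_a", "chrom_b", "pos_b", "sv_type"])
        for sample, svs in svs_by_sample.items():
            for s in svs:
                w.writerow([sample, s.chrom_a, s.pos_a, s.chrom_b, s.pos_b, s.sv_type])


def parse_svs(path: str | Path) -> dict[str, list[SVBreakpointPair]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    out: dict[str, list[SVBreakpointPair]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.setdefault(str(d["sample"]), []).append(SVBreakpointPair(
            d["chrom_a"], int(d["pos_a"]), d["chrom_b"], int(d["pos_b"]),
            d["sv_type"]))
    return out


# -------------------------------------------------------------- metadata

_META_COLUMNS = ["case_id", "classification", "platform_mode", "stage",
                 "time_months", "event"]


def write_metadata(cases: list[CaseRecord], path: str | Path) -> None:
    rows = [{
        "case_id": c.case_id, "classification": c.classification,
        "platform_mode": c.platform_mode, "stage": c.stage or "",
        "time_months": "" if c.time is None else c.time,
        "event": c.event or "",
    } for c in cases]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[CaseRecord]:
    df = pd.read_csv(path, dtype={"case_id": str})
    cases = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cases.append(CaseRecord(
            case_id=str(d["case_id"]), classification=d["classification"],
            platform_mode=d["platform_mode"],
            stage=None if _na(d.get("stage")) else str(d["stage"]),
            time=None if _na(d.get("time_months")) else float(d["time_months"]),
            event=None if _na(d.get("event")) else str(d["event"]),
        ))
    return cases


# ----------------------------------------------------------- whole cohort

def write_cohort(cases: list[CaseRecord], outdir: str | Path,
                 build: GenomeBuild | None = None) -> None:
    """Write a cohort as metadata.csv, segments.seg, svs.tsv and one VCF
    per case under variants/."""
    outdir = Path(outdir)
    (outdir / "variants").mkdir(parents=True, exist_ok=True)
    write_metadata(cases, outdir / "metadata.csv")
    write_segments({c.case_id: c.segments for c in cases}, outdir / "segments.seg")
    write_svs({c.case_id: c.svs for c in cases}, outdir / "svs.tsv")
    for c in cases:
        write_variants_vcf(c.variants, outdir / "variants" / f"{c.case_id}.vcf")


def load_cohort(indir: str | Path, build: GenomeBuild) -> list[CaseRecord]:
    indir = Path(indir)
    cases = read_metadata(indir / "metadata.csv")
    segs = parse_segments_multi(indir / "segments.seg", build)
    svs = parse_svs(indir / "svs.tsv") if (indir / "svs.tsv").exists() else {}
    for c in cases:
        vcf = indir / "variants" / f"{c.case_id}.vcf"
        if vcf.exists():
            c.variants = parse_variants(vcf, c.platform_mode)
        c.segments = segs.get(c.case_id, [])
        c.svs = svs.get(c.case_id, [])
    return cases
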