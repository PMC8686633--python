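"""VCF / BED / manifest input and output.

Input VCFs must carry ``SVTYPE`` (or a symbolic ALT such as ``<DEL>``) and,
where applicable, ``END`` and ``SVLEN`` in INFO.  Breakend/translocation
records (BND, TRA) and other unsupported types are dropped with a logged
count.  Merged sets are written in the SURVIVOR output dialect: one record
per cluster at representative coordinates with ``SUPP`` (integer support)
and ``SUPP_VEC`` (bit string over the inputs, documented in the header).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .core import CallSet, FactorKey, MergedSet, SVRecord, _SV_TYPE_SET

log = logging.getLogger(__name__)

_ALT_TYPES = {"<DEL>": "DEL", "<INS>": "INS", "<DUP>": "DUP",
              "<DUP:TANDEM>": "DUP", "<INV>": "INV"}


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def _info_get(rec, key):
    """INFO lookup tolerant of keys the header does not declare."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def read_sv_vcf(path, key: FactorKey | str | None = None) -> CallSet:
    """Read one SV call set from a VCF, resolving SVTYPE/END/SVLEN.

    END defaults to ``POS + |SVLEN|`` for DEL/DUP/INV when absent; for INS
    it is always the insertion point.  Unsupported types are counted and
    dropped; malformed records are skipped with a warning naming the site.
    """
    path = Path(path)
    records: list[SVRecord] = []
    dropped: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            svtype = _scalar(_info_get(rec, "SVTYPE")) or _ALT_TYPES.get(alt)
            if svtype is None:
                log.warning("%s:%s %s: no SVTYPE and non-symbolic ALT, skipped",
                            path.name, rec.chrom, rec.pos)
                continue
            svtype = str(svtype)
            if svtype not in _SV_TYPE_SET:
                dropped[svtype] = dropped.get(svtype, 0) + 1
                continue
            svlen = _info_get(rec, "SVLEN")
            svlen = abs(int(_scalar(svlen))) if svlen is not None else None
            pos = rec.pos
            if svtype == "INS":
                end = pos
                if svlen is None:
                    log.warning("%s:%s %s: INS without SVLEN, skipped",
                                path.name, rec.chrom, pos)
                    continue
            else:
                end = rec.stop  # pysam: INFO END if present, else POS+rlen-1
                if end <= pos and svlen is not None:
                    end = pos + svlen
            read_support = None
            rsup = _info_get(rec, "RSUP")
            if rsup is not None:
                read_support = int(_scalar(rsup))
            try:
                records.append(SVRecord(contig=rec.chrom, start=pos, end=end,
                                        svtype=svtype, svlen=svlen,
                                        id=rec.id or f"{rec.chrom}_{pos}",
                                        read_support=read_support))
            except ValueError as exc:
                log.warning("%s:%s %s: %s, skipped", path.name, rec.chrom, pos, exc)
    if dropped:
        log.info("%s: dropped unsupported SV types %s", path.name, dropped)
    return CallSet(key=key if key is not None else path.stem, records=records)


_HEADER_INFO = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of supporting input sets">',
    '##INFO=<ID=SUPP_VEC,Number=1,Type=String,Description="Support bit vector over inputs">',
    '##INFO=<ID=RSUP,Number=1,Type=Integer,Description="Supporting reads from genotyping">',
]


def _vcf_header(contigs: dict[str, int], extra: list[str] = ()) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=svfactor"]
    lines.extend(extra)
    lines.extend(_HEADER_INFO)
    for contig, length in contigs.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def _contig_sizes(records, genome: dict[str, int] | None) -> dict[str, int]:
    if genome:
        return dict(genome)
    sizes: dict[str, int] = {}
    for r in records:
        sizes[r.contig] = max(sizes.get(r.contig, 0), r.end + 1_000_000)
    return sizes


def _record_line(r: SVRecord, extra_info: str = "") -> str:
    svlen = r.svlen if r.svlen is not None else r.end - r.start
    if r.svtype == "DEL":
        svlen = -svlen  # VCF convention: deletions carry negative SVLEN
    info = f"SVTYPE={r.svtype};END={r.end};SVLEN={svlen}"
    if r.read_support is not None:
        info += f";RSUP={r.read_support}"
    if extra_info:
        info += ";" + extra_info
    return "\t".join([r.contig, str(r.start), r.id or ".", "N",
                      f"<{r.svtype}>", ".", "PASS", info])


def write_callset_vcf(cs: CallSet, path, genome: dict[str, int] | None = None) -> None:
    """Write a call set as a minimal SV VCF (symbolic ALTs, INFO keys)."""
    records = sorted(cs.records, key=lambda r: (r.contig, r.start, r.end))
    lines = _vcf_header(_contig_sizes(records, genome),
                        [f"##svfactor_callset={cs.label}"])
    lines.extend(_record_line(r) for r in records)
    Path(path).write_text("\n".join(lines) + "\n")


def write_merged_vcf(m: MergedSet, path, genome: dict[str, int] | None = None) -> None:
    """Write a merged set with SUPP/SUPP_VEC, inputs documented in bit order."""
    reps = m.representatives()
    extra = [f"##svfactor_input_{i}={label}" for i, label in enumerate(m.inputs)]
    lines = _vcf_header(_contig_sizes(reps, genome), extra)
    for c in m.clusters:
        lines.append(_record_line(
            c.representative, f"SUPP={c.support};SUPP_VEC={c.support_vector}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_merged_vcf(path) -> tuple[list[str], list[tuple[SVRecord, str]]]:
    """Parse back a merged VCF: (input labels, [(record, supp_vec), ...])."""
    inputs: list[str] = []
    out: list[tuple[SVRecord, str]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for line in str(vcf.header).splitlines():
            if line.startswith("##svfactor_input_"):
                inputs.append(line.split("=", 1)[1])
        for rec in vcf:
            svtype = str(_scalar(rec.info["SVTYPE"]))
            svlen = abs(int(_scalar(rec.info["SVLEN"])))
            end = rec.pos if svtype == "INS" else rec.stop
            record = SVRecord(contig=rec.chrom, start=rec.pos, end=end,
                              svtype=svtype, svlen=svlen, id=rec.id or "")
            out.append((record, str(_scalar(rec.info["SUPP_VEC"]))))
    return inputs, out


def read_bed(path) -> dict[str, IntervalTree]:
    """3-column BED (0-based half-open) -> per-contig interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


MANIFEST_COLUMNS = ["path", "sample", "center", "replicate", "mapper", "postproc"]


def read_manifest(path) -> list[tuple[Path, FactorKey]]:
    """TSV mapping VCF file -> FactorKey; paths resolve relative to the TSV."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.path in seen:
            raise ValueError(f"duplicate manifest path {row.path}")
        seen.add(row.path)
        key = FactorKey(str(row.sample), str(row.center), str(row.replicate),
                        str(row.mapper), str(row.postproc)).validate()
        out.append((base / row.path, key))
    return out


def write_manifest(rows: list[tuple[str, FactorKey]], path) -> None:
    df = pd.DataFrame([{"path": str(p), **key._asdict()} for p, key in rows],
                      columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_callsets(manifest_path) -> dict[FactorKey, CallSet]:
    """Read every call set listed in a manifest."""
    out: dict[FactorKey, CallSet] = {}
    for vcf_path, key in read_manifest(manifest_path):
        if not vcf_path.exists():
            raise FileNotFoundError(f"manifest entry does not exist: {vcf_path}")
        out[key] = read_sv_vcf(vcf_path, key)
    return out
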