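"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversions to
1-based happen only at the VCF boundary.  Every table writer embeds a
metadata header (tool version, seed, parameters) as ``#``-comment lines
so a rerun with identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .svfilter import SVRecord


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; sequences uppercased, IUPAC codes
    preserved.  Duplicate ids or empty records are errors."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_catalog_bed(path: str | Path, pad: int = 0) -> pd.DataFrame:
    """Repeat catalog from BED (0-based half-open; motif in column 4).

    Optional symmetric padding of ``pad`` bp widens each interval on both
    sides (floored at 0).  Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, motif = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer interval") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if not motif.isalpha():
                raise ValueError(f"{path}:{lineno}: motif must be alphabetic")
            rows.append(
                {
                    "chrom": chrom,
                    "start": max(0, start - pad),
                    "end": end + pad,
                    "motif": motif.upper(),
                    "locus_id": f"{chrom}:{start}-{end}",
                }
            )
    return pd.DataFrame(rows)


def read_vcf_minimal(path: str | Path) -> list[SVRecord]:
    """SV records from a minimal VCF 4.2 subset.

    Parses SVTYPE/SVLEN/END from INFO and GT/AD from the first sample;
    multiallelic records are rejected.  VCF 1-based POS becomes internal
    0-based.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"multiallelic or ALT-less record at {rec.chrom}:{rec.pos}")
            info = rec.info
            svtype = info.get("SVTYPE")
            svlen = info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype is None:
                svlen = len(rec.alts[0]) - len(rec.ref)
                svtype = "INS" if svlen > 0 else "DEL"
            if svlen is None:
                svlen = (rec.stop - rec.start) * (-1 if svtype == "DEL" else 1)
            pos = rec.start  # pysam is already 0-based
            # SVLEN is the span authority: internal DEL interval is
            # [pos, pos + |svlen|), INS has zero reference span
            end = pos + abs(int(svlen)) if svtype == "DEL" else pos
            gt, ad = "./.", 0.0
            if rec.samples:
                sample = rec.samples[0]
                gt_tuple = sample.get("GT")
                if gt_tuple and None not in gt_tuple:
                    gt = "/".join(str(a) for a in sorted(gt_tuple))
                ad_val = sample.get("AD")
                if ad_val is not None:
                    ad = float(ad_val[-1] if isinstance(ad_val, tuple) else ad_val)
            records.append(
                SVRecord(
                    chrom=rec.chrom,
                    pos=pos,
                    end=end,
                    svtype=str(svtype),
                    svlen=int(svlen),
                    allele_depth=ad,
                    genotype=gt,
                    record_id=rec.id or f"{rec.chrom}_{pos}",
                )
            )
    return records


def write_vcf_minimal(
    records: list[SVRecord], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write SV records as an uncompressed minimal VCF 4.2 file."""
    contigs = sorted({r.chrom for r in records})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=locuskit {__version__}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=1,Type=Float,Description="Alt allele depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for r in records:
        info = f"SVTYPE={r.svtype};SVLEN={r.svlen};END={max(r.end, r.pos + 1)}"
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos + 1),
                    r.record_id or ".",
                    "N",
                    f"<{r.svtype}>",
                    ".",
                    "PASS",
                    info,
                    "GT:AD",
                    f"{r.genotype}:{r.allele_depth:g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    params: dict | None = None,
) -> None:
    """TSV with a reproducibility metadata header (version, seed,
    parameter hash) as comment lines."""
    header = [f"# locuskit={__version__}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if params:
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        header.append(f"# params_sha256={digest}")
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text("\n".join(header) + "\n" + buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
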