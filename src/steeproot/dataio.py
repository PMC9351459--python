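"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 (per-sample DP/DV FORMAT fields) through pysam, GFF3 gene
models through gffutils, FASTA through Biopython, tables as CSV/TSV
through pandas, intervals as BED, summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bsa import LinkageInterval
from .mutations import GeneModel


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    panel: pd.DataFrame,
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a variant panel (chrom/pos/ref/alt/qual + DP_/DV_ columns) as VCF v4.2."""
    header = pysam.VariantHeader()
    contigs = (
        dict(contig_lengths)
        if contig_lengths is not None
        else {c: int(g["pos"].max()) + 1 for c, g in panel.groupby("chrom", sort=True)}
    )
    for c, length in contigs.items():
        header.contigs.add(c, length=length)
    header.formats.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("DV", 1, "Integer", "Number of non-reference reads at the site")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in panel.iterrows():
            rec = vcf.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
                qual=float(row["qual"]),
            )
            for s in samples:
                rec.samples[s]["DP"] = int(row[f"DP_{s}"])
                rec.samples[s]["DV"] = int(row[f"DV_{s}"])
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a VCF with per-sample DP/DV into the panel DataFrame layout."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "qual": rec.qual,
            }
            for s in samples:
                row[f"DP_{s}"] = rec.samples[s]["DP"]
                row[f"DV_{s}"] = rec.samples[s]["DV"]
            rows.append(row)
    return pd.DataFrame(rows), samples


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tsteeproot\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\tsteeproot\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tsteeproot\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}"
            )
        # phase of each CDS piece follows the cumulative length in transcription order
        cds = g.cds if g.strand == "+" else tuple(reversed(g.cds))
        done = 0
        phased = []
        for s, e in cds:
            phased.append((s, e, (3 - done % 3) % 3))
            done += e - s + 1
        for s, e, phase in sorted(phased):
            lines.append(
                f"{g.chrom}\tsteeproot\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            (f.start, f.end) for f in db.children(g, featuretype="exon", order_by="start")
        )
        cds = tuple(
            (f.start, f.end) for f in db.children(g, featuretype="CDS", order_by="start")
        )
        genes.append(GeneModel(g.id, g.seqid, g.strand, exons or ((g.start, g.end),), cds))
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# tables, intervals, summaries
# ---------------------------------------------------------------------------

def write_polylines(polylines: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Polyline CSV: root_id, root_class, point_index, x, y, z."""
    frames = []
    for rid, df in polylines.items():
        f = df[["x", "y", "z"]].copy()
        f.insert(0, "point_index", range(len(f)))
        f.insert(0, "root_class", df.attrs.get("root_class", "seminal"))
        f.insert(0, "root_id", rid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_polylines(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    out = {}
    for rid, g in df.groupby("root_id", sort=False):
        g = g.sort_values("point_index")
        pts = g[["x", "y", "z"]].reset_index(drop=True)
        pts.attrs["root_class"] = str(g["root_class"].iloc[0])
        out[str(rid)] = pts
    return out


def write_force_curves(curves: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Force-curve CSV: curve_id, z_nm, force_pN."""
    frames = []
    for cid, df in curves.items():
        f = df[["z_nm", "force_pN"]].copy()
        f.insert(0, "curve_id", cid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_force_curves(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    return {
        str(cid): g[["z_nm", "force_pN"]].reset_index(drop=True)
        for cid, g in df.groupby("curve_id", sort=False)
    }


def write_interval_bed(interval: LinkageInterval | None, path: str | Path) -> None:
    """Linked interval as BED (0-based half-open); empty file when no linkage."""
    if interval is None:
        Path(path).write_text("")
        return
    Path(path).write_text(
        f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t"
        f"{interval.peak_marker_id}\t{interval.peak_delta_theta:.4f}\n"
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if hasattr(o, "__dict__"):
        return o.__dict__
    if hasattr(o, "_asdict"):
        return o._asdict()
    if hasattr(o, "tolist"):
        return o.tolist()
    return str(o)
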