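"""Reading annotated genomes (GenBank, FASTA+GFF3) and writing repeat calls.

Internal coordinates are 0-based half-open. GFF3 output is 1-based inclusive,
BED output 0-based half-open, each matching its format standard exactly.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, GeneFeature, Group
from .repeats import InvertedRepeat, Repeat, TandemRepeat, repeat_kind

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(qualifiers: dict) -> str:
    for key in ("gene", "product", "locus_tag", "Name", "ID"):
        if key in qualifiers:
            v = qualifiers[key]
            return v[0] if isinstance(v, list) else v
    return "unknown"


def _genbank_features(record, length: int) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for f in record.features:
        kind = _KIND_MAP.get(f.type)
        if kind is None:
            continue
        name = _feature_name(f.qualifiers)
        strand = "-" if f.location.strand == -1 else "+"
        parts = getattr(f.location, "parts", [f.location])
        # a compound location crossing the origin is split on ingest; the
        # parts share a locus tag so downstream code can re-associate them
        tag = name if len(parts) > 1 else None
        for p in parts:
            start, end = int(p.start), int(p.end)
            if start >= end:
                continue
            feats.append(
                GeneFeature(name=name, kind=kind, start=start, end=end,
                            strand=strand, locus_tag=tag)
            )
    return feats


def _parse_gff3_features(path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line does not have 9 columns")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            kind = _KIND_MAP.get(ftype)
            if kind is None:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if s < 0 or e <= s:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}..{end}")
            feats.append(
                GeneFeature(
                    name=attr.get("Name") or attr.get("gene") or attr.get("ID", "unknown"),
                    kind=kind,
                    start=s,
                    end=e,
                    strand="-" if strand == "-" else "+",
                    locus_tag=attr.get("locus_tag"),
                )
            )
    return feats


def read_genome(
    path,
    format: str | None = None,
    group: str | Group = Group.OTHER,
    gff3=None,
    circular: bool = True,
) -> AnnotatedGenome:
    """Read an annotated genome from GenBank or a FASTA+GFF3 pair.

    `format` is "genbank" or "fasta+gff3"; inferred from the extension when
    omitted. For FASTA+GFF3 the annotation file is given via `gff3` (an empty
    or missing annotation yields zero features).
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        if ext in (".gb", ".gbk", ".gbff", ".genbank"):
            format = "genbank"
        elif ext in (".fa", ".fasta", ".fna"):
            format = "fasta+gff3"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")

    if format == "genbank":
        record = SeqIO.read(str(path), "genbank")
        length = len(record.seq)
        feats = _genbank_features(record, length)
        topology = record.annotations.get("topology", "")
        circ = circular if topology == "" else (topology == "circular")
        return AnnotatedGenome(
            id=record.id or path.stem, sequence=str(record.seq),
            circular=circ, features=feats, group=group,
        )
    if format == "fasta+gff3":
        record = SeqIO.read(str(path), "fasta")
        feats = _parse_gff3_features(gff3) if gff3 and os.path.exists(gff3) else []
        g = AnnotatedGenome(
            id=record.id or path.stem, sequence=str(record.seq),
            circular=circular, features=feats, group=group,
        )
        return g
    raise ValueError(f"unknown format {format!r}")


def write_genome(g: AnnotatedGenome, fasta_path, gff3_path=None) -> None:
    """Write a genome as FASTA plus (optionally) a GFF3 annotation file."""
    rec = SeqRecord(Seq(g.sequence), id=g.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    if gff3_path is None:
        return
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
        for f in g.features:
            attrs = f"ID={f.name};Name={f.name}"
            if f.locus_tag:
                attrs += f";locus_tag={f.locus_tag}"
            fh.write(
                f"{g.id}\tplastrep\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_group_table(path) -> dict[str, Group]:
    """TSV of accession -> group label; unknown genomes default to 'other'."""
    table: dict[str, Group] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = Group(row[1])
    return table


# ---------------------------------------------------------------------------
# repeat output / input

_TSV_FIELDS = [
    "genome", "repeat_id", "type", "start", "end", "arm1_start", "arm1_end",
    "arm2_start", "arm2_end", "stem_len", "loop_len", "mismatches", "gaps",
    "period", "copies", "consensus", "score",
]


def _repeat_rows(repeats, genome_id: str):
    for i, r in enumerate(repeats):
        rid = f"{repeat_kind(r)[:3]}{i + 1}"
        row = dict.fromkeys(_TSV_FIELDS, "")
        row.update(genome=genome_id, repeat_id=rid, type=repeat_kind(r),
                   start=r.start, end=r.end, score=r.score)
        if isinstance(r, InvertedRepeat):
            row.update(arm1_start=r.arm1_start, arm1_end=r.arm1_end,
                       arm2_start=r.arm2_start, arm2_end=r.arm2_end,
                       stem_len=r.stem_len, loop_len=r.loop_len,
                       mismatches=r.mismatches, gaps=r.gaps)
        else:
            row.update(period=r.period, copies=f"{r.copies:.2f}",
                       consensus=r.consensus)
        yield rid, row, r


def write_repeats(repeats, path, format: str = "tsv", genome_id: str = "genome") -> None:
    """Write repeat calls as GFF3 (one line per IR arm), BED, or TSV."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_TSV_FIELDS, delimiter="\t")
            w.writeheader()
            for _, row, _r in _repeat_rows(repeats, genome_id):
                w.writerow(row)
        return

    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rid, _, r in _repeat_rows(repeats, genome_id):
                if isinstance(r, InvertedRepeat):
                    common = (f"stem={r.stem_len};loop={r.loop_len};"
                              f"mismatches={r.mismatches};gaps={r.gaps}")
                    for arm, (s, e) in (("arm1", (r.arm1_start, r.arm1_end)),
                                        ("arm2", (r.arm2_start, r.arm2_end))):
                        fh.write(
                            f"{genome_id}\tplastrep\tinverted_repeat\t{s + 1}\t{e}"
                            f"\t{r.score}\t+\t.\tID={rid}.{arm};Parent={rid};{common}\n"
                        )
                else:
                    fh.write(
                        f"{genome_id}\tplastrep\ttandem_repeat\t{r.start + 1}\t{r.end}"
                        f"\t{r.score}\t+\t.\tID={rid};period={r.period};"
                        f"copies={r.copies:.2f};consensus={r.consensus}\n"
                    )
        return

    if format == "bed":
        with open(path, "w") as fh:
            for rid, _, r in _repeat_rows(repeats, genome_id):
                if isinstance(r, InvertedRepeat):
                    fh.write(f"{genome_id}\t{r.arm1_start}\t{r.arm1_end}\t{rid}.arm1\t{r.score}\t+\n")
                    fh.write(f"{genome_id}\t{r.arm2_start}\t{r.arm2_end}\t{rid}.arm2\t{r.score}\t+\n")
                else:
                    fh.write(f"{genome_id}\t{r.start}\t{r.end}\t{rid}\t{r.score}\t+\n")
        return

    raise ValueError(f"unknown repeat output format {format!r}")


def read_repeats(path, format: str = "tsv") -> list[Repeat]:
    """Re-read repeat calls written by write_repeats (tsv or gff3)."""
    path = Path(path)
    out: list[Repeat] = []
    if format == "tsv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row["type"] == "inverted_repeat":
                    out.append(InvertedRepeat(
                        arm1_start=int(row["arm1_start"]), arm1_end=int(row["arm1_end"]),
                        arm2_start=int(row["arm2_start"]), arm2_end=int(row["arm2_end"]),
                        mismatches=int(row["mismatches"]), gaps=int(row["gaps"]),
                        score=int(row["score"]),
                    ))
                else:
                    out.append(TandemRepeat(
                        start=int(row["start"]), end=int(row["end"]),
                        period=int(row["period"]), copies=float(row["copies"]),
                        consensus=row["consensus"], score=int(row["score"]),
                    ))
        return out

    if format == "gff3":
        arms: dict[str, dict] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                attr = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                s, e = int(cols[3]) - 1, int(cols[4])
                if cols[2] == "tandem_repeat":
                    period = int(attr["period"])
                    out.append(TandemRepeat(
                        start=s, end=e, period=period, copies=float(attr["copies"]),
                        consensus=attr["consensus"], score=int(float(cols[5])),
                    ))
                else:
                    rid = attr["Parent"]
                    d = arms.setdefault(rid, {"attr": attr, "score": int(float(cols[5]))})
                    d[attr["ID"].rsplit(".", 1)[1]] = (s, e)
        for rid in sorted(arms, key=lambda k: arms[k]["arm1"][0]):
            d = arms[rid]
            out.append(InvertedRepeat(
                arm1_start=d["arm1"][0], arm1_end=d["arm1"][1],
                arm2_start=d["arm2"][0], arm2_end=d["arm2"][1],
                mismatches=int(d["attr"]["mismatches"]), gaps=int(d["attr"]["gaps"]),
                score=d["score"],
            ))
        out.sort(key=lambda r: (r.start, r.end))
        return out

    raise ValueError(f"unknown repeat input format {format!r}")


def fetch_genbank(accession: str, email: str, dest_dir=".") -> Path:
    """Thin optional helper: download one GenBank record from NCBI (network)."""
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nucleotide", id=accession, rettype="gbwithparts",
                       retmode="text") as handle:
        text = handle.read()
    dest = Path(dest_dir) / f"{accession}.gb"
    dest.write_text(text)
    return dest
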