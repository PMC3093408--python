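"""Readers and writers for every external format the pipeline touches.

Formats
-------
* chain table — this package's own TSV dialect for provirus-screening output
  (one row per chain, sub-features as typed columns); coordinates in the file
  are 1-based inclusive, converted to 0-based half-open on read
* gene annotation — GFF3 or BED12
* repeat annotation — RepeatMasker ``.out`` or BED6 (name field
  ``repname#repclass``)
* assembly structure — AGP v1.1 / v2.0
* chromosome sizes — two-column TSV (UCSC ``chrom.sizes``)
* sequences — FASTA via Biopython

Every writer/reader pair round-trips losslessly on files the writer
produced.  All in-memory coordinates are 0-based half-open; conversion
happens exactly once, here.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    PUTEIN_GENES,
    AgpComponent,
    AgpGap,
    ChainTable,
    GenomeIndex,
    LTRFeature,
    ProviralChain,
    Putein,
    RepeatInterval,
    TranscriptRecord,
)

MISSING = "."

_CHAIN_COLUMNS = [
    "id",
    "chromosome",
    "start",
    "end",
    "strand",
    "score",
    "genus",
    "pbs",
    "ltr5_start",
    "ltr5_end",
    "ltr3_start",
    "ltr3_end",
    "gag",
    "pro",
    "pol",
    "env",
]


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# chain table
# ---------------------------------------------------------------------------

def read_chain_table(path: str | os.PathLike) -> ChainTable:
    """Read a provirus chain table from the package's TSV dialect.

    The file holds one row per chain.  Coordinates (chain span and LTR
    spans) are 1-based inclusive in the file and converted to 0-based
    half-open here.  Putein columns (gag/pro/pol/env) hold one or more
    amino-acid sequences separated by ``;``, or ``.`` when the gene was not
    annotated.  A ``#genome=<id>`` comment line carries the assembly name.
    """
    genome_id = ""
    rows: list[ProviralChain] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome="):
                    genome_id = line[len("#genome="):]
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _CHAIN_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        path, lineno, f"header lacks columns {missing}"
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    path,
                    lineno,
                    f"expected {len(header)} columns, found {len(fields)}",
                )
            rec = dict(zip(header, fields))
            try:
                rows.append(_parse_chain_row(rec))
            except (ValueError, KeyError) as exc:
                raise FormatError(path, lineno, str(exc)) from exc
    return ChainTable(rows=rows, genome_id=genome_id)


def _parse_chain_row(rec: Mapping[str, str]) -> ProviralChain:
    strand = rec["strand"]
    if strand not in {"+", "-"}:
        raise ValueError(f"unknown strand symbol {strand!r}")
    start = int(rec["start"]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(rec["end"])
    puteins = []
    for gene in PUTEIN_GENES:
        cell = rec.get(gene, MISSING)
        if cell != MISSING and cell != "":
            for seq in cell.split(";"):
                puteins.append(Putein(gene=gene, sequence=seq))
    ltr5 = _parse_ltr(rec, "ltr5")
    ltr3 = _parse_ltr(rec, "ltr3")
    pbs = rec.get("pbs", MISSING)
    return ProviralChain(
        id=int(rec["id"]),
        chromosome=rec["chromosome"],
        start=start,
        end=end,
        strand=strand,
        score=float(rec["score"]),
        genus=rec["genus"],
        puteins=puteins,
        ltr5=ltr5,
        ltr3=ltr3,
        pbs=None if pbs == MISSING else pbs,
    )


def _parse_ltr(rec: Mapping[str, str], prefix: str) -> LTRFeature | None:
    s, e = rec.get(f"{prefix}_start", MISSING), rec.get(f"{prefix}_end", MISSING)
    if s == MISSING or e == MISSING:
        return None
    return LTRFeature(start=int(s) - 1, end=int(e))


def write_chain_table(table: ChainTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        if table.genome_id:
            fh.write(f"#genome={table.genome_id}\n")
        fh.write("\t".join(_CHAIN_COLUMNS) + "\n")
        for c in table.rows:
            by_gene: dict[str, list[str]] = {g: [] for g in PUTEIN_GENES}
            for p in c.puteins:
                by_gene[p.gene].append(p.sequence)
            cells = [
                str(c.id),
                c.chromosome,
                str(c.start + 1),
                str(c.end),
                c.strand,
                _fmt_num(c.score),
                c.genus,
                c.pbs if c.pbs is not None else MISSING,
            ]
            for ltr in (c.ltr5, c.ltr3):
                if ltr is None:
                    cells += [MISSING, MISSING]
                else:
                    cells += [str(ltr.start + 1), str(ltr.end)]
            for gene in PUTEIN_GENES:
                cells.append(";".join(by_gene[gene]) or MISSING)
            fh.write("\t".join(cells) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / BED12)
# ---------------------------------------------------------------------------

def read_gff_genes(
    path: str | os.PathLike, dialect: str | None = None
) -> list[TranscriptRecord]:
    """Read transcript records from GFF3 or BED12.

    The dialect is auto-detected from the extension (``.gff``/``.gff3`` vs
    ``.bed``) unless ``dialect`` is given explicitly.  GFF 1-based closed
    coordinates are converted to 0-based half-open.  Transcripts are
    grouped by their parent gene; a transcript without a parent gene is
    grouped under its own id with a warning.
    """
    if dialect is None:
        ext = os.path.splitext(str(path))[1].lower()
        dialect = "bed12" if ext == ".bed" else "gff3"
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect != "gff3":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _read_gff3(path)


def _read_gff3(path: str | os.PathLike) -> list[TranscriptRecord]:
    with open(path) as fh:
        body = fh.read()
    if not any(
        line and not line.startswith("#") for line in body.splitlines()
    ):
        return []
    db = gffutils.create_db(
        body,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[TranscriptRecord] = []
    for tx in db.features_of_type(("mRNA", "transcript", "ncRNA")):
        parents = tx.attributes.get("Parent", [])
        if parents:
            gene_id = parents[0]
        else:
            warnings.warn(
                f"transcript {tx.id} has no parent gene; grouping by its own id"
            )
            gene_id = tx.id
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="CDS")
        )
        records.append(
            TranscriptRecord(
                gene_id=gene_id,
                transcript_id=tx.id,
                chromosome=tx.seqid,
                strand=tx.strand,
                start=tx.start - 1,
                end=tx.end,
                exons=exons,
                cds=cds,
            )
        )
    return records


def write_gff_genes(
    transcripts: Iterable[TranscriptRecord], path: str | os.PathLike
) -> None:
    """Write transcripts as GFF3 (gene/mRNA/exon/CDS hierarchy)."""
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            gs = min(t.start for t in txs)
            ge = max(t.end for t in txs)
            chrom, strand = txs[0].chromosome, txs[0].strand
            fh.write(
                f"{chrom}\tervscape\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for tx in txs:
                fh.write(
                    f"{tx.chromosome}\tervscape\tmRNA\t{tx.start + 1}\t{tx.end}"
                    f"\t.\t{tx.strand}\t.\tID={tx.transcript_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(tx.exons, 1):
                    fh.write(
                        f"{tx.chromosome}\tervscape\texon\t{s + 1}\t{e}\t.\t"
                        f"{tx.strand}\t.\tID={tx.transcript_id}.exon{i};"
                        f"Parent={tx.transcript_id}\n"
                    )
                for i, (s, e) in enumerate(tx.cds, 1):
                    fh.write(
                        f"{tx.chromosome}\tervscape\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{tx.strand}\t0\tID={tx.transcript_id}.cds{i};"
                        f"Parent={tx.transcript_id}\n"
                    )


def _read_bed12(path: str | os.PathLike) -> list[TranscriptRecord]:
    records: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(path, lineno, "BED12 requires 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(path, lineno, "block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = [
                (max(s, thick_s), min(e, thick_e))
                for s, e in exons
                if max(s, thick_s) < min(e, thick_e)
            ]
            gene_id, _, tx_id = name.partition("|")
            records.append(
                TranscriptRecord(
                    gene_id=gene_id,
                    transcript_id=tx_id or name,
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
    return records


def write_bed12_genes(
    transcripts: Iterable[TranscriptRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            exons = tx.exons or [(tx.start, tx.end)]
            if tx.cds:
                thick_s = min(s for s, _ in tx.cds)
                thick_e = max(e for _, e in tx.cds)
            else:
                thick_s = thick_e = tx.start
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - tx.start) for s, _ in exons)
            fh.write(
                "\t".join(
                    [
                        tx.chromosome,
                        str(tx.start),
                        str(tx.end),
                        f"{tx.gene_id}|{tx.transcript_id}",
                        "0",
                        tx.strand,
                        str(thick_s),
                        str(thick_e),
                        "0",
                        str(len(exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

_REPEAT_CLASSES = ("SINE", "LINE", "LTR", "Simple_repeat")


def normalize_repeat_class(raw: str) -> str:
    """Map a RepeatMasker class/family string onto the coarse classes used
    by the gap analysis: SINE, LINE, LTR, Simple_repeat or Other."""
    base = raw.split("/")[0].strip()
    for cls in _REPEAT_CLASSES:
        if base.lower() == cls.lower() or base.lower().startswith(cls.lower()):
            return cls
    warnings.warn(f"unrecognized repeat class {raw!r}; mapping to Other")
    return "Other"


def read_repeat_track(
    path: str | os.PathLike, dialect: str | None = None
) -> list[RepeatInterval]:
    """Read repeat intervals from RepeatMasker ``.out`` or BED6.

    BED name field is expected as ``repname#repclass`` (class alone also
    accepted).  ``.out`` coordinates are 1-based inclusive; BED is 0-based
    half-open already.
    """
    if dialect is None:
        ext = os.path.splitext(str(path))[1].lower()
        dialect = "bed" if ext == ".bed" else "rmout"
    if dialect == "bed":
        return _read_repeat_bed(path)
    if dialect != "rmout":
        raise ValueError(f"unknown dialect {dialect!r}")
    repeats: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith(("sw", "score", "there")):
                continue
            f = line.split()
            if len(f) < 11:
                raise FormatError(path, lineno, "short RepeatMasker row")
            try:
                start = int(f[5]) - 1
                end = int(f[6])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            strand = "-" if f[8] == "C" else "+"
            repeats.append(
                RepeatInterval(
                    chromosome=f[4],
                    start=start,
                    end=end,
                    repeat_class=normalize_repeat_class(f[10]),
                    name=f[9],
                    strand=strand,
                )
            )
    return repeats


def _read_repeat_bed(path: str | os.PathLike) -> list[RepeatInterval]:
    repeats: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(path, lineno, "repeat BED requires >=4 columns")
            name, _, cls = f[3].partition("#")
            if not cls:
                name, cls = "", name
            repeats.append(
                RepeatInterval(
                    chromosome=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    repeat_class=normalize_repeat_class(cls),
                    name=name,
                    strand=f[5] if len(f) > 5 else "+",
                )
            )
    return repeats


def write_repeat_bed(
    repeats: Iterable[RepeatInterval], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}#{r.repeat_class}"
                f"\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

_AGP_GAP_CODES = {"N", "U"}


def read_agp(path: str | os.PathLike) -> list[AgpComponent | AgpGap]:
    """Read AGP v1.1 or v2.0 rows.

    Object coordinates (columns 2-3, 1-based inclusive) are converted to
    0-based half-open.  ``N`` rows are gaps of known size, ``U`` rows gaps
    of unknown size (v2.0); both are returned as :class:`AgpGap`.
    """
    rows: list[AgpComponent | AgpGap] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(
                    path, lineno, f"AGP requires >=8 columns, found {len(f)}"
                )
            obj, obj_beg, obj_end, _part, comp_type = f[0], f[1], f[2], f[3], f[4]
            try:
                start = int(obj_beg) - 1
                end = int(obj_end)
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if comp_type in _AGP_GAP_CODES:
                rows.append(
                    AgpGap(
                        chromosome=obj,
                        start=start,
                        end=end,
                        gap_type=f[6].lower(),
                        sized=comp_type == "N",
                    )
                )
            else:
                if len(f) < 9:
                    raise FormatError(
                        path, lineno, "component row requires 9 columns"
                    )
                rows.append(
                    AgpComponent(
                        chromosome=obj,
                        start=start,
                        end=end,
                        component_id=f[5],
                        orientation=f[8],
                    )
                )
    return rows


def write_agp(rows: Iterable[AgpComponent | AgpGap], path: str | os.PathLike) -> None:
    part_no: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        for r in rows:
            part_no[r.chromosome] = part_no.get(r.chromosome, 0) + 1
            common = [r.chromosome, str(r.start + 1), str(r.end), str(part_no[r.chromosome])]
            if isinstance(r, AgpGap):
                code = "N" if r.sized else "U"
                fh.write(
                    "\t".join(
                        common + [code, str(r.length), r.gap_type, "yes", "align_genus"]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        common
                        + ["W", r.component_id, "1", str(r.end - r.start), r.orientation]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# genome index & FASTA
# ---------------------------------------------------------------------------

def read_genome_index(path: str | os.PathLike) -> GenomeIndex:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(path, lineno, "expected name<TAB>length")
            if f[0] in lengths:
                raise FormatError(path, lineno, f"duplicate chromosome {f[0]!r}")
            lengths[f[0]] = int(f[1])
    return GenomeIndex(lengths)


def write_genome_index(index: GenomeIndex, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in index.items():
            fh.write(f"{name}\t{length}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def ltr_fasta_key(chain_id: int, which: str) -> str:
    """FASTA record id for a chain's 5' or 3' LTR sequence."""
    if which not in {"5", "3"}:
        raise ValueError("which must be '5' or '3'")
    return f"chain{chain_id}_LTR{which}"


def attach_ltr_sequences(table: ChainTable, seqs: Mapping[str, str]) -> ChainTable:
    """Attach LTR sequences from a FASTA mapping onto a chain table's LTR
    features (in place); returns the table for chaining."""
    for chain in table:
        for which, ltr in (("5", chain.ltr5), ("3", chain.ltr3)):
            if ltr is None:
                continue
            key = ltr_fasta_key(chain.id, which)
            if key in seqs:
                ltr.sequence = seqs[key]
    return table
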