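"""Annotated-genome and alignment I/O.

Provides the gene-order data model every downstream stage of the census
consumes: contigs plus ordered, stranded gene records with protein
translations (bacterial code, table 11), multiple-alignment containers, and
the tab-separated locus report emulating a supplementary locus table.

Coordinates are GFF3-native throughout: 1-based, inclusive, ``end >= start``.
Contigs are treated as independent sequences; loci never span contigs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from urllib.parse import unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("comcensus")

ROLES = ("ComQ", "ComX", "ComP", "ComA")

#: 20 standard amino acids, fixed ordering used for all emission vectors.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(dna: str, strand: str = "+") -> str:
    """Translate a CDS with the bacterial table (11), trailing stop removed.

    The sequence is trimmed to a codon multiple; internal stops (if any)
    are kept as ``*`` so malformed records remain visible downstream.
    """
    if strand == "-":
        dna = reverse_complement(dna)
    dna = dna[: len(dna) - len(dna) % 3]
    prot = str(Seq(dna).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass
class GeneRecord:
    """One annotated CDS on a contig.

    ``irregular`` marks records whose span is not ``3*len(protein) + 3``
    (partial CDSs on draft contigs); they are retained and scanned.
    """

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, end >= start
    strand: str  # '+' or '-'
    protein: str
    index_on_contig: int = -1
    irregular: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def sort_and_index(self) -> None:
        """Sort genes by (contig, start) and refresh ``index_on_contig``."""
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
        counters: dict[str, int] = {}
        for g in self.genes:
            g.index_on_contig = counters.get(g.contig_id, 0)
            counters[g.contig_id] = g.index_on_contig + 1

    def genes_on(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}")
            if not (1 <= g.start <= g.end <= len(self.contigs[g.contig_id])):
                raise ValueError(f"gene {g.gene_id!r} coordinates outside contig {g.contig_id!r}")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, val = part.split("=", 1)
        out[key.strip()] = unquote(val.strip())
    return out


def read_annotated_genome(gff_path: str | Path, fasta_path: str | Path,
                          genome_id: str | None = None) -> AnnotatedGenome:
    """Read paired GFF3 + nucleotide FASTA into an :class:`AnnotatedGenome`.

    Only CDS features are consumed. A CDS whose seqid has no FASTA contig is
    a hard error; an unparsable feature line is skipped with a warning.
    Translations use the bacterial code; CDSs whose span is not a codon
    multiple (+stop) are flagged ``irregular`` but retained.
    """
    gff_path = Path(gff_path)
    fasta_path = Path(fasta_path)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if genome_id is None:
        genome_id = gff_path.stem
    genome = AnnotatedGenome(genome_id=genome_id, contigs=contigs)
    auto = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                logger.warning("%s:%d: unparsable feature line skipped", gff_path.name, lineno)
                continue
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-numeric coordinates skipped", gff_path.name, lineno)
                continue
            if strand not in "+-" or end < start:
                logger.warning("%s:%d: bad strand/coordinates skipped", gff_path.name, lineno)
                continue
            if seqid not in contigs:
                raise ValueError(
                    f"{gff_path.name}:{lineno}: CDS references seqid {seqid!r} "
                    f"absent from {fasta_path.name}")
            attrs = _parse_gff_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                auto += 1
                gene_id = f"{genome_id}_cds{auto:04d}"
            dna = contigs[seqid][start - 1:end]
            span = end - start + 1
            irregular = span % 3 != 0
            protein = translate_cds(dna, strand)
            genome.genes.append(GeneRecord(
                gene_id=gene_id, contig_id=seqid, start=start, end=end,
                strand=strand, protein=protein, irregular=irregular))
    genome.sort_and_index()
    genome.validate()
    return genome


def write_genome(genome: AnnotatedGenome, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit a genome as deterministic GFF3 + FASTA (byte-stable for a fixed input)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff = out_dir / f"{genome.genome_id}.gff3"
    fna = out_dir / f"{genome.genome_id}.fna"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted(genome.contigs):
            fh.write(f"##sequence-region {cid} 1 {len(genome.contigs[cid])}\n")
        for g in genome.genes:
            fh.write("\t".join([
                g.contig_id, "comcensus", "CDS", str(g.start), str(g.end),
                ".", g.strand, "0", f"ID={g.gene_id}"]) + "\n")
    with open(fna, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return gff, fna


# ---------------------------------------------------------------------------
# Multiple alignments
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """Aligned amino-acid rows; gap normalized to ``-``, upper case."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = [n for n, r in zip(self.names, self.rows) if len(r) != len(self.rows[0])]
            raise ValueError(f"ragged alignment; offending row(s): {bad}")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


_MSA_FORMATS = {"afa": "fasta", "stockholm": "stockholm"}


def read_msa(path: str | Path, format: str = "afa") -> Msa:
    if format not in _MSA_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}; use 'afa' or 'stockholm'")
    records = list(SeqIO.parse(str(path), _MSA_FORMATS[format]))
    return Msa(names=[r.id for r in records], rows=[str(r.seq) for r in records])


def write_msa(msa: Msa, path: str | Path, format: str = "afa") -> None:
    if format not in _MSA_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    with open(path, "w") as fh:
        if format == "afa":
            for n, r in zip(msa.names, msa.rows):
                fh.write(f">{n}\n{r}\n")
        else:
            fh.write("# STOCKHOLM 1.0\n")
            for n, r in zip(msa.names, msa.rows):
                fh.write(f"{n} {r}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Locus report table
# ---------------------------------------------------------------------------

LOCUS_TABLE_COLUMNS = ["genome_id", "contig_id", "strand", "completeness",
                       "overlap_type", "unusual"]
for _r in ROLES:
    LOCUS_TABLE_COLUMNS += [f"{_r}_id", f"{_r}_start", f"{_r}_end", f"{_r}_strand"]


def write_locus_table(loci: Iterable, path: str | Path) -> None:
    """Write one row per locus as TSV, deterministically ordered.

    Accepts :class:`comcensus.census.ComLocus` objects (anything with the
    same attribute surface works). Missing roles leave empty cells.
    """
    rows = []
    for loc in loci:
        row: dict[str, object] = {
            "genome_id": loc.genome_id, "contig_id": loc.contig_id,
            "strand": loc.strand, "completeness": loc.completeness,
            "overlap_type": loc.overlap_type, "unusual": loc.unusual,
        }
        for role in ROLES:
            g = loc.genes.get(role)
            row[f"{role}_id"] = g.gene_id if g else ""
            row[f"{role}_start"] = g.start if g else ""
            row[f"{role}_end"] = g.end if g else ""
            row[f"{role}_strand"] = g.strand if g else ""
        row["_sort"] = min((g.start for g in loc.genes.values()), default=0)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS + ["_sort"])
    frame = frame.sort_values(["genome_id", "contig_id", "_sort"]).drop(columns="_sort")
    frame.to_csv(path, sep="\t", index=False)


def read_locus_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: "string" for c in
                                              ("genome_id", "contig_id", "strand",
                                               "completeness", "overlap_type", "unusual")},
                       keep_default_na=False)
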