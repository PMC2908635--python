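"""Input/output of genomes, gene models, probes and alignment hits.

This module is the coordinate authority for the whole package.  All gene
models are converted at read time into *coding orientation*: for a gene on
the minus strand of a contig of length ``L`` every contig coordinate ``c``
is mirrored to ``L - c + 1`` on the reverse-complemented contig, so that
downstream code never needs to consider strand.  Within that system,

* exon/intron intervals are 1-based inclusive (GFF3 convention),
* each intron carries the pair ``(x, y)`` where ``x`` is the last exonic
  base before the intron and ``y`` the first exonic base after it,
* probes carry a 1-based start on the spliced CDS, and distances are
  counted from the CDS 3' end (``d = cds_length - cds_start + 1``).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IntronRecord",
    "GeneModel",
    "ProbeRecord",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_est_confirmations",
    "write_est_confirmations",
    "read_probe_table",
    "write_probe_table",
    "read_alignment_hits",
    "distance_from_3prime",
    "map_probe",
]

_VALID_BASES = frozenset("ACGT")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class IntronRecord:
    """An intron in coding-orientation coordinates.

    ``x`` is the contig coordinate (coding orientation) of the last
    nucleotide of the exon preceding the intron; ``y`` is the coordinate of
    the first nucleotide following the intron 3' end.  The intron interior
    is therefore ``x+1 .. y-1``.
    """

    x: int
    y: int
    est_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.y <= self.x + 1:
            raise ValueError(f"empty intron: x={self.x}, y={self.y}")


@dataclass(frozen=True)
class GeneModel:
    """A CDS with its exon/intron structure, in coding orientation.

    ``exons`` are transcription-ordered, non-overlapping 1-based inclusive
    intervals on the coding-orientation contig.  ``spliced`` is the spliced
    CDS sequence, ``unspliced`` the contiguous coding-strand genomic
    sequence spanning the gene (first exon base to last exon base).
    """

    cds_id: str
    contig_id: str
    strand: str
    contig_length: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[IntronRecord, ...] = ()
    spliced: str = ""
    unspliced: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.cds_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.cds_id}: gene has no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.cds_id}: inverted exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError(f"{self.cds_id}: exons out of order or overlapping")
            prev_end = e
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.cds_id}: {len(self.introns)} introns for {len(self.exons)} exons"
            )
        for (a, b), intron in zip(self.exons, self.introns):
            if intron.x != b:
                raise ValueError(f"{self.cds_id}: intron x={intron.x} != exon end {b}")
        for (s, e), intron in zip(self.exons[1:], self.introns):
            if intron.y != s:
                raise ValueError(f"{self.cds_id}: intron y={intron.y} != exon start {s}")
        if self.cds_length <= 0:
            raise ValueError(f"{self.cds_id}: zero-length CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """First and last exonic coordinate of the gene (coding orientation)."""
        return self.exons[0][0], self.exons[-1][1]

    def cds_to_coding(self, pos: int) -> int:
        """Map a 1-based spliced-CDS position to a coding-orientation contig coordinate."""
        if not 1 <= pos <= self.cds_length:
            raise ValueError(f"{self.cds_id}: CDS position {pos} outside [1, {self.cds_length}]")
        offset = pos
        for s, e in self.exons:
            n = e - s + 1
            if offset <= n:
                return s + offset - 1
            offset -= n
        raise AssertionError("unreachable")

    def cds_footprint(self, start: int, length: int) -> tuple[tuple[int, int], ...]:
        """Genomic footprint (coding orientation) of a spliced-CDS interval."""
        if length < 1:
            raise ValueError("length must be >= 1")
        coords = [self.cds_to_coding(p) for p in range(start, start + length)]
        pieces: list[list[int]] = []
        for c in coords:
            if pieces and c == pieces[-1][1] + 1:
                pieces[-1][1] = c
            else:
                pieces.append([c, c])
        return tuple((a, b) for a, b in pieces)


@dataclass(frozen=True)
class ProbeRecord:
    """A candidate oligonucleotide probe, identical to the coding strand."""

    probe_id: str
    cds_id: str
    cds_start: int
    sequence: str
    bypass_experimental: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.probe_id}: non-ACGT characters {sorted(bad)}")
        if self.cds_start < 1:
            raise ValueError(f"{self.probe_id}: cds_start must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)

def read_gene_models(
    gff3_path,
    fasta_path,
    est_path=None,
) -> dict[str, GeneModel]:
    """Read gene models from GFF3 + genome FASTA into coding orientation.

    Genes are ``gene`` features with an ``ID`` attribute; exons are ``exon``
    features with a ``Parent`` attribute.  Exon rows of one gene must appear
    in ascending contig order.  EST confirmations, if given, are a TSV with
    columns (cds_id, intron_index, est_confirmed); intron_index is 1-based
    in transcription order.
    """
    genome = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    est = read_est_confirmations(est_path) if est_path else {}
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        cds_id = gene.id
        if gene.seqid not in genome:
            raise ValueError(f"{cds_id}: contig {gene.seqid!r} missing from genome FASTA")
        contig = genome[gene.seqid]
        exon_rows = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon", order_by=None)
        ]
        if not exon_rows:
            raise ValueError(f"{cds_id}: gene has no exon features")
        if any(b[0] <= a[1] for a, b in zip(exon_rows, exon_rows[1:])):
            raise ValueError(f"{cds_id}: exon features out of order or overlapping")
        confirmed = {i for (g, i) in est if g == cds_id and est[(g, i)]}
        models[cds_id] = build_gene_model(
            cds_id,
            gene.seqid,
            gene.strand,
            contig,
            exon_rows,
            est_confirmed_indices=confirmed,
        )
    return models


def build_gene_model(
    cds_id: str,
    contig_id: str,
    strand: str,
    contig_seq: str,
    exons_contig: Sequence[tuple[int, int]],
    est_confirmed_indices: Iterable[int] = (),
) -> GeneModel:
    """Assemble a GeneModel from contig-coordinate exons (ascending order)."""
    L = len(contig_seq)
    if strand == "+":
        exons = [tuple(iv) for iv in exons_contig]
        coding_contig = contig_seq
    elif strand == "-":
        exons = [(L - e + 1, L - s + 1) for s, e in reversed(list(exons_contig))]
        coding_contig = _revcomp(contig_seq)
    else:
        raise ValueError(f"{cds_id}: bad strand {strand!r}")
    confirmed = set(est_confirmed_indices)
    introns = tuple(
        IntronRecord(x=a[1], y=b[0], est_confirmed=(i + 1) in confirmed)
        for i, (a, b) in enumerate(zip(exons, exons[1:]))
    )
    spliced = "".join(coding_contig[s - 1 : e] for s, e in exons)
    g0, g1 = exons[0][0], exons[-1][1]
    unspliced = coding_contig[g0 - 1 : g1]
    return GeneModel(
        cds_id=cds_id,
        contig_id=contig_id,
        strand=strand,
        contig_length=L,
        exons=tuple(exons),
        introns=introns,
        spliced=spliced,
        unspliced=unspliced,
    )


def write_gene_models(models: Mapping[str, GeneModel], gff3_path) -> None:
    """Write gene models back to GFF3 in contig coordinates."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models.values():
            L = gene.contig_length
            if gene.strand == "+":
                exons_contig = list(gene.exons)
            else:
                exons_contig = [(L - e + 1, L - s + 1) for s, e in reversed(gene.exons)]
            gs, ge = exons_contig[0][0], exons_contig[-1][1]
            fh.write(
                f"{gene.contig_id}\tprobesieve\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\t"
                f"ID={gene.cds_id}\n"
            )
            for i, (s, e) in enumerate(exons_contig, 1):
                fh.write(
                    f"{gene.contig_id}\tprobesieve\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={gene.cds_id}.exon{i};Parent={gene.cds_id}\n"
                )


def read_est_confirmations(path) -> dict[tuple[str, int], bool]:
    out: dict[tuple[str, int], bool] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["cds_id", "intron_index", "est_confirmed"]:
            raise ValueError(f"bad EST table header: {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"EST table line {lineno}: expected 3 columns")
            out[(fields[0], int(fields[1]))] = fields[2].strip().lower() in ("1", "true", "yes")
    return out


def write_est_confirmations(models: Mapping[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("cds_id\tintron_index\test_confirmed\n")
        for gene in models.values():
            for i, intron in enumerate(gene.introns, 1):
                fh.write(f"{gene.cds_id}\t{i}\t{str(intron.est_confirmed).lower()}\n")


# ---------------------------------------------------------------------------
# Probe tables

def read_probe_table(path) -> list[ProbeRecord]:
    probes: list[ProbeRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for need in ("probe_id", "cds_id", "cds_start", "sequence"):
            if need not in cols:
                raise ValueError(f"probe table missing column {need!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            bypass = False
            if "bypass_experimental" in cols and len(f) > cols["bypass_experimental"]:
                bypass = f[cols["bypass_experimental"]].strip().lower() in ("1", "true", "yes")
            probes.append(
                ProbeRecord(
                    probe_id=f[cols["probe_id"]],
                    cds_id=f[cols["cds_id"]],
                    cds_start=int(f[cols["cds_start"]]),
                    sequence=f[cols["sequence"]].upper(),
                    bypass_experimental=bypass,
                )
            )
    return probes


def write_probe_table(probes: Iterable[ProbeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tcds_id\tcds_start\tsequence\tbypass_experimental\n")
        for p in probes:
            fh.write(
                f"{p.probe_id}\t{p.cds_id}\t{p.cds_start}\t{p.sequence}\t"
                f"{str(p.bypass_experimental).lower()}\n"
            )


# ---------------------------------------------------------------------------
# Tabular alignment hits (12-column, BLAST outfmt-6 layout)

def read_alignment_hits(path, probe_targets: Mapping[str, str]):
    """Parse 12-column tabular alignment hits.

    Columns: query, subject, % identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value, bit score.  Hits whose
    subject equals the query probe's own target CDS are flagged as target
    hits.  ``probe_targets`` maps probe_id -> target cds_id.
    """
    from .crosshyb import AlignmentHit

    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                probe_id, subject = fields[0], fields[1]
                pct = float(fields[2])
                length = int(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from None
            hits.append(
                AlignmentHit(
                    probe_id=probe_id,
                    subject_cds_id=subject,
                    percent_identity=pct,
                    alignment_length=length,
                    is_target=(probe_targets.get(probe_id) == subject),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Probe geometry

def distance_from_3prime(probe: ProbeRecord, gene: GeneModel) -> int:
    """1-based distance of the probe's 5'-most base from the CDS 3' end."""
    if not 1 <= probe.cds_start <= gene.cds_length:
        raise ValueError(
            f"{probe.probe_id}: cds_start {probe.cds_start} outside "
            f"[1, {gene.cds_length}] of {gene.cds_id}"
        )
    return gene.cds_length - probe.cds_start + 1


def map_probe(probe: ProbeRecord, gene: GeneModel):
    """Locate a probe on its gene and return ``(kind, footprint)``.

    ``kind`` is ``"spliced"`` when the probe matches the spliced CDS at its
    stated start (its footprint then jumps over introns), or ``"genomic"``
    when it matches the contiguous coding-strand genomic sequence starting
    at the same 5' base (a probe designed on an unspliced/mispredicted
    model, possibly running into an intron).  The footprint is a tuple of
    coding-orientation intervals.
    """
    if probe.cds_id != gene.cds_id:
        raise ValueError(f"{probe.probe_id} targets {probe.cds_id}, not {gene.cds_id}")
    start0 = probe.cds_start - 1
    n = probe.length
    if not 1 <= probe.cds_start <= gene.cds_length:
        raise ValueError(
            f"{probe.probe_id}: cds_start {probe.cds_start} outside CDS of {gene.cds_id}"
        )
    if gene.spliced[start0 : start0 + n] == probe.sequence:
        return "spliced", gene.cds_footprint(probe.cds_start, n)
    g5 = gene.cds_to_coding(probe.cds_start)
    g0, _ = gene.span
    off = g5 - g0
    if gene.unspliced[off : off + n] == probe.sequence:
        return "genomic", ((g5, g5 + n - 1),)
    raise ValueError(
        f"{probe.probe_id}: sequence matches neither spliced nor unspliced "
        f"coding strand of {gene.cds_id} at position {probe.cds_start}"
    )
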