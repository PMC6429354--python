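"""Readers and writers for every external format the pipeline touches.

Supported inputs
----------------
* per-sample transcript quantification tables in the Salmon ``quant.sf``
  dialect (``Name``/``Length``/``EffectiveLength``/``TPM``/``NumReads``,
  tab separated; extra columns are ignored, column order is irrelevant),
* a transcript-to-gene map (two-column TSV),
* transcript models as GTF (1-based inclusive coordinates on disk,
  0-based half-open internally) plus a transcriptome FASTA,
* a domain-motif library (TSV: name, motif) and gene-set collections (GMT).

The central in-memory container is :class:`TimeCourseMatrix`: transcripts x
ordered sampling times in TPM, with the transcript->gene map attached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TimeCourseMatrix",
    "TranscriptModel",
    "DomainLibrary",
    "GeneSetCollection",
    "FormatError",
    "read_quant_table",
    "read_tx2gene",
    "assemble_time_course",
    "load_gene_models",
    "read_domain_library",
    "read_gmt",
    "write_time_course",
    "read_time_course",
]

QUANT_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass(frozen=True)
class AbundanceRecord:
    transcript_id: str
    length: int
    effective_length: float
    tpm: float
    num_reads: float


@dataclass
class AbundanceTable:
    """One sample's transcript quantification (one row per transcript)."""

    records: list[AbundanceRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.transcript_id in seen:
                raise FormatError(f"duplicate transcript_id {rec.transcript_id!r}")
            seen.add(rec.transcript_id)

    def __len__(self) -> int:
        return len(self.records)

    def tpm_by_id(self) -> dict[str, float]:
        return {r.transcript_id: r.tpm for r in self.records}


@dataclass
class TimeCourseMatrix:
    """Transcripts x sampling times TPM matrix with a transcript->gene map.

    Times are hours on the experiment's own axis (first sample at the
    configured origin, typically 0); they must be strictly increasing.
    """

    transcript_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    tx2gene: dict[str, str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids in matrix")
        if self.values.shape != (len(self.transcript_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {self.times.size} times"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("TPM values must be finite and non-negative")
        missing = [t for t in self.transcript_ids if t not in self.tx2gene]
        if missing:
            raise ValueError(
                f"transcripts without gene mapping: {', '.join(missing[:5])}"
            )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def row(self, transcript_id: str) -> np.ndarray:
        return self.values[self.transcript_ids.index(transcript_id)]

    def gene_transcripts(self, gene_id: str) -> list[str]:
        return [t for t in self.transcript_ids if self.tx2gene[t] == gene_id]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcript_ids:
            seen.setdefault(self.tx2gene[t], None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=self.transcript_ids,
            columns=[_format_time(t) for t in self.times],
        )
        df.index.name = "transcript_id"
        return df


def _format_time(t: float) -> str:
    return f"t{t:g}"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and sense-strand sequence of one transcript.

    Exons are genomic intervals, 0-based half-open, sorted ascending
    regardless of strand. ``sequence`` is the spliced transcript in sense
    orientation (as given in a transcriptome FASTA). ``cds`` is an optional
    transcript-coordinate interval covering start through stop codon.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str | None = None
    cds: tuple[int, int] | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise FormatError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: overlapping or unsorted exons"
                )
            prev_end = end
        if self.sequence is not None and self.exons:
            total = sum(e - s for s, e in self.exons)
            if len(self.sequence) != total:
                raise FormatError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} "
                    f"!= summed exon length {total}"
                )
        if self.cds is not None:
            s, e = self.cds
            if self.sequence is not None and not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.transcript_id}: cds outside sequence")
            if (e - s) % 3 != 0:
                raise ValueError(f"{self.transcript_id}: cds length not divisible by 3")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def junctions_tx(self) -> list[int]:
        """Exon-exon junction positions in transcript coordinates (5'->3')."""
        lengths = self.exon_lengths()
        if self.strand == "-":
            lengths = lengths[::-1]
        out, acc = [], 0
        for ln in lengths[:-1]:
            acc += ln
            out.append(acc)
        return out

    def tx_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript-coordinate interval onto genomic exon pieces."""
        if not (0 <= start <= end <= self.length):
            raise ValueError("interval outside transcript")
        exons = list(self.exons) if self.strand == "+" else list(self.exons)[::-1]
        pieces: list[tuple[int, int]] = []
        offset = 0
        for gs, ge in exons:
            ln = ge - gs
            lo, hi = max(start, offset), min(end, offset + ln)
            if lo < hi:
                if self.strand == "+":
                    pieces.append((gs + (lo - offset), gs + (hi - offset)))
                else:
                    pieces.append((ge - (hi - offset), ge - (lo - offset)))
            offset += ln
        pieces.sort()
        return pieces


@dataclass
class DomainLibrary:
    """Named protein motif patterns (a literal/regex stand-in for profile HMMs)."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise FormatError("duplicate domain names in library")
        for name, motif in self.entries:
            if not motif:
                raise FormatError(f"domain {name!r} has empty motif")


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate set_id in collection")

    def default_universe(self) -> list[str]:
        if self.universe is not None:
            return list(self.universe)
        seen: dict[str, None] = {}
        for s in self.sets:
            for g in s.members:
                seen.setdefault(g, None)
        return list(seen)


# ---------------------------------------------------------------------------
# quant.sf and tx2gene


def read_quant_table(path: str | Path) -> AbundanceTable:
    """Read a Salmon ``quant.sf`` table.

    Columns are matched by header name, so column order is irrelevant and
    extra columns are ignored. Numeric fields may use scientific notation.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise FormatError(f"{path}: empty file")
    cols = header.split("\t")
    for required in QUANT_COLUMNS:
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    df = pd.read_csv(path, sep="\t", dtype={"Name": str},
                     float_precision="round_trip")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tpm = float(getattr(row, "TPM"))
        reads = float(getattr(row, "NumReads"))
        if not np.isfinite(tpm) or tpm < 0:
            raise ValueError(f"{path}:{i}: negative or non-finite TPM {tpm}")
        if not np.isfinite(reads) or reads < 0:
            raise ValueError(f"{path}:{i}: negative or non-finite NumReads {reads}")
        records.append(
            AbundanceRecord(
                transcript_id=str(getattr(row, "Name")),
                length=int(getattr(row, "Length")),
                effective_length=float(getattr(row, "EffectiveLength")),
                tpm=tpm,
                num_reads=reads,
            )
        )
    return AbundanceTable(records=records)


def read_tx2gene(path: str | Path, strip_versions: bool = False) -> dict[str, str]:
    """Read a two-column transcript->gene TSV (no header required).

    A header line is detected and skipped if its first field is literally
    ``transcript_id``.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            tx, gene = parts[0], parts[1]
            if lineno == 1 and tx.lower() in ("transcript_id", "tx", "transcript"):
                continue
            if strip_versions:
                tx = strip_version(tx)
            mapping[tx] = gene
    return mapping


def strip_version(transcript_id: str) -> str:
    return re.sub(r"\.\d+$", "", transcript_id)


def assemble_time_course(
    samples: Sequence[tuple[float, AbundanceTable]],
    tx2gene: Mapping[str, str],
    zero_fill: bool = False,
) -> TimeCourseMatrix:
    """Assemble per-timepoint quantifications into a time-course matrix.

    Columns are sorted by time. By default a transcript present in one
    sample but absent in another is an error; with ``zero_fill=True`` the
    union of transcripts is kept and absences become 0 TPM. Silent
    zero-filling can fabricate expression reversals, hence opt-in.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a time course")
    times = [t for t, _ in samples]
    if len(set(times)) != len(times):
        raise ValueError("duplicate sampling times")
    order = np.argsort(times)
    samples = [samples[i] for i in order]
    per_sample = [tab.tpm_by_id() for _, tab in samples]

    union: dict[str, None] = {}
    for d in per_sample:
        for tx in d:
            union.setdefault(tx, None)
    if not zero_fill:
        for tx in union:
            missing_at = [t for (t, _), d in zip(samples, per_sample) if tx not in d]
            if missing_at:
                raise ValueError(
                    f"transcript {tx!r} absent at time(s) {missing_at}; "
                    "pass zero_fill=True to fill with 0 TPM"
                )
    transcript_ids = list(union)
    unmapped = [t for t in transcript_ids if t not in tx2gene]
    if unmapped:
        raise ValueError(
            f"transcripts without gene mapping: {', '.join(unmapped[:5])}"
        )
    values = np.zeros((len(transcript_ids), len(samples)))
    for j, d in enumerate(per_sample):
        for i, tx in enumerate(transcript_ids):
            values[i, j] = d.get(tx, 0.0)
    return TimeCourseMatrix(
        transcript_ids=transcript_ids,
        times=np.array([t for t, _ in samples], dtype=float),
        values=values,
        tx2gene={t: tx2gene[t] for t in transcript_ids},
    )


# ---------------------------------------------------------------------------
# GTF + FASTA transcript models

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into id->sequence; the id is the first header token."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return {title.split()[0]: seq for title, seq in SimpleFastaParser(fh)}


def load_gene_models(
    gtf_path: str | Path,
    fasta_path: str | Path | None = None,
    strip_versions: bool = False,
) -> list[TranscriptModel]:
    """Load transcript models from a GTF, attaching FASTA sequences.

    GTF exon coordinates (1-based inclusive) are converted to 0-based
    half-open and sorted ascending. Sequences are taken as given in the
    FASTA (sense orientation) and matched on the first whitespace-separated
    header token. Models lacking a sequence are flagged ``no_sequence``
    rather than dropped.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(Path(gtf_path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{gtf_path}:{lineno}: expected 9 GTF fields")
            feature = fields[2]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(fields[8])
            tx = attrs.get("transcript_id")
            gene = attrs.get("gene_id", "")
            if tx is None:
                raise FormatError(f"{gtf_path}:{lineno}: missing transcript_id")
            if strip_versions:
                tx = strip_version(tx)
            start, end = int(fields[3]) - 1, int(fields[4])  # to 0-based half-open
            meta.setdefault(tx, (gene, fields[6]))
            (exons if feature == "exon" else cds).setdefault(tx, []).append(
                (start, end)
            )

    sequences = read_fasta(fasta_path) if fasta_path is not None else {}
    if strip_versions:
        sequences = {strip_version(k): v for k, v in sequences.items()}

    models = []
    for tx, (gene, strand) in meta.items():
        tx_exons = sorted(exons.get(tx, []))
        for (s1, e1), (s2, _) in zip(tx_exons, tx_exons[1:]):
            if s2 < e1:
                raise FormatError(f"transcript {tx}: overlapping exons in GTF")
        seq = sequences.get(tx)
        flags: list[str] = []
        if seq is None:
            flags.append("no_sequence")
        model = TranscriptModel(
            transcript_id=tx,
            gene_id=gene,
            strand=strand,
            exons=tuple(tx_exons),
            sequence=seq,
            flags=tuple(flags),
        )
        models.append(model)
    return models


def to_gtf_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (the GTF on-disk convention)."""
    return start + 1, end


def from_gtf_coords(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


# ---------------------------------------------------------------------------
# domain library and GMT


def read_domain_library(path: str | Path) -> DomainLibrary:
    """Read a TSV of (domain name, protein motif pattern); header optional."""
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>motif")
            name, motif = parts[0], parts[1]
            if lineno == 1 and name.lower() in ("name", "domain", "domain_name"):
                continue
            if not motif:
                raise FormatError(f"{path}:{lineno}: empty motif")
            entries.append((name, motif))
    return DomainLibrary(entries=entries)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line as id, description, members."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            members = tuple(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: empty member list")
            sets.append(GeneSet(set_id=parts[0], description=parts[1], members=members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# time-course matrix TSV round-trip


def write_time_course(matrix: TimeCourseMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: transcript_id, gene_id, then one t<hours> column.

    Values use ``repr``-faithful float formatting so a round-trip through
    :func:`read_time_course` is bit-exact.
    """
    with open(path, "w") as fh:
        cols = "\t".join(_format_time(t) for t in matrix.times)
        fh.write(f"transcript_id\tgene_id\t{cols}\n")
        for i, tx in enumerate(matrix.transcript_ids):
            vals = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{tx}\t{matrix.tx2gene[tx]}\t{vals}\n")


def read_time_course(path: str | Path) -> TimeCourseMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str},
                     float_precision="round_trip")
    time_cols = [c for c in df.columns
                 if re.fullmatch(r"t-?[0-9.]+(?:e[+-]?[0-9]+)?", c)]
    times = np.array([float(c[1:]) for c in time_cols])
    return TimeCourseMatrix(
        transcript_ids=df["transcript_id"].tolist(),
        times=times,
        values=df[time_cols].to_numpy(dtype=float),
        tx2gene=dict(zip(df["transcript_id"], df["gene_id"])),
    )
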