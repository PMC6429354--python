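"""Functional consequence classification for switching isoform pairs.

For each filtered switch event the isoform gaining dominance is compared
to the isoform losing it along several axes:

* coding potential (CP) -- external CPAT-style scores if supplied, else a
  built-in heuristic (logistic combination of ORF length, ORF coverage
  and the Fickett TESTCODE statistic), thresholded at 0.725;
* ORF length -- longer / shorter / similar (relative difference <= 0.1) /
  complete gain or loss;
* NMD sensitivity -- the canonical 50-nt rule: a transcript is a
  nonsense-mediated-decay candidate when its stop codon ends more than
  50 nt upstream of the last exon-exon junction;
* intron retention and the generating splice event (alternative
  transcription start/stop site, exon skipping, intron retention,
  alternative 5'/3' splice site), from pairwise genomic exon comparison;
* protein domain content, from a motif library scanned over the
  predicted protein (a literal-pattern stand-in for profile HMM search);
* ORF sequence similarity -- Jaccard index of the genomic bases covered
  by the two ORFs.

Per switch time peak, gains and losses on each axis are tallied and
tested against a symmetric null with a two-sided exact binomial test
plus a 95% Clopper-Pearson interval for the gain fraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import DomainLibrary, TranscriptModel
from .switch_detection import SwitchEvent

__all__ = [
    "Orf",
    "ConsequenceRecord",
    "SkippedPair",
    "AxisSummary",
    "StpConsequenceSummary",
    "find_orf",
    "fickett_score",
    "coding_potential",
    "detect_nmd",
    "classify_splice_events",
    "identify_domains",
    "orf_similarity",
    "classify_pair",
    "summarize_stp",
    "CODING_POTENTIAL_CUTOFF",
    "ORF_LENGTH_SIMILAR_FRACTION",
    "NMD_JUNCTION_DISTANCE_NT",
]

CODING_POTENTIAL_CUTOFF = 0.725
ORF_LENGTH_SIMILAR_FRACTION = 0.1
NMD_JUNCTION_DISTANCE_NT = 50
ORF_SIMILARITY_MIN = 0.9

STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Orf:
    """A predicted open reading frame in transcript coordinates
    (0-based half-open; ``end`` includes the stop codon)."""

    start: int
    end: int
    protein: str
    complete: bool = True

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def find_orf(sequence: str) -> Orf | None:
    """Longest ATG-initiated forward-frame ORF ending at a stop codon.

    Ties break to the 5'-most start; codons containing N never match a
    start or stop. Returns None when no complete ORF exists.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    best: Orf | None = None
    for frame in range(3):
        start = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = i + 3 - start
                if best is None or length > best.length_nt:
                    protein = "".join(
                        _CODON_TABLE.get(seq[p:p + 3], "X")
                        for p in range(start, i, 3)
                    )
                    best = Orf(start=start, end=i + 3, protein=protein)
                start = None
            i += 3
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic (position asymmetry + base composition with
# the published lookup tables; higher values indicate protein-coding bias)

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_STEPS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_STEPS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def _lookup(value: float, steps: Sequence[float], probs: Sequence[float]) -> float:
    for i, step in enumerate(steps):
        if value >= step:
            return probs[i]
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence."""
    seq = sequence.upper()
    if len(seq) < 3:
        return 0.0
    score = 0.0
    total = max(1, sum(seq.count(b) for b in "ACGT"))
    for base in "ACGT":
        counts = [seq[f::3].count(base) for f in range(3)]
        position = max(counts) / (min(counts) + 1)
        content = seq.count(base) / total
        score += _lookup(position, _POSITION_STEPS, _POSITION_PROB[base]) \
            * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_STEPS, _CONTENT_PROB[base]) \
            * _CONTENT_WEIGHT[base]
    return score


# logistic(a*log(orf_len+1) + b*orf_coverage + c*fickett + d); constants
# fixed so that long high-coverage ORFs with coding-like composition score
# well above the 0.725 cutoff and ORF-less transcripts score 0
_CP_COEF_LOG_LEN = 1.2
_CP_COEF_COVERAGE = 2.0
_CP_COEF_FICKETT = 2.0
_CP_INTERCEPT = -8.0


def coding_potential(
    model: TranscriptModel, external_score: float | None = None,
    cutoff: float = CODING_POTENTIAL_CUTOFF,
) -> tuple[float, bool]:
    """Coding-potential score in [0, 1] and its thresholded call.

    An externally computed score (e.g. ingested from a CPAT output table)
    is used verbatim when given; otherwise the built-in heuristic is
    evaluated on the transcript sequence. A transcript without a complete
    ORF is never called coding.
    """
    if external_score is not None:
        return float(external_score), float(external_score) >= cutoff
    if model.sequence is None:
        raise ValueError(
            f"{model.transcript_id}: no sequence and no external score"
        )
    orf = find_orf(model.sequence)
    if orf is None:
        return 0.0, False
    coverage = orf.length_nt / len(model.sequence)
    z = (
        _CP_COEF_LOG_LEN * np.log(orf.length_nt + 1)
        + _CP_COEF_COVERAGE * coverage
        + _CP_COEF_FICKETT * fickett_score(model.sequence)
        + _CP_INTERCEPT
    )
    score = float(1.0 / (1.0 + np.exp(-z)))
    return score, score >= cutoff


def detect_nmd(model: TranscriptModel, orf: Orf) -> bool:
    """Canonical 50-nt rule: NMD-sensitive iff the stop codon ends more
    than 50 nt upstream of the last exon-exon junction."""
    if model.sequence is not None and orf.end > len(model.sequence):
        raise ValueError("ORF outside transcript sequence")
    junctions = model.junctions_tx()
    if not junctions:
        return False
    return junctions[-1] - orf.end > NMD_JUNCTION_DISTANCE_NT


# ---------------------------------------------------------------------------
# splice-event comparison on genomic exon structures

ALT_TSS = "alt_tss"
ALT_TTS = "alt_tts"
EXON_SKIPPING = "exon_skipping"
INTRON_RETENTION = "intron_retention"
ALT_5PRIME = "alt_5prime"
ALT_3PRIME = "alt_3prime"


def _introns(exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [(exons[k][1], exons[k + 1][0]) for k in range(len(exons) - 1)]


def _directional_events(
    a: TranscriptModel, b: TranscriptModel
) -> set[tuple[str, str | None]]:
    """Pairwise structural events as (event, carrier) where carrier names
    the isoform holding the extra structure ('a'/'b'; None if symmetric)."""
    if a.gene_id != b.gene_id:
        raise ValueError("isoforms of different genes cannot be compared")
    if a.strand != b.strand:
        raise ValueError("isoforms on different strands cannot be compared")
    if not a.exons or not b.exons:
        raise ValueError("both isoforms need exon structures")
    plus = a.strand == "+"
    events: set[tuple[str, str | None]] = set()

    a5 = a.exons[0][0] if plus else a.exons[-1][1]
    b5 = b.exons[0][0] if plus else b.exons[-1][1]
    a3 = a.exons[-1][1] if plus else a.exons[0][0]
    b3 = b.exons[-1][1] if plus else b.exons[0][0]
    if a5 != b5:
        events.add((ALT_TSS, None))
    if a3 != b3:
        events.add((ALT_TTS, None))

    for name, x, y in (("a", a, b), ("b", b, a)):
        y_introns = _introns(y.exons)
        for (xs, xe) in x.exons:
            # exon of x entirely inside an intron of y: y skips it
            if any(is_ <= xs and xe <= ie for is_, ie in y_introns):
                events.add((EXON_SKIPPING, name))
            # exon of x covering an entire intron of y and reaching into
            # both flanking exons: x retains that intron
            if any(xs < is_ and ie < xe for is_, ie in y_introns):
                events.add((INTRON_RETENTION, name))

    # shared exons differing at exactly one internal boundary
    a_internal_starts = {s for k, (s, _) in enumerate(a.exons) if k > 0}
    a_internal_ends = {e for k, (_, e) in enumerate(a.exons) if k < len(a.exons) - 1}
    b_internal_starts = {s for k, (s, _) in enumerate(b.exons) if k > 0}
    b_internal_ends = {e for k, (_, e) in enumerate(b.exons) if k < len(b.exons) - 1}
    a_introns = _introns(a.exons)
    b_introns = _introns(b.exons)
    for (as_, ae) in a.exons:
        for (bs, be) in b.exons:
            if max(as_, bs) >= min(ae, be):
                continue  # no overlap
            # a retention exon's boundaries are explained by the retained
            # intron, not by an alternative splice site
            if any(as_ < is_ and ie < ae for is_, ie in b_introns) or any(
                bs < is_ and ie < be for is_, ie in a_introns
            ):
                continue
            if as_ == bs and ae != be and ae in a_internal_ends and be in b_internal_ends:
                # internal exon end differs: donor-side change
                events.add((ALT_5PRIME if plus else ALT_3PRIME, None))
            if ae == be and as_ != bs and as_ in a_internal_starts and bs in b_internal_starts:
                # internal exon start differs: acceptor-side change
                events.add((ALT_3PRIME if plus else ALT_5PRIME, None))
    return events


def classify_splice_events(a: TranscriptModel, b: TranscriptModel) -> set[str]:
    """The set of splice-event categories distinguishing two isoforms of
    the same gene (strand-aware, on genomic coordinates)."""
    return {name for name, _ in _directional_events(a, b)}


def identify_domains(
    protein: str, lib: DomainLibrary
) -> list[tuple[str, int]]:
    """Scan a protein for motif-library hits; overlapping matches of
    different motifs (and repeated hits of one motif) are all reported
    with 0-based positions."""
    if set(protein) - _AA_ALPHABET:
        raise ValueError("protein contains non-standard residues")
    hits: list[tuple[str, int]] = []
    for name, motif in lib.entries:
        for m in re.finditer(f"(?=({motif}))", protein):
            hits.append((name, m.start()))
    return hits


def _merge_intervals(pieces: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(pieces):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _interval_overlap(
    xs: Sequence[tuple[int, int]], ys: Sequence[tuple[int, int]]
) -> int:
    total = 0
    for s1, e1 in xs:
        for s2, e2 in ys:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def orf_similarity(a: TranscriptModel, b: TranscriptModel) -> float:
    """Jaccard index of the genomic base sets covered by the two
    predicted ORFs (0 when either transcript lacks a complete ORF)."""
    pieces = []
    for model in (a, b):
        if model.sequence is None:
            return 0.0
        orf = find_orf(model.sequence)
        if orf is None:
            return 0.0
        pieces.append(_merge_intervals(model.tx_to_genomic(orf.start, orf.end)))
    inter = _interval_overlap(pieces[0], pieces[1])
    len_a = sum(e - s for s, e in pieces[0])
    len_b = sum(e - s for s, e in pieces[1])
    union = len_a + len_b - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# per-pair record and per-STP summary

CP_AXES = ("cp", "domains", "orf_length", "nmd", "ir")


@dataclass(frozen=True)
class SkippedPair:
    event: SwitchEvent
    reason: str


@dataclass(frozen=True)
class ConsequenceRecord:
    """Consequence classification of one switching pair; gained_iso is the
    isoform dominant after the switch, lost_iso the one dominant before."""

    event: SwitchEvent
    gained_iso: str
    lost_iso: str
    cp_class: str           # coding->coding etc., gained relative to lost
    orf_class: str          # longer/shorter/similar/complete_gain/complete_loss/both_absent
    nmd_class: str          # gain_sensitivity/loss_sensitivity/unchanged
    ir_class: str           # gain/loss/unchanged
    domains_gained: tuple[str, ...]
    domains_lost: tuple[str, ...]
    orf_similarity: float
    splice_events: frozenset[str]

    def axis_direction(self, axis: str) -> str:
        """'gain' / 'loss' / 'unchanged' along one consequence axis."""
        if axis == "cp":
            if self.cp_class == "noncoding->coding":
                return "gain"
            if self.cp_class == "coding->noncoding":
                return "loss"
            return "unchanged"
        if axis == "domains":
            if len(self.domains_gained) > len(self.domains_lost):
                return "gain"
            if len(self.domains_lost) > len(self.domains_gained):
                return "loss"
            return "unchanged"
        if axis == "orf_length":
            if self.orf_class in ("longer", "complete_gain"):
                return "gain"
            if self.orf_class in ("shorter", "complete_loss"):
                return "loss"
            return "unchanged"
        if axis == "nmd":
            if self.nmd_class == "gain_sensitivity":
                return "gain"
            if self.nmd_class == "loss_sensitivity":
                return "loss"
            return "unchanged"
        if axis == "ir":
            return self.ir_class if self.ir_class in ("gain", "loss") else "unchanged"
        raise KeyError(f"unknown axis {axis!r}")


def classify_pair(
    event: SwitchEvent,
    models: Mapping[str, TranscriptModel],
    lib: DomainLibrary | None = None,
    cp_scores: Mapping[str, float] | None = None,
    cp_cutoff: float = CODING_POTENTIAL_CUTOFF,
    length_similar_fraction: float = ORF_LENGTH_SIMILAR_FRACTION,
) -> ConsequenceRecord | SkippedPair:
    """Classify the functional consequences of one switch event.

    The isoform gaining dominance (``event.iso_j``) is compared to the
    losing one (``event.iso_i``); all gain/loss polarity flows from that
    orientation. Pairs lacking a model or sequence are skipped with a
    reason rather than raising.
    """
    gained_id, lost_id = event.iso_j, event.iso_i
    for tx in (gained_id, lost_id):
        if tx not in models:
            return SkippedPair(event, f"no transcript model for {tx}")
        if models[tx].sequence is None:
            return SkippedPair(event, f"no sequence for {tx}")
    gained, lost = models[gained_id], models[lost_id]

    def cp_call(model: TranscriptModel) -> bool:
        ext = cp_scores.get(model.transcript_id) if cp_scores else None
        return coding_potential(model, external_score=ext, cutoff=cp_cutoff)[1]

    g_coding, l_coding = cp_call(gained), cp_call(lost)
    cp_class = (
        f"{'coding' if l_coding else 'noncoding'}->"
        f"{'coding' if g_coding else 'noncoding'}"
    )

    g_orf, l_orf = find_orf(gained.sequence), find_orf(lost.sequence)
    if g_orf is None and l_orf is None:
        orf_class = "both_absent"
    elif l_orf is None:
        orf_class = "complete_gain"
    elif g_orf is None:
        orf_class = "complete_loss"
    else:
        rel = abs(g_orf.length_nt - l_orf.length_nt) / max(
            g_orf.length_nt, l_orf.length_nt
        )
        if rel <= length_similar_fraction:
            orf_class = "similar"
        else:
            orf_class = "longer" if g_orf.length_nt > l_orf.length_nt else "shorter"

    g_nmd = detect_nmd(gained, g_orf) if g_orf else False
    l_nmd = detect_nmd(lost, l_orf) if l_orf else False
    if g_nmd and not l_nmd:
        nmd_class = "gain_sensitivity"
    elif l_nmd and not g_nmd:
        nmd_class = "loss_sensitivity"
    else:
        nmd_class = "unchanged"

    directional = _directional_events(gained, lost)
    g_retains = (INTRON_RETENTION, "a") in directional
    l_retains = (INTRON_RETENTION, "b") in directional
    if g_retains and not l_retains:
        ir_class = "gain"
    elif l_retains and not g_retains:
        ir_class = "loss"
    else:
        ir_class = "unchanged"

    g_domains: set[str] = set()
    l_domains: set[str] = set()
    if lib is not None:
        if g_orf:
            g_domains = {n for n, _ in identify_domains(g_orf.protein, lib)}
        if l_orf:
            l_domains = {n for n, _ in identify_domains(l_orf.protein, lib)}

    return ConsequenceRecord(
        event=event,
        gained_iso=gained_id,
        lost_iso=lost_id,
        cp_class=cp_class,
        orf_class=orf_class,
        nmd_class=nmd_class,
        ir_class=ir_class,
        domains_gained=tuple(sorted(g_domains - l_domains)),
        domains_lost=tuple(sorted(l_domains - g_domains)),
        orf_similarity=orf_similarity(gained, lost),
        splice_events=frozenset(name for name, _ in directional),
    )


@dataclass(frozen=True)
class AxisSummary:
    gains: int
    losses: int
    unchanged: int
    pvalue: float | None       # None when no gains or losses to test
    ci_low: float | None       # 95% Clopper-Pearson bounds on gain fraction
    ci_high: float | None

    @property
    def applicable(self) -> bool:
        return self.pvalue is not None


@dataclass(frozen=True)
class StpConsequenceSummary:
    n_records: int
    axes: dict[str, AxisSummary]


def summarize_stp(records: Sequence[ConsequenceRecord]) -> StpConsequenceSummary:
    """Tally gains vs losses per consequence axis over the records of one
    switch time peak; two-sided exact binomial test (H0: gain fraction
    0.5, unchanged pairs excluded) with a 95% Clopper-Pearson interval."""
    if not records:
        raise ValueError("need at least one record to summarise")
    axes: dict[str, AxisSummary] = {}
    for axis in CP_AXES:
        directions = [r.axis_direction(axis) for r in records]
        gains = directions.count("gain")
        losses = directions.count("loss")
        unchanged = directions.count("unchanged")
        if gains + losses == 0:
            axes[axis] = AxisSummary(gains, losses, unchanged, None, None, None)
            continue
        test = stats.binomtest(gains, gains + losses, p=0.5)
        ci = test.proportion_ci(confidence_level=0.95, method="exact")
        axes[axis] = AxisSummary(
            gains, losses, unchanged,
            float(test.pvalue), float(ci.low), float(ci.high),
        )
    return StpConsequenceSummary(n_records=len(records), axes=axes)
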