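"""Synthetic circadian time-course datasets with planted ground truth.

The generator emulates the experimental design this package targets: a
single-replicate time course sampled every 3 h over 30 h (11 time
points), transcript abundances in TPM with ~24 h periodic components,
planted expression reversals between isoform pairs of the same gene, and
uniform measurement noise of amplitude 2 TPM.

Two layers are generated, separately usable or composed:

* expression profiles (:func:`simulate_profiles`) -- switching pairs as
  antiphase waveforms whose analytic crossing times are recorded as
  truth; non-switching isoforms as proportional or constant profiles
  that never cross;
* gene models (:func:`simulate_gene_models`) -- two-isoform genes built
  from structural archetypes with exactly known consequences:

  - ``cp``      coding full isoform vs a 3'-truncated (alternative
                transcription stop) isoform with no complete ORF,
  - ``nmd``     full isoform vs an intron-retaining isoform whose
                retained intron carries an in-frame premature stop more
                than 50 nt upstream of the remaining last junction,
  - ``domains`` full isoform vs an alternative-TSS isoform starting
                past the first start codon, losing the 5' ORF portion
                and the domain motif planted there,
  - ``skip``    full isoform vs an exon-skipping isoform; the skipped
                exon is codon-aligned so the shorter ORF stays in frame.

All coding sequence is written as NNC codons (no stop codons, no ATG in
any frame), so the single planted ORF per transcript is provably the
longest; untranslated and intronic sequence is scrubbed of ATG. Every
random draw flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    TimeCourseMatrix,
    TranscriptModel,
    read_quant_table,
    assemble_time_course,
)
from .consequence import INTRON_RETENTION, ALT_TSS, ALT_TTS, EXON_SKIPPING

__all__ = [
    "SimulationConfig",
    "PlantedSwitch",
    "PlantedPair",
    "SimulationTruth",
    "SyntheticDataset",
    "simulate_profiles",
    "simulate_gene_models",
    "simulate_dataset",
    "write_dataset",
    "simulate_gene_sets",
]

DEFAULT_TIMES = tuple(float(t) for t in range(0, 31, 3))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# codons of the form NNC: never a stop (stops end in A/G), never ATG, and
# no ATG or stop can form across a boundary between two such codons
_NNC_CODONS = [b1 + b2 + "C" for b1 in "ACGT" for b2 in "ACGT"]

# amino acid -> NNC codon, for planting protein motifs inside NNC bodies
_AA_TO_NNC = {
    "F": "TTC", "L": "CTC", "I": "ATC", "V": "GTC", "S": "TCC",
    "P": "CCC", "T": "ACC", "A": "GCC", "Y": "TAC", "H": "CAC",
    "N": "AAC", "D": "GAC", "C": "TGC", "R": "CGC", "G": "GGC",
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scrubbed_random(rng: np.random.Generator, n: int) -> str:
    """Random nucleotide sequence with every ATG occurrence removed
    (T->C substitution, which can create neither ATG nor a stop codon)."""
    seq = "".join(rng.choice(list("ACGT"), size=n))
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[:i] + "ACG" + seq[i + 3:]
    return seq


def _body_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NNC_CODONS, size=n))


def _motif_codons(motif: str) -> str:
    try:
        return "".join(_AA_TO_NNC[aa] for aa in motif)
    except KeyError as exc:
        raise ValueError(
            f"motif {motif!r} contains residue {exc.args[0]!r} with no "
            "NNC codon; use residues from " + "".join(sorted(_AA_TO_NNC))
        ) from None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults emulate the targeted experiment: 11 samples 3 h apart over
    30 h of experimental time, one sample per time point, ~24 h period,
    oscillation amplitude 5 TPM around a 10 TPM baseline, and uniform
    noise of amplitude 2 TPM.
    """

    n_genes: int = 50
    fraction_switching: float = 0.2
    single_isoform_fraction: float = 0.1
    times: tuple[float, ...] = DEFAULT_TIMES
    period: float = 24.0
    baseline_tpm: float = 10.0
    amplitude_tpm: float = 5.0
    noise_amount: float = 2.0
    seed: int = 0
    phase: float | None = None          # None: random per gene
    profile_archetype: str = "sinusoid"  # sinusoid | square | step | ramp
    step_time: float | None = None       # step/ramp crossing time
    motifs: tuple[str, ...] = ("HISTAG",)

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.fraction_switching <= 1.0:
            problems.append("fraction_switching must be in [0, 1]")
        if not 0.0 <= self.single_isoform_fraction <= 1.0:
            problems.append("single_isoform_fraction must be in [0, 1]")
        if self.amplitude_tpm > self.baseline_tpm:
            problems.append("amplitude_tpm must not exceed baseline_tpm")
        if self.noise_amount < 0:
            problems.append("noise_amount must be non-negative")
        if self.period <= 0:
            problems.append("period must be positive")
        if len(self.times) < 2 or any(
            b <= a for a, b in zip(self.times, self.times[1:])
        ):
            problems.append("times must be >= 2 strictly increasing values")
        if self.profile_archetype not in ("sinusoid", "square", "step", "ramp"):
            problems.append(f"unknown profile_archetype {self.profile_archetype!r}")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass(frozen=True)
class PlantedSwitch:
    gene_id: str
    iso_a: str
    iso_b: str
    crossing_times: tuple[float, ...]
    amplitude: float


@dataclass(frozen=True)
class PlantedPair:
    """Designed consequence truth for one two-isoform gene; ``iso_a`` is
    the full-structure isoform, ``iso_b`` the structural variant."""

    gene_id: str
    iso_a: str
    iso_b: str
    archetype: str
    coding: dict[str, bool]
    nmd: dict[str, bool]
    domains: dict[str, tuple[str, ...]]
    splice_events: frozenset[str]
    orf_class_b_vs_a: str
    ir_carrier: str | None = None


@dataclass
class SimulationTruth:
    switches: list[PlantedSwitch] = field(default_factory=list)
    pairs: list[PlantedPair] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    matrix: TimeCourseMatrix
    models: list[TranscriptModel]
    truth: SimulationTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# expression profiles


def _waveform(
    archetype: str,
    t: np.ndarray,
    period: float,
    phase: float,
    t_cross: float,
) -> tuple[np.ndarray, list[float]]:
    """Unit-amplitude switching waveform and its analytic zero crossings
    strictly inside the sampled window."""
    t0, t1 = float(t[0]), float(t[-1])
    if archetype in ("sinusoid", "square"):
        s = np.sin(2 * np.pi * t / period + phase)
        if archetype == "square":
            s = np.sign(s)
        k0 = int(np.ceil((2 * np.pi * t0 / period + phase) / np.pi))
        crossings = []
        k = k0
        while True:
            tc = (k * np.pi - phase) * period / (2 * np.pi)
            if tc >= t1:
                break
            if tc > t0:
                crossings.append(float(tc))
            k += 1
        return s, crossings
    if archetype == "step":
        s = np.where(t < t_cross, 1.0, -1.0)
        return s, [float(t_cross)] if t0 < t_cross < t1 else []
    # ramp: single linear crossing at t_cross
    s = np.clip((t_cross - t) / ((t1 - t0) / 2.0), -1.0, 1.0)
    return s, [float(t_cross)] if t0 < t_cross < t1 else []


def simulate_profiles(
    config: SimulationConfig,
    gene_isoforms: Mapping[str, Sequence[str]] | None = None,
    switching_genes: Sequence[str] | None = None,
) -> tuple[TimeCourseMatrix, SimulationTruth]:
    """Generate the TPM time-course matrix with planted switches.

    Switching genes carry one antiphase pair ``B +/- A*w(t)`` whose
    analytic crossings (zeros of the waveform) go into the truth; the
    remaining isoforms get proportional rhythmic profiles at well
    separated scales, which never cross each other. Uniform noise of
    ``noise_amount`` is then added and clamped at zero.

    ``gene_isoforms`` can pin the gene -> transcript structure (as from
    :func:`simulate_gene_models`); by default synthetic ids are made.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)

    if gene_isoforms is None:
        gene_isoforms = {}
        n_single = int(round(config.single_isoform_fraction * config.n_genes))
        for g in range(config.n_genes):
            gene = f"G{g + 1:04d}"
            n_iso = 1 if g < n_single else 2
            gene_isoforms[gene] = [f"{gene}.T{k + 1}" for k in range(n_iso)]
    multi = [g for g, isos in gene_isoforms.items() if len(isos) >= 2]
    if switching_genes is None:
        n_switch = int(round(config.fraction_switching * len(multi)))
        switching_genes = list(
            rng.choice(multi, size=n_switch, replace=False)
        ) if n_switch else []
    switching = set(switching_genes)

    t_cross = config.step_time
    if t_cross is None:
        mid = (t.size - 1) // 2
        t_cross = float((t[mid - 1] + t[mid]) / 2.0) if t.size > 2 else float(t[0])

    transcript_ids: list[str] = []
    rows: list[np.ndarray] = []
    tx2gene: dict[str, str] = {}
    truth = SimulationTruth()
    B, A = config.baseline_tpm, config.amplitude_tpm

    for gene, isoforms in gene_isoforms.items():
        phase = (
            config.phase if config.phase is not None
            else float(rng.uniform(0.0, 2.0 * np.pi))
        )
        if gene in switching:
            wave, crossings = _waveform(
                config.profile_archetype, t, config.period, phase, t_cross
            )
            profiles = {isoforms[0]: B + A * wave, isoforms[1]: B - A * wave}
            truth.switches.append(
                PlantedSwitch(
                    gene_id=gene,
                    iso_a=isoforms[0],
                    iso_b=isoforms[1],
                    crossing_times=tuple(crossings),
                    amplitude=A,
                )
            )
            extra = isoforms[2:]
        else:
            profiles = {}
            extra = list(isoforms)
        # non-switching isoforms: proportional rhythmic profiles at widely
        # separated scales -- they never cross one another and sit well
        # below the switching pair's envelope even after noise smoothing
        base = B * (1.0 + 0.3 * np.sin(2 * np.pi * t / config.period + phase))
        scale = 0.15 if gene in switching else 1.0
        for iso in extra:
            profiles[iso] = scale * base
            scale *= 0.15
        for iso in isoforms:
            transcript_ids.append(iso)
            rows.append(profiles[iso])
            tx2gene[iso] = gene

    values = np.vstack(rows)
    if config.noise_amount > 0:
        values = values + rng.uniform(
            -config.noise_amount, config.noise_amount, size=values.shape
        )
    matrix = TimeCourseMatrix(
        transcript_ids=transcript_ids,
        times=t,
        values=np.clip(values, 0.0, None),
        tx2gene=tx2gene,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene models with designed consequence truth


def _assemble_locus(
    tx_seq: str,
    cuts: Sequence[int],
    intron_seqs: Sequence[str],
) -> tuple[str, list[tuple[int, int]]]:
    """Interleave transcript exon slices with introns into a locus string
    (plus-strand layout); returns the genome and genomic exon intervals."""
    bounds = [0, *cuts, len(tx_seq)]
    exon_seqs = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    assert len(intron_seqs) == len(exon_seqs) - 1
    genome_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for k, ex in enumerate(exon_seqs):
        exons.append((pos, pos + len(ex)))
        genome_parts.append(ex)
        pos += len(ex)
        if k < len(intron_seqs):
            genome_parts.append(intron_seqs[k])
            pos += len(intron_seqs[k])
    return "".join(genome_parts), exons


def _sense_sequence(
    genome: str, exons: Sequence[tuple[int, int]], strand: str
) -> str:
    spliced = "".join(genome[s:e] for s, e in exons)
    return spliced if strand == "+" else _revcomp(spliced)


def _flip_locus(
    genome: str, exon_sets: list[list[tuple[int, int]]]
) -> tuple[str, list[list[tuple[int, int]]]]:
    L = len(genome)
    flipped = [
        sorted((L - e, L - s) for s, e in exons) for exons in exon_sets
    ]
    return _revcomp(genome), flipped


def _build_pair_gene(
    rng: np.random.Generator,
    gene_id: str,
    archetype: str,
    motif: str,
) -> tuple[list[TranscriptModel], PlantedPair]:
    """Construct one two-isoform gene of the given structural archetype
    with exactly known consequence truth (see module docstring)."""
    u5, u3 = 30, 60
    motif_nt = _motif_codons(motif)

    if archetype == "cp":
        # A: 3 exons, full ORF with the motif; B: alternative transcription
        # stop truncating the last exon before A's stop codon -> no ORF
        n_body = int(rng.integers(190, 260))
        body = _body_codons(rng, n_body)
        body = body[:15] + motif_nt + body[15 + len(motif_nt):]
        seq_a = _scrubbed_random(rng, u5) + "ATG" + body + "TAA" \
            + _scrubbed_random(rng, u3)
        stop_start = u5 + 3 + n_body * 3
        cut1 = u5 + 3 + 3 * int(rng.integers(60, 90))
        cut2 = cut1 + 3 * int(rng.integers(40, 60))
        assert cut2 <= stop_start - 60
        introns = [_scrubbed_random(rng, int(rng.integers(80, 150)))
                   for _ in range(2)]
        genome, exons_a = _assemble_locus(seq_a, [cut1, cut2], introns)
        b_len = cut2 + int(rng.integers(30, min(50, stop_start - cut2 - 6)))
        exons_b = exons_a[:2] + [(exons_a[2][0], exons_a[2][0] + (b_len - cut2))]
        truth = dict(
            coding={"a": True, "b": False},
            nmd={"a": False, "b": False},
            domains={"a": (motif,), "b": ()},
            splice_events=frozenset({ALT_TTS}),
            orf_class_b_vs_a="complete_loss",
            ir_carrier=None,
        )

    elif archetype == "nmd":
        # A: 3 exons, stop in the last exon; B retains intron 1, which
        # opens with an in-frame stop -> premature stop > 50 nt upstream
        # of B's remaining (last) junction
        a1 = int(rng.integers(150, 190))   # codons in exon 1 past ATG
        a2 = int(rng.integers(45, 60))     # codons in exon 2
        a3 = int(rng.integers(25, 40))     # codons in exon 3 before stop
        n_body = a1 + a2 + a3
        body = _body_codons(rng, n_body)
        body = body[:15] + motif_nt + body[15 + len(motif_nt):]  # in exon 1
        seq_a = _scrubbed_random(rng, u5) + "ATG" + body + "TAA" \
            + _scrubbed_random(rng, u3)
        cut1 = u5 + 3 + 3 * a1
        cut2 = cut1 + 3 * a2
        i1 = "TAA" + _scrubbed_random(rng, int(rng.integers(90, 150)) - 3)
        i2 = _scrubbed_random(rng, int(rng.integers(80, 150)))
        genome, exons_a = _assemble_locus(seq_a, [cut1, cut2], [i1, i2])
        exons_b = [(exons_a[0][0], exons_a[1][1]), exons_a[2]]
        truth = dict(
            coding={"a": True, "b": True},
            nmd={"a": False, "b": True},
            domains={"a": (motif,), "b": (motif,)},
            splice_events=frozenset({INTRON_RETENTION}),
            orf_class_b_vs_a="shorter",
            ir_carrier="b",
        )

    elif archetype == "domains":
        # A: 2 exons, ORF from ATG1 with the motif early, then an in-frame
        # internal ATG; B: alternative TSS starting past ATG1 -> shorter
        # ORF from the internal ATG, motif lost
        a1 = int(rng.integers(160, 200))   # codons in exon 1 past ATG1
        a2 = int(rng.integers(35, 55))     # codons in exon 2 before stop
        k1 = int(rng.integers(45, 60))     # internal ATG at codon k1
        body = _body_codons(rng, a1 + a2)
        body = body[:9] + motif_nt + body[9 + len(motif_nt):]
        body = body[: 3 * k1] + "ATG" + body[3 * k1 + 3:]
        seq_a = _scrubbed_random(rng, u5) + "ATG" + body + "TAA" \
            + _scrubbed_random(rng, u3)
        cut1 = u5 + 3 + 3 * a1
        intron = _scrubbed_random(rng, int(rng.integers(80, 150)))
        genome, exons_a = _assemble_locus(seq_a, [cut1], [intron])
        delta = u5 + 3 + 3 * k1 - 21       # B keeps a 21 nt 5' UTR
        exons_b = [(exons_a[0][0] + delta, exons_a[0][1]), exons_a[1]]
        truth = dict(
            coding={"a": True, "b": True},
            nmd={"a": False, "b": False},
            domains={"a": (motif,), "b": ()},
            splice_events=frozenset({ALT_TSS}),
            orf_class_b_vs_a="shorter",
            ir_carrier=None,
        )

    else:  # skip
        # A: 4 exons; B skips the codon-aligned third exon, keeping the
        # frame and the stop; exon size sets similar vs shorter ORF truth
        a1 = int(rng.integers(55, 75))
        a2 = int(rng.integers(45, 60))
        similar = bool(rng.integers(0, 2))
        total_hint = a1 + a2 + 40
        a3 = max(5, int(total_hint * (0.05 if similar else 0.30)))
        a4 = int(rng.integers(35, 50))
        n_total = a1 + a2 + a3 + a4
        body = _body_codons(rng, n_total)
        body = body[:9] + motif_nt + body[9 + len(motif_nt):]  # in exon 1
        seq_a = _scrubbed_random(rng, u5) + "ATG" + body + "TAA" \
            + _scrubbed_random(rng, u3)
        cut1 = u5 + 3 + 3 * a1
        cut2 = cut1 + 3 * a2
        cut3 = cut2 + 3 * a3
        introns = [_scrubbed_random(rng, int(rng.integers(80, 150)))
                   for _ in range(3)]
        genome, exons_a = _assemble_locus(seq_a, [cut1, cut2, cut3], introns)
        exons_b = [exons_a[0], exons_a[1], exons_a[3]]
        orf_len = 3 * (n_total + 2)
        rel = 3 * a3 / orf_len
        truth = dict(
            coding={"a": True, "b": True},
            nmd={"a": False, "b": False},
            domains={"a": (motif,), "b": (motif,)},
            splice_events=frozenset({EXON_SKIPPING}),
            orf_class_b_vs_a="similar" if rel <= 0.1 else "shorter",
            ir_carrier=None,
        )

    strand = "+" if rng.integers(0, 2) == 0 else "-"
    exon_sets = [list(exons_a), list(exons_b)]
    if strand == "-":
        genome, exon_sets = _flip_locus(genome, exon_sets)
    iso_ids = [f"{gene_id}.T1", f"{gene_id}.T2"]
    models = [
        TranscriptModel(
            transcript_id=iso,
            gene_id=gene_id,
            strand=strand,
            exons=tuple(sorted(exons)),
            sequence=_sense_sequence(genome, sorted(exons), strand),
        )
        for iso, exons in zip(iso_ids, exon_sets)
    ]
    remap = {"a": iso_ids[0], "b": iso_ids[1]}
    pair = PlantedPair(
        gene_id=gene_id,
        iso_a=iso_ids[0],
        iso_b=iso_ids[1],
        archetype=archetype,
        coding={remap[k]: v for k, v in truth["coding"].items()},
        nmd={remap[k]: v for k, v in truth["nmd"].items()},
        domains={remap[k]: v for k, v in truth["domains"].items()},
        splice_events=truth["splice_events"],
        orf_class_b_vs_a=truth["orf_class_b_vs_a"],
        ir_carrier=remap.get(truth["ir_carrier"]),
    )
    return models, pair


def _build_single_gene(
    rng: np.random.Generator, gene_id: str
) -> TranscriptModel:
    n_body = int(rng.integers(120, 200))
    seq = _scrubbed_random(rng, 30) + "ATG" + _body_codons(rng, n_body) \
        + "TAA" + _scrubbed_random(rng, 60)
    cut = 33 + 3 * int(rng.integers(40, min(80, n_body - 10)))
    genome, exons = _assemble_locus(
        seq, [cut], [_scrubbed_random(rng, int(rng.integers(80, 150)))]
    )
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    exon_sets = [list(exons)]
    if strand == "-":
        genome, exon_sets = _flip_locus(genome, exon_sets)
    return TranscriptModel(
        transcript_id=f"{gene_id}.T1",
        gene_id=gene_id,
        strand=strand,
        exons=tuple(sorted(exon_sets[0])),
        sequence=_sense_sequence(genome, sorted(exon_sets[0]), strand),
    )


_ARCHETYPES = ("cp", "nmd", "domains", "skip")


def simulate_gene_models(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], SimulationTruth]:
    """Generate transcript models with planted consequence truth.

    Structural archetypes are cycled over the multi-isoform genes; a
    ``single_isoform_fraction`` of genes get one transcript only (these
    exercise the single-isoform removal rule downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    models: list[TranscriptModel] = []
    truth = SimulationTruth()
    n_single = int(round(config.single_isoform_fraction * config.n_genes))
    arch_i = 0
    for g in range(config.n_genes):
        gene = f"G{g + 1:04d}"
        if g < n_single:
            models.append(_build_single_gene(rng, gene))
            continue
        archetype = _ARCHETYPES[arch_i % len(_ARCHETYPES)]
        arch_i += 1
        motif = config.motifs[g % len(config.motifs)] if config.motifs else "HISTAG"
        gene_models, pair = _build_pair_gene(rng, gene, archetype, motif)
        models.extend(gene_models)
        truth.pairs.append(pair)
    return models, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset: gene models plus a matching expression time course.

    Switching profiles are planted on the two isoforms of a random
    subset of the structurally generated genes, so switch detection,
    peak calling and consequence classification all run off one
    coherent ground truth.
    """
    models, truth = simulate_gene_models(config)
    gene_isoforms: dict[str, list[str]] = {}
    for m in models:
        gene_isoforms.setdefault(m.gene_id, []).append(m.transcript_id)
    matrix, profile_truth = simulate_profiles(config, gene_isoforms)
    truth.switches = profile_truth.switches
    return SyntheticDataset(matrix=matrix, models=models, truth=truth,
                            config=config)


# ---------------------------------------------------------------------------
# gene sets for enrichment tests


def simulate_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int,
    enriched_query: Sequence[str] | None = None,
):
    """Random gene sets over ``gene_ids``; if ``enriched_query`` is given
    the first set is built mostly from it (a planted enriched set)."""
    from .io_formats import GeneSet, GeneSetCollection

    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        if i == 0 and enriched_query:
            core = list(enriched_query)[: set_size - 1]
            pad = [g for g in gene_ids if g not in core]
            members = core + list(rng.choice(pad, size=set_size - len(core),
                                             replace=False))
        else:
            members = list(rng.choice(gene_ids, size=set_size, replace=False))
        sets.append(GeneSet(set_id=f"SET{i + 1:03d}",
                            description=f"synthetic set {i + 1}",
                            members=tuple(members)))
    return GeneSetCollection(sets=sets, universe=list(gene_ids))


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(
    matrix: TimeCourseMatrix,
    models: Sequence[TranscriptModel],
    truth: SimulationTruth,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write a complete ingestible dataset: one quant.sf per time point,
    tx2gene TSV, GTF, transcript FASTA and truth tables. Returns a
    manifest of logical name -> path. Re-reading the quant files with the
    I/O layer reproduces the matrix bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    model_by_id = {m.transcript_id: m for m in models}

    for j, t in enumerate(matrix.times):
        path = out / f"quant_t{t:g}.sf"
        with open(path, "w") as fh:
            fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
            for i, tx in enumerate(matrix.transcript_ids):
                model = model_by_id.get(tx)
                length = model.length if model else 1000
                eff = max(1.0, length - 100.0)
                tpm = float(matrix.values[i, j])
                fh.write(
                    f"{tx}\t{length}\t{eff:.3f}\t{tpm!r}\t{tpm * eff / 1000:.3f}\n"
                )
        manifest[f"quant_t{t:g}"] = str(path)

    t2g = out / "tx2gene.tsv"
    with open(t2g, "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx in matrix.transcript_ids:
            fh.write(f"{tx}\t{matrix.tx2gene[tx]}\n")
    manifest["tx2gene"] = str(t2g)

    gtf = out / "models.gtf"
    with open(gtf, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                )
                fh.write(
                    f"chr_{m.gene_id}\tsynthetic\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
    manifest["gtf"] = str(gtf)

    fasta = out / "transcripts.fa"
    with open(fasta, "w") as fh:
        for m in models:
            if m.sequence is None:
                continue
            fh.write(f">{m.transcript_id} gene={m.gene_id}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i:i + 70] + "\n")
    manifest["fasta"] = str(fasta)

    sw = out / "truth_switches.tsv"
    with open(sw, "w") as fh:
        fh.write("gene_id\tiso_a\tiso_b\tcrossing_times_h\tamplitude_tpm\n")
        for s in truth.switches:
            times = ",".join(f"{c:g}" for c in s.crossing_times)
            fh.write(f"{s.gene_id}\t{s.iso_a}\t{s.iso_b}\t{times}\t{s.amplitude:g}\n")
    manifest["truth_switches"] = str(sw)

    pr = out / "truth_pairs.tsv"
    with open(pr, "w") as fh:
        fh.write(
            "gene_id\tiso_a\tiso_b\tarchetype\tcoding_a\tcoding_b\t"
            "nmd_a\tnmd_b\tsplice_events\torf_class_b_vs_a\tir_carrier\n"
        )
        for p in truth.pairs:
            fh.write(
                f"{p.gene_id}\t{p.iso_a}\t{p.iso_b}\t{p.archetype}\t"
                f"{p.coding[p.iso_a]}\t{p.coding[p.iso_b]}\t"
                f"{p.nmd[p.iso_a]}\t{p.nmd[p.iso_b]}\t"
                f"{','.join(sorted(p.splice_events))}\t{p.orf_class_b_vs_a}\t"
                f"{p.ir_carrier or ''}\n"
            )
    manifest["truth_pairs"] = str(pr)
    return manifest


def read_dataset_matrix(manifest_or_dir: Mapping[str, str] | str | Path) -> TimeCourseMatrix:
    """Re-ingest a written dataset's quant files into a time-course matrix
    (the round-trip counterpart of :func:`write_dataset`)."""
    from .io_formats import read_tx2gene

    if isinstance(manifest_or_dir, (str, Path)):
        d = Path(manifest_or_dir)
        quants = sorted(d.glob("quant_t*.sf"))
        t2g_path = d / "tx2gene.tsv"
    else:
        quants = [Path(v) for k, v in manifest_or_dir.items()
                  if k.startswith("quant_t")]
        t2g_path = Path(manifest_or_dir["tx2gene"])
    samples = []
    for q in quants:
        time = float(q.stem.split("quant_t")[1])
        samples.append((time, read_quant_table(q)))
    return assemble_time_course(samples, read_tx2gene(t2g_path))
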