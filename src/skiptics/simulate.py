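"""Synthetic fixtures with machine-readable truth tables.

Three generators emulate the statistical structure of an exon-skipping
overexpression experiment:

* :func:`simulate_junctions` — per-sample junction read counts for a panel of
  three-exon genes whose middle (target) exon has a known true inclusion
  fraction per condition. Counts follow a Poisson factorization: per exon and
  sample, the exclusion junction draws ``E ~ Poisson(d * (1 - psi))`` and each
  inclusion junction draws ``I ~ Poisson(d * psi)`` where ``d`` is the mean
  informative depth per splice site. By Poisson thinning, each site's total
  ``I + E`` is Poisson(d) and ``I | I + E`` is Binomial(I + E, psi), while a
  single exclusion interval is shared by both sites, exactly as a junction
  caller sees it. An optional beta-binomial mode adds the overdispersion real
  junction counts show.
* :func:`simulate_genome` — a FASTA + GTF pair whose background sequence is
  drawn over {A, C} only (so no spurious UG/GU dinucleotide can occur) with
  (TG)ₖ runs planted at specified splice-site offsets; repeat-profile
  expectations on this background are exact, not approximate.
* :func:`simulate_dose` — wild-type and NLS-mutant dose-response series
  generated from a known passive-diffusion fraction and a monotone response
  curve, with optional multiplicative noise on the skipping response.

All draws are fixed by ``SimConfig.seed``; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .dose import DoseObservation, ResponseCurve
from .junction_io import (
    ExonRecord,
    SpliceJunction,
    write_junction_bed,
)
from .motifs import reverse_complement

_FASTA_WIDTH = 60


@dataclass(frozen=True, slots=True)
class RepeatInsert:
    """One (TG)ₖ run planted at a sense-strand offset from a splice site."""

    anchor: Literal["3SS", "5SS"]
    offset: int  # sense-strand offset of the run's first base (0 = anchored exonic base)
    n_units: int  # number of TG units; run length is 2 * n_units

    @property
    def length(self) -> int:
        return 2 * self.n_units


@dataclass(frozen=True, slots=True)
class DoseSimSpec:
    """Ground truth for the dose-response generator.

    The default response-curve knots place skipping onset between 1.1- and
    1.5-fold nuclear TDP-43 (about 40% skipping at 1.5-fold and near-complete
    repression by 2-fold, saturating above), and the default diffusion
    fraction is 0.45. Construct levels are chosen so the wild-type series
    covers every knot of the true curve and the NLS-mutant series stays within
    the strictly increasing part of the wild-type range.
    """

    diffusion_fraction: float = 0.45
    curve_knots: tuple[tuple[float, float], ...] = (
        (1.0, 0.0),
        (1.1, 5.0),
        (1.5, 40.0),
        (2.0, 90.0),
        (4.0, 95.0),
    )
    noise_sd: float = 0.05  # multiplicative SD on the skipping response
    wt_levels: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0)
    nlsm_levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.0, 5.0)
    endogenous_level: float = 1.0

    def true_curve(self) -> ResponseCurve:
        knots = np.asarray(self.curve_knots, dtype=float)
        if np.any(np.diff(knots[:, 1]) < 0):
            raise ValueError("dose curve knots must be non-decreasing")
        return ResponseCurve(folds=knots[:, 0], values=knots[:, 1])

    def __post_init__(self) -> None:
        if not 0.0 <= self.diffusion_fraction <= 1.0:
            raise ValueError("diffusion_fraction must be in [0, 1]")
        self.true_curve()  # validates knot monotonicity


@dataclass(frozen=True, slots=True)
class SimConfig:
    """All knobs of the synthetic experiment.

    True control PSI is drawn uniformly from ``psi_control_range`` (default
    >= 0.92, i.e. constitutive exons); ``n_skiptic`` randomly chosen exons get
    a treated PSI shifted by a delta drawn from ``skiptic_delta_range``
    (default -0.9..-0.5, deep skipping), the rest are unchanged.
    """

    seed: int = 0
    n_genes: int = 20
    read_depth: float = 100.0  # mean informative reads per splice site
    n_replicates: int = 3  # per condition
    n_skiptic: int = 5
    psi_control_range: tuple[float, float] = (0.92, 1.0)
    skiptic_delta_range: tuple[float, float] = (-0.9, -0.5)
    exon_length_range: tuple[int, int] = (60, 180)
    flank_exon_length: int = 150
    intron_length: int = 1000
    flank: int = 400
    repeat_spec: tuple[RepeatInsert, ...] = (
        RepeatInsert("3SS", -60, 10),
        RepeatInsert("5SS", 15, 10),
    )
    repeat_exon_fraction: float = 1.0
    overdispersion: float | None = None  # beta-binomial concentration
    dose: DoseSimSpec = field(default_factory=DoseSimSpec)

    def __post_init__(self) -> None:
        if self.n_skiptic > self.n_genes:
            raise ValueError("n_skiptic cannot exceed n_genes")
        for lo, hi in (self.psi_control_range,):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("psi_control_range must be within [0, 1]")
        if not 0.0 <= self.repeat_exon_fraction <= 1.0:
            raise ValueError("repeat_exon_fraction must be in [0, 1]")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        for ins in self.repeat_spec:
            if abs(ins.offset) > self.flank or abs(ins.offset + ins.length - 1) > self.flank:
                raise ValueError(
                    f"planted repeat {ins} does not fit inside the +/-{self.flank} window"
                )
        if self.intron_length <= self.flank:
            raise ValueError("intron_length must exceed the window flank")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """Layout of one synthetic three-exon gene on its own contig."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[ExonRecord, ...]  # genomic order: upstream, target, downstream
    contig_length: int
    psi_control: float
    psi_treated: float
    is_skiptic: bool

    @property
    def target(self) -> ExonRecord:
        return self.exons[1]


def build_gene_models(config: SimConfig) -> list[GeneModel]:
    """Deterministic gene layout plus true PSI assignment."""
    rng = np.random.default_rng([config.seed, 1])
    margin = config.flank + 100
    skiptic_idx = set(
        rng.choice(config.n_genes, size=config.n_skiptic, replace=False).tolist()
    )
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        gene_id = f"G{g:04d}"
        transcript_id = f"T{g:04d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if g % 2 == 0 else "-"
        target_len = int(rng.integers(*config.exon_length_range, endpoint=True))
        e1_start = margin
        e1_end = e1_start + config.flank_exon_length
        t_start = e1_end + config.intron_length
        t_end = t_start + target_len
        e3_start = t_end + config.intron_length
        e3_end = e3_start + config.flank_exon_length
        contig_length = e3_end + margin
        # exon numbering follows transcription order
        order = (1, 2, 3) if strand == "+" else (3, 2, 1)
        exons = tuple(
            ExonRecord(
                chrom=chrom,
                start=s,
                end=e,
                strand=strand,
                gene_id=gene_id,
                exon_id=f"{transcript_id}_exon{num}",
                transcript_id=transcript_id,
            )
            for (s, e), num in zip(
                ((e1_start, e1_end), (t_start, t_end), (e3_start, e3_end)), order
            )
        )
        psi_control = float(rng.uniform(*config.psi_control_range))
        if g in skiptic_idx:
            delta = float(rng.uniform(*config.skiptic_delta_range))
            psi_treated = float(np.clip(psi_control + delta, 0.0, 1.0))
        else:
            psi_treated = psi_control
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                contig_length=contig_length,
                psi_control=psi_control,
                psi_treated=psi_treated,
                is_skiptic=g in skiptic_idx,
            )
        )
    return genes


@dataclass(frozen=True, slots=True)
class JunctionSim:
    """Simulated junction counts plus their truth table."""

    samples: dict[str, list[SpliceJunction]]
    truth: pd.DataFrame
    genes: tuple[GeneModel, ...]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "junctions").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        for sample_id in sorted(self.samples):
            write_junction_bed(
                self.samples[sample_id],
                outdir / "junctions" / f"{sample_id}.bed",
            )
        self.truth.to_csv(outdir / "truth" / "junctions.tsv", sep="\t", index=False)


def simulate_junctions(config: SimConfig) -> JunctionSim:
    """Draw junction read counts for every gene, sample, and condition."""
    genes = build_gene_models(config)
    rng = np.random.default_rng([config.seed, 2])
    if config.read_depth == 0:
        warnings.warn("read_depth is 0: all junction counts are zero", stacklevel=2)
    samples: dict[str, list[SpliceJunction]] = {}
    for condition in ("control", "treated"):
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{condition}_{rep}"
            junctions: list[SpliceJunction] = []
            for gene in genes:
                psi = gene.psi_control if condition == "control" else gene.psi_treated
                if config.overdispersion is not None and 0.0 < psi < 1.0:
                    k = config.overdispersion
                    psi = float(rng.beta(psi * k, (1.0 - psi) * k))
                d = config.read_depth
                i_up = int(rng.poisson(d * psi))
                i_down = int(rng.poisson(d * psi))
                excl = int(rng.poisson(d * (1.0 - psi)))
                up, target, down = gene.exons
                junctions.append(
                    SpliceJunction(
                        gene.chrom, up.end, target.start, gene.strand, i_up, sample_id
                    )
                )
                junctions.append(
                    SpliceJunction(
                        gene.chrom, target.end, down.start, gene.strand, i_down, sample_id
                    )
                )
                junctions.append(
                    SpliceJunction(
                        gene.chrom, up.end, down.start, gene.strand, excl, sample_id
                    )
                )
            samples[sample_id] = junctions
    truth = pd.DataFrame(
        [
            {
                "exon_id": g.target.exon_id,
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.target.start,
                "end": g.target.end,
                "strand": g.strand,
                "psi_control": g.psi_control,
                "psi_treated": g.psi_treated,
                "is_skiptic": g.is_skiptic,
            }
            for g in genes
        ]
    )
    return JunctionSim(samples=samples, truth=truth, genes=tuple(genes))


@dataclass(frozen=True, slots=True)
class GenomeSim:
    """Simulated genome, annotation, and planted-repeat truth table."""

    contigs: dict[str, str]
    exons: tuple[ExonRecord, ...]
    genes: tuple[GeneModel, ...]
    repeat_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        fasta = outdir / "genome.fa"
        gtf = outdir / "annotation.gtf"
        with open(fasta, "w") as handle:
            for chrom in sorted(self.contigs):
                handle.write(f">{chrom}\n")
                seq = self.contigs[chrom]
                for i in range(0, len(seq), _FASTA_WIDTH):
                    handle.write(seq[i : i + _FASTA_WIDTH] + "\n")
        with open(gtf, "w") as handle:
            handle.write("#!genome synthetic\n")
            for gene in self.genes:
                span = (gene.exons[0].start + 1, gene.exons[-1].end)
                attrs = f'gene_id "{gene.gene_id}";'
                handle.write(
                    f"{gene.chrom}\tsim\tgene\t{span[0]}\t{span[1]}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}";'
                handle.write(
                    f"{gene.chrom}\tsim\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for exon in gene.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{gene.transcript_id}"; '
                        f'exon_id "{exon.exon_id}";'
                    )
                    handle.write(
                        f"{gene.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
        self.repeat_truth.to_csv(outdir / "truth" / "repeats.tsv", sep="\t", index=False)
        return fasta, gtf


def _planted_span(exon: ExonRecord, insert: RepeatInsert) -> tuple[int, int]:
    """Genomic half-open span of a planted run, given sense-strand offsets."""
    if (insert.anchor == "3SS") == (exon.strand == "+"):
        center = exon.start
    else:
        center = exon.end - 1
    if exon.strand == "+":
        start = center + insert.offset
        return start, start + insert.length
    end_incl = center - insert.offset
    return end_incl - insert.length + 1, end_incl + 1


def simulate_genome(config: SimConfig) -> GenomeSim:
    """Build the {A, C}-background genome with planted (TG)ₖ runs."""
    genes = build_gene_models(config)
    rng = np.random.default_rng([config.seed, 3])
    n_planted = int(np.ceil(config.repeat_exon_fraction * len(genes)))
    planted_genes = set(
        rng.choice(len(genes), size=n_planted, replace=False).tolist()
    )
    contigs: dict[str, str] = {}
    truth_rows = []
    for gi, gene in enumerate(genes):
        # The UG-free background must hold on the SENSE strand: use {A, C} on
        # '+' contigs and its reverse complement {T, G} on '-' contigs.
        alphabet = b"AC" if gene.strand == "+" else b"TG"
        seq = rng.choice(np.frombuffer(alphabet, dtype="S1"), size=gene.contig_length)
        spans: list[tuple[int, int]] = []
        if gi in planted_genes:
            for insert in config.repeat_spec:
                start, end = _planted_span(gene.target, insert)
                if not (0 <= start < end <= gene.contig_length):
                    raise ValueError(
                        f"planted repeat {insert} falls outside contig {gene.chrom}"
                    )
                for s, e in spans:
                    if start < e and s < end:
                        raise ValueError(
                            f"planted repeats overlap on {gene.chrom}: "
                            f"[{s}, {e}) and [{start}, {end})"
                        )
                spans.append((start, end))
                run = "TG" * insert.n_units
                if gene.strand == "-":
                    run = reverse_complement(run)
                seq[start:end] = np.frombuffer(run.encode(), dtype="S1")
                truth_rows.append(
                    {
                        "exon_id": gene.target.exon_id,
                        "gene_id": gene.gene_id,
                        "strand": gene.strand,
                        "anchor": insert.anchor,
                        "offset_start": insert.offset,
                        "offset_end": insert.offset + insert.length - 1,
                        "n_units": insert.n_units,
                        "genome_start": start,
                        "genome_end": end,
                    }
                )
        contigs[gene.chrom] = seq.tobytes().decode()
    exons = tuple(exon for gene in genes for exon in gene.exons)
    return GenomeSim(
        contigs=contigs,
        exons=exons,
        genes=tuple(genes),
        repeat_truth=pd.DataFrame(
            truth_rows,
            columns=[
                "exon_id",
                "gene_id",
                "strand",
                "anchor",
                "offset_start",
                "offset_end",
                "n_units",
                "genome_start",
                "genome_end",
            ],
        ),
    )


@dataclass(frozen=True, slots=True)
class DoseSim:
    """Simulated dose-response observations plus their generating truth."""

    observations: tuple[DoseObservation, ...]
    truth: pd.DataFrame

    @property
    def wt(self) -> list[DoseObservation]:
        return [o for o in self.observations if o.construct == "WT"]

    @property
    def nlsm(self) -> list[DoseObservation]:
        return [o for o in self.observations if o.construct == "NLSm"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        from .dose import write_dose_tsv

        write_dose_tsv(self.observations, outdir / "dose.tsv")
        self.truth.to_csv(outdir / "truth" / "dose.tsv", sep="\t", index=False)


def simulate_dose(config: SimConfig) -> DoseSim:
    """Generate WT and NLSm dose-response series from the true curve."""
    spec = config.dose
    curve = spec.true_curve()
    rng = np.random.default_rng([config.seed, 4])
    observations: list[DoseObservation] = []
    for construct, levels, nuclear_frac in (
        ("WT", spec.wt_levels, 1.0),
        ("NLSm", spec.nlsm_levels, spec.diffusion_fraction),
    ):
        for i, level in enumerate(levels):
            fold = spec.endogenous_level + nuclear_frac * level
            response = float(curve(fold))
            if spec.noise_sd > 0:
                response *= 1.0 + float(rng.normal(0.0, spec.noise_sd))
            observations.append(
                DoseObservation(
                    construct=construct,
                    construct_level=float(level),
                    endogenous_level=spec.endogenous_level,
                    skipping_percent=float(np.clip(response, 0.0, 100.0)),
                    fraction_id=f"F{i + 1}",
                )
            )
    truth = pd.DataFrame(
        {
            "parameter": ["diffusion_fraction", "noise_sd", "endogenous_level"]
            + [f"knot_{i}" for i in range(len(spec.curve_knots))],
            "value": [spec.diffusion_fraction, spec.noise_sd, spec.endogenous_level]
            + [f"{f}:{v}" for f, v in spec.curve_knots],
        }
    )
    return DoseSim(observations=tuple(observations), truth=truth)


def simulate_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture directory: junctions, genome, annotation, dose.

    Returns the paths of the main artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    junctions = simulate_junctions(config)
    junctions.write(outdir)
    genome = simulate_genome(config)
    fasta, gtf = genome.write(outdir)
    dose = simulate_dose(config)
    dose.write(outdir)
    sample_paths = {
        sample_id: outdir / "junctions" / f"{sample_id}.bed"
        for sample_id in sorted(junctions.samples)
    }
    return {
        "fasta": fasta,
        "gtf": gtf,
        "dose": outdir / "dose.tsv",
        "truth_dir": outdir / "truth",
        **sample_paths,
    }


def noiseless(config: SimConfig) -> SimConfig:
    """A copy of the config with dose-response noise switched off."""
    return replace(config, dose=replace(config.dose, noise_sd=0.0))
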