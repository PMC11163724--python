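"""End-to-end workflow: PSI -> delta-PSI -> skiptic calls -> motif profiles ->
NMD summary (-> dose fit), with a run manifest recording every tunable."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import pyfaidx

from . import calling, dose, junction_io, motifs, nmd, psi
from .errors import ConfigError, SkipticsError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and bookkeeping for one pipeline run.

    A plain-text ``key=value`` config file maps 1:1 onto these fields;
    list-valued fields take comma-separated paths.
    """

    control_junctions: Sequence[str] = field(default_factory=list)
    treated_junctions: Sequence[str] = field(default_factory=list)
    gtf: str = ""
    fasta: str = ""
    dose_tsv: str = ""
    junction_format: str = "bed"  # "bed" | "star"
    outdir: str = "skiptics_out"
    min_reads: int = psi.DEFAULT_MIN_READS
    constitutive_threshold: float = calling.DEFAULT_CONSTITUTIVE_THRESHOLD
    skip_threshold: float = calling.DEFAULT_SKIP_THRESHOLD
    flank: int = motifs.DEFAULT_FLANK
    detection_floor: float = dose.DEFAULT_DETECTION_FLOOR
    diffusion_fraction: float = dose.DEFAULT_DIFFUSION_FRACTION
    aggregator: str = "pooled"
    motif_profiles: bool = True
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        values: dict = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path} line {lineno}: expected key=value")
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: dict) -> "RunConfig":
        kwargs: dict = {}
        by_name = {f.name: f for f in fields(cls)}
        for key, value in values.items():
            if key not in by_name:
                raise ConfigError(f"unknown config key {key!r}")
            if key in ("control_junctions", "treated_junctions"):
                if isinstance(value, str):
                    value = [p.strip() for p in value.split(",") if p.strip()]
                kwargs[key] = list(value)
            elif by_name[key].type in ("int", int):
                kwargs[key] = int(value)
            elif by_name[key].type in ("float", float):
                kwargs[key] = float(value)
            elif by_name[key].type in ("bool", bool):
                kwargs[key] = (
                    value if isinstance(value, bool) else str(value).lower() in ("1", "true", "yes")
                )
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.control_junctions or not self.treated_junctions:
            raise ConfigError("control_junctions and treated_junctions are required")
        for path in [*self.control_junctions, *self.treated_junctions, self.gtf]:
            if not path:
                raise ConfigError("a GTF annotation is required")
            if not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")
        if self.motif_profiles and not self.fasta:
            raise ConfigError(
                "stage 'motif': motif profiles requested but no FASTA configured "
                "(set motif_profiles=false to skip)"
            )
        if self.fasta and not Path(self.fasta).exists():
            raise ConfigError(f"input path does not exist: {self.fasta}")
        if self.dose_tsv and not Path(self.dose_tsv).exists():
            raise ConfigError(f"input path does not exist: {self.dose_tsv}")
        if self.junction_format not in ("bed", "star"):
            raise ConfigError("junction_format must be 'bed' or 'star'")
        if not 0 < self.constitutive_threshold < 1 or not 0 < self.skip_threshold < 1:
            raise ConfigError("thresholds must lie in (0, 1)")

    def tunables(self) -> dict:
        return {
            "min_reads": self.min_reads,
            "constitutive_threshold": self.constitutive_threshold,
            "skip_threshold": self.skip_threshold,
            "flank": self.flank,
            "detection_floor": self.detection_floor,
            "diffusion_fraction": self.diffusion_fraction,
            "aggregator": self.aggregator,
            "motif_profiles": self.motif_profiles,
            "junction_format": self.junction_format,
            "seed": self.seed,
        }

    def digest(self) -> str:
        payload = {
            "inputs": {
                "control_junctions": list(self.control_junctions),
                "treated_junctions": list(self.treated_junctions),
                "gtf": self.gtf,
                "fasta": self.fasta,
                "dose_tsv": self.dose_tsv,
            },
            "tunables": self.tunables(),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


class StageError(SkipticsError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_samples(paths: Sequence[str], fmt: str) -> dict[str, psi.JunctionIndex]:
    reader = (
        junction_io.read_junction_bed if fmt == "bed" else junction_io.read_star_sj
    )
    samples: dict[str, psi.JunctionIndex] = {}
    for path in paths:
        sample_id = Path(path).stem
        samples[sample_id] = psi.index_junctions(reader(path, sample_id))
    return samples


def run_end_to_end(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns the manifest dictionary. On any stage failure the manifest is
    written with ``status: incomplete`` naming the failed stage, and the
    error is re-raised wrapped in :class:`StageError`.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "skiptics",
        "config_sha256": config.digest(),
        "tunables": config.tunables(),
        "inputs": {
            "control_junctions": list(config.control_junctions),
            "treated_junctions": list(config.treated_junctions),
            "gtf": config.gtf,
            "fasta": config.fasta or None,
            "dose_tsv": config.dose_tsv or None,
        },
        "stages": [],
        "status": "incomplete",
    }
    stage = "psi"
    try:
        exons = junction_io.unique_exon_intervals(
            junction_io.read_exons_gtf(config.gtf)
        )
        control = _read_samples(config.control_junctions, config.junction_format)
        treated = _read_samples(config.treated_junctions, config.junction_format)
        psi_control = psi.psi_matrix(exons, control, config.min_reads)
        psi_treated = psi.psi_matrix(exons, treated, config.min_reads)
        frame = psi.psi_to_frame(psi_control + psi_treated)
        frame.to_csv(outdir / "psi.tsv", sep="\t", index=False)
        manifest["stages"].append({"name": "psi", "n_exons": len(exons)})

        stage = "delta"
        records = psi.delta_psi(
            psi_control, psi_treated, config.aggregator, config.min_reads
        )
        psi.delta_to_frame(records).to_csv(
            outdir / "delta_psi.tsv", sep="\t", index=False
        )
        manifest["stages"].append({"name": "delta", "n_records": len(records)})

        stage = "call"
        gene_ids = {e.exon_id: e.gene_id for e in exons}
        calls = calling.call_skiptics(
            records,
            config.constitutive_threshold,
            config.skip_threshold,
            gene_ids=gene_ids,
        )
        calling.calls_to_frame(calls).to_csv(
            outdir / "skiptic_calls.tsv", sep="\t", index=False
        )
        calling.write_skiptic_bed(calls, exons, outdir / "skiptic_exons.bed")
        label_counts = calling.summarize_calls(calls)
        manifest["stages"].append({"name": "call", "counts": label_counts})
        skiptic_ids = {c.exon_id for c in calls if c.label == "skiptic"}
        skiptic_exons = [e for e in exons if e.exon_id in skiptic_ids]

        stage = "motif"
        if config.motif_profiles and skiptic_exons:
            genome = pyfaidx.Fasta(config.fasta)
            for anchor in ("3SS", "5SS"):
                profile = motifs.splice_site_profile(
                    skiptic_exons, genome, anchor, config.flank
                )
                motifs.write_profile_tsv(
                    profile, outdir / f"repeat_profile_{anchor}.tsv"
                )
            manifest["stages"].append(
                {"name": "motif", "n_sequences": len(skiptic_exons)}
            )
        else:
            manifest["stages"].append({"name": "motif", "skipped": True})

        stage = "nmd"
        if skiptic_exons:
            nmd_calls = [nmd.predict_nmd_frame(e) for e in skiptic_exons]
            nmd.write_nmd_tsv(nmd_calls, outdir / "nmd_calls.tsv")
            summary = nmd.summarize_nmd(nmd_calls)
            manifest["stages"].append(
                {
                    "name": "nmd",
                    "n_nmd": summary.n_nmd,
                    "n_total": summary.n_total,
                    "fraction": summary.fraction,
                }
            )
        else:
            manifest["stages"].append({"name": "nmd", "skipped": True})

        stage = "dose"
        if config.dose_tsv:
            observations = dose.read_dose_tsv(config.dose_tsv)
            fit = dose.fit_dose_model(observations, config.detection_floor)
            (outdir / "dose_fit.json").write_text(
                json.dumps(fit.summary(), indent=2) + "\n"
            )
            manifest["stages"].append({"name": "dose", **fit.summary()})
        else:
            manifest["stages"].append({"name": "dose", "skipped": True})

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        raise StageError(stage, exc) from exc
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
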