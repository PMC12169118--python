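"""End-to-end analysis pipeline driven by one YAML configuration.

Stages, per structure: sequence extraction (FASTA), propensity profiles,
consensus linear-epitope calling from predictor score tracks, residue
interaction network + interface subnetwork, quaternary-epitope clustering
from conformational seeds, and a run manifest with parameters and input
checksums.  Identical configuration + inputs yield byte-identical outputs.

Configuration schema (YAML)::

    seed: 0
    output_dir: out
    min_support: 2
    rin: {cutoff: 6.0, atom_mode: CA}
    quaternary: {radius: 6.0, atom_mode: any_heavy}
    structures:
      - id: toy
        path: toy.pdb
        chains: [A, B]            # optional; default: all chains
        profile_chain: A          # optional; default: first chain
        tracks:                   # linear-predictor score tracks
          - {path: bp1.tsv, predictor: bepipred1}        # default threshold
          - {path: sema.tsv, predictor: sema, threshold: 1.1}
        seeds: seeds.tsv          # conformational residues: chain, number[, score]
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consensus as cons
from . import profiles as prof
from . import quaternary as quat
from . import rin as rinmod
from .errors import PipelineConfigError, QuatmapError
from .structure import (
    ResidueKey,
    Structure,
    chain_sequence,
    read_pdb,
    write_cluster_table,
    write_fasta,
)

__all__ = ["TrackInput", "StructureJob", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class TrackInput:
    path: Path
    predictor: str
    threshold: float | None = None


@dataclass
class StructureJob:
    id: str
    path: Path
    chains: list[str] | None = None
    profile_chain: str | None = None
    tracks: list[TrackInput] = field(default_factory=list)
    seeds: Path | None = None


@dataclass
class PipelineConfig:
    output_dir: Path
    structures: list[StructureJob]
    min_support: int = 2
    rin_cutoff: float = 6.0
    rin_atom_mode: str = rinmod.CA_MODE
    quaternary_radius: float = 6.0
    quaternary_atom_mode: str = rinmod.ANY_HEAVY
    seed: int = 0

    def __post_init__(self) -> None:
        for value, name in (
            (self.min_support, "min_support"),
            (self.rin_cutoff, "rin.cutoff"),
            (self.quaternary_radius, "quaternary.radius"),
        ):
            if value <= 0:
                raise PipelineConfigError(f"{name} must be positive, got {value}")
        if not self.structures:
            raise PipelineConfigError("no structures configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"{path}: config must be a mapping")
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        jobs = []
        for entry in raw.get("structures", []):
            tracks = [
                TrackInput(
                    path=resolve(t["path"]),
                    predictor=t["predictor"],
                    threshold=t.get("threshold"),
                )
                for t in entry.get("tracks", [])
            ]
            jobs.append(
                StructureJob(
                    id=str(entry.get("id") or Path(entry["path"]).stem),
                    path=resolve(entry["path"]),
                    chains=entry.get("chains"),
                    profile_chain=entry.get("profile_chain"),
                    tracks=tracks,
                    seeds=resolve(entry["seeds"]) if entry.get("seeds") else None,
                )
            )
        rin_cfg = raw.get("rin", {})
        quat_cfg = raw.get("quaternary", {})
        return cls(
            output_dir=resolve(raw.get("output_dir", "quatmap_out")),
            structures=jobs,
            min_support=int(raw.get("min_support", 2)),
            rin_cutoff=float(rin_cfg.get("cutoff", 6.0)),
            rin_atom_mode=str(rin_cfg.get("atom_mode", rinmod.CA_MODE)),
            quaternary_radius=float(quat_cfg.get("radius", 6.0)),
            quaternary_atom_mode=str(quat_cfg.get("atom_mode", rinmod.ANY_HEAVY)),
            seed=int(raw.get("seed", 0)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_text(path: Path, text: str) -> None:
    path.write_text(text)


def _write_frame(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_seed_table(path: Path, structure_id: str) -> quat.EpitopeSeedSet:
    """Read a conformational seed table (TSV: chain, number)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in table.columns}
    if "chain" not in cols or "number" not in cols:
        raise PipelineConfigError(f"{path}: seed table needs chain and number columns")
    keys = {
        ResidueKey(str(row[cols["chain"]]), int(row[cols["number"]]))
        for _, row in table.iterrows()
    }
    return quat.EpitopeSeedSet(structure_id=structure_id, residues=keys)


def _run_structure(job: StructureJob, cfg: PipelineConfig, outdir: Path) -> dict:
    structure = read_pdb(job.path, id=job.id)
    chains = job.chains or list(structure.chains)
    outputs: dict[str, str] = {}

    fasta = write_fasta(structure, chains)
    _write_text(outdir / f"{job.id}.fasta", fasta)
    outputs["fasta"] = f"{job.id}.fasta"

    profile_chain = job.profile_chain or chains[0]
    seq, _ = chain_sequence(structure, profile_chain)
    frames = []
    for scale_name in prof.builtin_scale_names():
        scale = prof.load_scale(scale_name)
        if len(seq) < scale.default_window:
            logger.warning("profile: chain %s too short for %s", profile_chain, scale_name)
            continue
        if scale_name == "emini_accessibility":
            p = prof.emini_accessibility(seq)
        elif scale_name == "kolaskar_antigenicity":
            p = prof.kolaskar_antigenicity(seq)
        else:
            p = prof.sliding_window_profile(seq, scale)
        frame = prof.profile_frame(p)
        frame.insert(0, "scale", scale_name)
        frames.append(frame)
    if frames:
        _write_frame(outdir / f"{job.id}.profiles.tsv", pd.concat(frames, ignore_index=True))
        outputs["profiles"] = f"{job.id}.profiles.tsv"

    if job.tracks:
        binary = []
        for t in job.tracks:
            track = cons.read_score_track(
                t.path, predictor_name=t.predictor, sequence_id=job.id,
                threshold=t.threshold, reference_sequence=None,
            )
            binary.append(cons.binarize(track))
        regions = cons.consensus_regions(
            binary, min_support=cfg.min_support,
            sequence=seq if all(len(b) == len(seq) for b in binary) else "",
        )
        _write_frame(
            outdir / f"{job.id}.consensus.tsv",
            cons.regions_frame(regions, sequence_id=job.id),
        )
        outputs["consensus"] = f"{job.id}.consensus.tsv"

    rin = rinmod.build_rin(structure, cutoff=cfg.rin_cutoff, atom_mode=cfg.rin_atom_mode)
    _write_text(outdir / f"{job.id}.rin.sif", rinmod.export_sif(rin))
    _write_frame(outdir / f"{job.id}.rin_edges.tsv", rinmod.edge_attribute_frame(rin))
    _write_frame(outdir / f"{job.id}.rin_nodes.tsv",
                 rinmod.node_attribute_frame(rin, structure))
    iface = rinmod.interface_subnetwork(rin)
    _write_text(outdir / f"{job.id}.interface.sif", rinmod.export_sif(iface))
    outputs.update(
        rin=f"{job.id}.rin.sif", rin_edges=f"{job.id}.rin_edges.tsv",
        rin_nodes=f"{job.id}.rin_nodes.tsv", interface=f"{job.id}.interface.sif",
    )

    if job.seeds is not None:
        seed_set = read_seed_table(job.seeds, job.id)
        clusters = quat.build_quaternary_clusters(
            structure, seed_set,
            radius=cfg.quaternary_radius, atom_mode=cfg.quaternary_atom_mode,
        )
        text, frame = write_cluster_table(structure, clusters)
        _write_text(outdir / f"{job.id}.clusters.txt", text)
        _write_frame(outdir / f"{job.id}.clusters.tsv", frame)
        outputs["clusters"] = f"{job.id}.clusters.tsv"
        outputs["clusters_text"] = f"{job.id}.clusters.txt"

    inputs = {str(job.path): _sha256(job.path)}
    for t in job.tracks:
        inputs[str(t.path)] = _sha256(t.path)
    if job.seeds is not None:
        inputs[str(job.seeds)] = _sha256(job.seeds)
    return {"structure": job.id, "inputs": inputs, "outputs": outputs}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for job in config.structures:
        logger.info("pipeline: structure %s", job.id)
        try:
            records.append(_run_structure(job, config, outdir))
        except QuatmapError as exc:
            raise type(exc)(f"[structure {job.id}] {exc}") from exc
    from . import __version__

    manifest = {
        "version": __version__,
        "parameters": {
            "min_support": config.min_support,
            "rin": {"cutoff": config.rin_cutoff, "atom_mode": config.rin_atom_mode},
            "quaternary": {
                "radius": config.quaternary_radius,
                "atom_mode": config.quaternary_atom_mode,
            },
            "seed": config.seed,
        },
        "structures": records,
    }
    checks = {
        rec["outputs"][k]: _sha256(outdir / rec["outputs"][k])
        for rec in records
        for k in rec["outputs"]
    }
    manifest["output_checksums"] = dict(sorted(checks.items()))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
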