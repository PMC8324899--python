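"""End-to-end pipeline: extract -> cluster -> match -> classify -> abundance.

Two entry points: :func:`analyze` runs on in-memory inputs (the route the
test-suite and the synthetic generator use), :func:`run_pipeline` binds
it to files on disk, writes every intermediate TSV plus a JSON report,
and records a run manifest. Outputs are built in a temporary directory
and promoted atomically on success.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    ReferenceIndex,
    SampleProfile,
    normalize_coverage,
    profile_sample,
    spacer_dynamics,
)
from .classification import (
    Classification,
    demarcate,
    features_from_inputs,
    similarity_matrix,
)
from .classification import classify as classify_features
from .clustering import SpacerCluster, cluster_spacers
from .extraction import SpacerRecord, extract_spacers
from .io import iter_fastq, read_fasta, write_fasta
from .matching import (
    ProtospacerMatch,
    match_clusters_to_scaffolds,
    spacer_targeted_ids,
    summarize_linkage,
)


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the study's published thresholds."""

    reads: dict[str, str] = field(default_factory=dict)  # sample_id -> FASTQ path
    scaffolds: str | None = None
    references: str | None = None
    annotations: str | None = None
    dr: str | None = None
    dr_fasta: str | None = None
    host_id: str = "host"
    outdir: str = "spacerlink_out"
    spacer_min_len: int = 20
    spacer_max_len: int = 60
    cluster_identity: float = 0.99
    match_similarity: float = 0.80
    match_word_size: int = 7
    sim_denominator: str = "query"
    min_scaffold_len: int = 3000
    extensive_crispr: int = 5
    bacterial_evidence: int = 3
    max_mismatch_frac: float = 0.02
    species_threshold: float = 95.0
    genus_threshold: float = 15.8
    allow_partial: bool = False
    multi: str = "first"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_identity", "match_similarity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1]")
        if self.spacer_min_len > self.spacer_max_len:
            raise ValueError("spacer_min_len must not exceed spacer_max_len")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    spacers: list[SpacerRecord]
    clusters: list[SpacerCluster]
    matches: list[ProtospacerMatch]
    linkage: pd.DataFrame
    classifications: list[Classification]
    profiles: list[SampleProfile]
    dynamics: object  # DynamicsReport
    similarity: pd.DataFrame | None = None
    species: dict[str, int] | None = None
    genera: dict[str, int] | None = None

    @property
    def verdicts(self) -> dict[str, str]:
        return {c.scaffold_id: c.verdict for c in self.classifications}


def analyze(
    samples: dict[str, list[tuple[str, str]]],
    dr: str,
    scaffolds: list[tuple[str, str]],
    references: list[tuple[str, str]],
    config: PipelineConfig | None = None,
    annotations: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory reads, scaffolds and references."""
    cfg = config or PipelineConfig()
    spacers: list[SpacerRecord] = []
    for sample_id, reads in samples.items():
        spacers.extend(
            extract_spacers(
                reads,
                dr,
                sample_id=sample_id,
                min_len=cfg.spacer_min_len,
                max_len=cfg.spacer_max_len,
                allow_partial=cfg.allow_partial,
            )
        )
    clusters = cluster_spacers(spacers, threshold=cfg.cluster_identity)
    matches = match_clusters_to_scaffolds(
        clusters,
        scaffolds,
        min_similarity=cfg.match_similarity,
        word_size=cfg.match_word_size,
        sim_denominator=cfg.sim_denominator,
    )
    linkage = summarize_linkage(matches, scaffolds)
    targeted = spacer_targeted_ids(matches)
    features = features_from_inputs(scaffolds, annotations, targeted)
    classifications = [
        classify_features(
            f,
            min_len=cfg.min_scaffold_len,
            extensive_crispr=cfg.extensive_crispr,
            bacterial_evidence=cfg.bacterial_evidence,
        )
        for f in features
    ]
    idx = ReferenceIndex(references)
    profiles = [
        profile_sample(
            sample_id, reads, idx, max_mismatch_frac=cfg.max_mismatch_frac, multi=cfg.multi
        )
        for sample_id, reads in samples.items()
    ]
    normalize_coverage(profiles)
    virus_ids = [
        c.scaffold_id for c in classifications if c.verdict in ("virus", "putative_virus")
    ]
    dynamics = spacer_dynamics(clusters, matches, profiles, cfg.host_id, virus_ids)

    viral_genomes = [
        (sc_id, seq) for sc_id, seq in scaffolds if sc_id in set(virus_ids)
    ]
    similarity = species = genera = None
    if len(viral_genomes) >= 2:
        similarity = similarity_matrix(viral_genomes)
        species, genera = demarcate(
            similarity, cfg.species_threshold, cfg.genus_threshold
        )
    return PipelineResult(
        spacers,
        clusters,
        matches,
        linkage,
        classifications,
        profiles,
        dynamics,
        similarity,
        species,
        genera,
    )


def analyze_community(community, config: PipelineConfig | None = None) -> PipelineResult:
    """Run :func:`analyze` on an in-memory synthetic community."""
    from .synthetic import annotation_table

    samples = {
        s.sample_id: [(rec[0].split()[0], rec[1]) for rec in s.reads]
        for s in community.samples
    }
    scaffolds = [(r.id, r.sequence) for r in community.scaffolds]
    references = [(r.id, r.sequence) for r in community.reference_replicons]
    return analyze(
        samples, community.dr, scaffolds, references, config, annotation_table(community)
    )


def _spacer_table(spacers: list[SpacerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "read_id": s.read_id,
                "dr_label": s.dr_label,
                "dr_orientation": s.dr_orientation,
                "spacer_seq": s.sequence,
                "length": s.length,
            }
            for s in spacers
        ],
        columns=["sample_id", "read_id", "dr_label", "dr_orientation", "spacer_seq", "length"],
    )


def _cluster_table(clusters: list[SpacerCluster], sample_ids: list[str]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        row = {
            "cluster_id": cl.cluster_id,
            "representative": cl.representative,
            "length": len(cl.representative),
            "distinct_members": cl.distinct_members,
            "is_singleton": cl.is_singleton,
        }
        for s in sample_ids:
            row[f"count_{s}"] = cl.member_count_per_sample.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def _match_table(matches: list[ProtospacerMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": m.cluster_id,
                "scaffold_id": m.scaffold_id,
                "scaffold_start": m.scaffold_start,
                "scaffold_end": m.scaffold_end,
                "strand": m.strand,
                "aligned_length": m.aligned_length,
                "identities": m.identities,
                "similarity": round(m.similarity, 4),
            }
            for m in matches
        ],
        columns=[
            "cluster_id", "scaffold_id", "scaffold_start", "scaffold_end",
            "strand", "aligned_length", "identities", "similarity",
        ],
    )


def _profile_table(profiles: list[SampleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for rid in p.ref_lengths:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "reference": rid,
                    "reference_length": p.ref_lengths[rid],
                    "total_bp": p.total_bp,
                    "mapped_bp": p.mapped_bp[rid],
                    "raw_coverage": round(p.raw_coverage[rid], 6),
                    "normalized_coverage": round(p.normalized_coverage.get(rid, 0.0), 6),
                }
            )
    return pd.DataFrame(rows)


def write_result(
    result: PipelineResult, outdir: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write all pipeline tables; built in a temp dir, promoted atomically."""
    outdir = Path(outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    sample_ids = [p.sample_id for p in result.profiles]
    tmp = Path(tempfile.mkdtemp(prefix=".spacerlink-", dir=outdir.parent))
    try:
        _spacer_table(result.spacers).to_csv(tmp / "spacers.tsv", sep="\t", index=False)
        _cluster_table(result.clusters, sample_ids).to_csv(
            tmp / "clusters.tsv", sep="\t", index=False
        )
        write_fasta(
            tmp / "representatives.fasta",
            [(c.cluster_id, c.representative) for c in result.clusters],
        )
        _match_table(result.matches).to_csv(tmp / "matches.tsv", sep="\t", index=False)
        result.linkage.to_csv(tmp / "linkage.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "scaffold_id": c.scaffold_id,
                    "verdict": c.verdict,
                    "reasons": ";".join(c.reasons),
                }
                for c in result.classifications
            ]
        ).to_csv(tmp / "classification.tsv", sep="\t", index=False)
        _profile_table(result.profiles).to_csv(tmp / "profiles.tsv", sep="\t", index=False)
        result.dynamics.samples.to_csv(tmp / "dynamics_samples.tsv", sep="\t")
        result.dynamics.per_virus.to_csv(
            tmp / "dynamics_viruses.tsv", sep="\t", index=False
        )
        if result.similarity is not None:
            result.similarity.round(3).to_csv(tmp / "similarity.tsv", sep="\t")
            pd.DataFrame(
                [
                    {
                        "genome_id": g,
                        "species_cluster": result.species[g],
                        "genus_cluster": result.genera[g],
                    }
                    for g in result.similarity.index
                ]
            ).to_csv(tmp / "demarcation.tsv", sep="\t", index=False)
        report = {
            "n_spacer_occurrences": len(result.spacers),
            "n_spacer_clusters": len(result.clusters),
            "n_singleton_clusters": sum(1 for c in result.clusters if c.is_singleton),
            "n_matches": len(result.matches),
            "spacer_targeted_scaffolds": sorted(
                {m.scaffold_id for m in result.matches}
            ),
            "verdicts": result.verdicts,
        }
        with open(tmp / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        if config is not None:
            cfg_dict = dataclasses.asdict(config)
            manifest = {
                "spacerlink_version": __version__,
                "seed": config.seed,
                "config": cfg_dict,
                "config_sha256": hashlib.sha256(
                    json.dumps(cfg_dict, sort_keys=True).encode()
                ).hexdigest(),
            }
            with open(tmp / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
        outdir.mkdir(exist_ok=True)
        for f in tmp.iterdir():
            os.replace(f, outdir / f.name)
    finally:
        if tmp.exists():
            for f in tmp.iterdir():
                f.unlink()
            tmp.rmdir()


def load_clusters(path: str | Path) -> list[SpacerCluster]:
    """Rebuild SpacerCluster objects from a clusters.tsv."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        cl = SpacerCluster(row["cluster_id"], row["representative"])
        cl.members.add(row["representative"])
        for col in df.columns:
            if col.startswith("count_") and int(row[col]) > 0:
                cl.member_count_per_sample[col[len("count_") :]] = int(row[col])
        out.append(cl)
    return out


def load_matches(path: str | Path, clusters: list[SpacerCluster] | None = None):
    """Rebuild ProtospacerMatch objects from a matches.tsv."""
    from collections import Counter

    df = pd.read_csv(path, sep="\t")
    by_id = {c.cluster_id: c for c in clusters} if clusters else {}
    out = []
    for _, row in df.iterrows():
        cl = by_id.get(row["cluster_id"])
        out.append(
            ProtospacerMatch(
                row["cluster_id"],
                row["scaffold_id"],
                int(row["scaffold_start"]),
                int(row["scaffold_end"]),
                row["strand"],
                int(row["aligned_length"]),
                int(row["identities"]),
                float(row["similarity"]),
                Counter(cl.member_count_per_sample) if cl else Counter(),
            )
        )
    return out


def load_profiles(path: str | Path) -> list[SampleProfile]:
    """Rebuild SampleProfile objects from a profiles.tsv."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        p = SampleProfile(
            str(sid),
            int(grp["total_bp"].iloc[0]),
            dict(zip(grp["reference"], grp["mapped_bp"].astype(int))),
            dict(zip(grp["reference"], grp["reference_length"].astype(int))),
            dict(zip(grp["reference"], grp["normalized_coverage"].astype(float))),
        )
        out.append(p)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Disk-to-disk pipeline run driven by a :class:`PipelineConfig`."""
    if not config.reads:
        raise FileNotFoundError("no read files configured")
    for path in list(config.reads.values()) + [config.scaffolds, config.references]:
        if path is None:
            raise FileNotFoundError("scaffolds and references FASTA paths are required")
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    if config.dr:
        dr = config.dr
    elif config.dr_fasta:
        dr = read_fasta(config.dr_fasta)[0][1]
    else:
        raise ValueError("a direct repeat must be given via dr or dr_fasta")
    samples = {
        sid: list(iter_fastq(path)) for sid, path in config.reads.items()
    }
    scaffolds = read_fasta(config.scaffolds)
    references = read_fasta(config.references)
    annotations = None
    if config.annotations:
        annotations = pd.read_csv(config.annotations, sep="\t")
    result = analyze(samples, dr, scaffolds, references, config, annotations)
    write_result(result, config.outdir, config)
    return result
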