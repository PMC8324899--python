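"""Synthetic subsurface community generator with full ground truth.

Emulates the study system the pipeline is built for: one dominant host
genome carrying a CRISPR array (conserved direct repeat, variable
spacers), a handful of co-occurring viral genomes carrying protospacers
derived from host spacers with point mutations (a subset circular,
emitted in assembly convention with a duplicated terminal repeat),
minority background genomes, uniform-error shotgun reads, and multiple
timepoints with shifting virus abundance and leader-polarized spacer
turnover. Every planted feature is recorded so downstream stages can be
scored against known truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical config and seed reproduce every
emitted byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .sequtils import mutate, random_dna, revcomp, validate_dna

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class TimepointSpec:
    """Per-timepoint overrides applied relative to the previous timepoint."""

    label: str
    virus_weight_scale: float = 1.0
    abundance_overrides: dict[str, float] = field(default_factory=dict)
    n_new_spacers: int = 0
    n_lost_spacers: int = 0


def _default_timepoints() -> list[TimepointSpec]:
    # two-timepoint demo profile: virus decline plus spacer turnover
    return [
        TimepointSpec("t0"),
        TimepointSpec("t1", virus_weight_scale=0.5, n_new_spacers=3, n_lost_spacers=1),
    ]


@dataclass
class CommunityConfig:
    """Parameters of the synthetic community.

    Defaults describe the reference desk-scale community: a dominant
    100 kb host (weight 20) with a 30-spacer CRISPR array, three viruses
    (weights 8/4/2, so planted host-virus ratios 2.5/5/10) each carrying
    5 protospacers mutated at 2%/base, two background genomes, and 1e5
    150 bp reads per sample at 0.2%/base error.
    """

    seed: int = 0
    dr_sequence: str | None = None
    dr_length: int = 30
    host_length: int = 100_000
    n_host_spacers: int = 30
    spacer_len_range: tuple[int, int] = (30, 45)
    n_viruses: int = 3
    virus_len_range: tuple[int, int] = (5_000, 25_000)
    circular_fraction: float = 1 / 3
    terminal_repeat_len: int = 55
    protospacers_per_virus: int = 5
    protospacer_mutation_rate: float = 0.02
    n_background_genomes: int = 2
    background_len_range: tuple[int, int] = (20_000, 50_000)
    read_length: int = 150
    read_error_rate: float = 0.002
    n_reads: int = 100_000
    host_weight: float = 20.0
    virus_weights: tuple[float, ...] = (8.0, 4.0, 2.0)
    background_weight: float = 2.0
    per_sample_abundance: dict[str, float] | None = None
    acquisition_from_virus_fraction: float = 0.5
    mini_crispr_viruses: int = 1
    timepoints: list[TimepointSpec] = field(default_factory=_default_timepoints)

    def __post_init__(self) -> None:
        for name in (
            "circular_fraction",
            "protospacer_mutation_rate",
            "read_error_rate",
            "acquisition_from_virus_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dr_sequence is not None:
            validate_dna(self.dr_sequence, "dr_sequence")
        lo, hi = self.spacer_len_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid spacer_len_range {self.spacer_len_range}")
        if not self.timepoints:
            raise ValueError("at least one timepoint is required")
        if self.n_host_spacers < 0 or self.n_viruses < 0:
            raise ValueError("counts must be non-negative")

    def resolve_weights(self) -> dict[str, float]:
        """Initial per-replicon abundance weights (timepoint 0)."""
        if self.per_sample_abundance is not None:
            return dict(self.per_sample_abundance)
        weights = {"host": self.host_weight}
        vw = list(self.virus_weights)
        while len(vw) < self.n_viruses:
            vw.append(vw[-1] / 2 if vw else 1.0)
        for i in range(self.n_viruses):
            weights[f"virus_{i + 1:02d}"] = vw[i]
        for i in range(self.n_background_genomes):
            weights[f"background_{i + 1:02d}"] = self.background_weight
        return weights


@dataclass
class Replicon:
    id: str
    sequence: str  # emitted (assembly-convention) sequence
    circular: bool = False
    core_length: int = 0  # length of the underlying circle; == len for linear

    def __post_init__(self) -> None:
        if self.core_length == 0:
            self.core_length = len(self.sequence)


@dataclass
class ProtospacerTruth:
    virus_id: str
    spacer_id: str
    start: int
    end: int
    strand: str
    n_mutations: int
    source_seq: str
    planted_seq: str


@dataclass
class _HostModel:
    """Host genome as flanks + evolving repeat-spacer array."""

    dr: str
    left_flank: str
    right_flank: str
    spacers: list[tuple[str, str]]  # (spacer_id, sequence), leader end first

    def array(self) -> str:
        parts = [self.dr]
        for _, seq in self.spacers:
            parts.append(seq)
            parts.append(self.dr)
        return "".join(parts)

    def genome(self) -> tuple[str, int, int]:
        arr = self.array()
        start = len(self.left_flank)
        return self.left_flank + arr + self.right_flank, start, start + len(arr)


def generate_host(
    config: CommunityConfig, rng: np.random.Generator | None = None
) -> tuple[Replicon, dict]:
    """Host genome with one CRISPR array; returns (replicon, truth fragment)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = _build_host_model(config, rng)
    genome, a, b = model.genome()
    truth = {
        "dr": model.dr,
        "locus_start": a,
        "locus_end": b,
        "spacers": [{"id": sid, "seq": seq} for sid, seq in model.spacers],
    }
    return Replicon("host", genome), truth


def _build_host_model(config: CommunityConfig, rng: np.random.Generator) -> _HostModel:
    dr = config.dr_sequence or random_dna(rng, config.dr_length)
    validate_dna(dr, "dr_sequence")
    lo, hi = config.spacer_len_range
    spacers = [
        (f"sp_t0_{i + 1:04d}", random_dna(rng, int(rng.integers(lo, hi + 1))))
        for i in range(config.n_host_spacers)
    ]
    array_len = len(dr) * (len(spacers) + 1) + sum(len(s) for _, s in spacers)
    flank_total = config.host_length - array_len
    if flank_total < 2:
        raise ValueError(
            f"host_length {config.host_length} too short for CRISPR array of {array_len} bp"
        )
    left = random_dna(rng, flank_total // 2)
    right = random_dna(rng, flank_total - flank_total // 2)
    return _HostModel(dr, left, right, spacers)


def _place_nonoverlapping(
    rng: np.random.Generator, occupied: list[tuple[int, int]], seg_len: int, region: int
) -> int:
    """Random start for a segment of seg_len in [0, region) avoiding occupied."""
    if region < seg_len:
        raise ValueError("replicon too short for requested insert")
    for _ in range(2000):
        start = int(rng.integers(0, region - seg_len + 1))
        if all(start + seg_len <= a or start >= b for a, b in occupied):
            occupied.append((start, start + seg_len))
            return start
    raise ValueError("could not place insert without overlap")


def generate_viruses(
    config: CommunityConfig,
    host_truth: dict,
    rng: np.random.Generator | None = None,
) -> tuple[list[Replicon], list[ProtospacerTruth], list[dict]]:
    """Viral genomes with planted protospacers and optional mini-CRISPR arrays."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    spacers = [(d["id"], d["seq"]) for d in host_truth["spacers"]]
    if config.protospacers_per_virus > 0 and not spacers:
        raise ValueError("protospacers requested but the host has no spacers")
    n = config.n_viruses
    n_circular = int(round(config.circular_fraction * n))
    circular_ids = set(rng.choice(n, size=n_circular, replace=False).tolist()) if n else set()

    replicons: list[Replicon] = []
    proto_truth: list[ProtospacerTruth] = []
    mini_truth: list[dict] = []
    for vi in range(n):
        vid = f"virus_{vi + 1:02d}"
        lo, hi = config.virus_len_range
        length = int(rng.integers(lo, hi + 1))
        circular = vi in circular_ids
        # keep inserts clear of the duplicated terminus of circular genomes
        region = length - (config.terminal_repeat_len if circular else 0)
        need = config.protospacers_per_virus * (max(config.spacer_len_range) + 10)
        if region < need:
            raise ValueError(
                f"{vid}: length {length} too short for "
                f"{config.protospacers_per_virus} protospacers"
            )
        genome = list(random_dna(rng, length))
        occupied: list[tuple[int, int]] = []
        if vi < config.mini_crispr_viruses:
            repeat = random_dna(rng, 29)
            mini_spacer = random_dna(rng, 33)
            unit = repeat + mini_spacer + repeat
            start = _place_nonoverlapping(rng, occupied, len(unit), region)
            genome[start : start + len(unit)] = unit
            mini_truth.append(
                {"virus_id": vid, "start": start, "repeat": repeat, "n_spacers": 1}
            )
        for _ in range(config.protospacers_per_virus):
            sid, src = spacers[int(rng.integers(0, len(spacers)))]
            planted, n_mut = mutate(src, config.protospacer_mutation_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = planted if strand == "+" else revcomp(planted)
            start = _place_nonoverlapping(rng, occupied, len(inserted), region)
            genome[start : start + len(inserted)] = inserted
            proto_truth.append(
                ProtospacerTruth(
                    vid, sid, start, start + len(inserted), strand, n_mut, src, planted
                )
            )
        core = "".join(genome)
        if circular:
            emitted = core + core[: config.terminal_repeat_len]
        else:
            emitted = core
        replicons.append(Replicon(vid, emitted, circular, len(core)))
    return replicons, proto_truth, mini_truth


def generate_backgrounds(
    config: CommunityConfig, rng: np.random.Generator | None = None
) -> list[Replicon]:
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    out = []
    lo, hi = config.background_len_range
    for i in range(config.n_background_genomes):
        out.append(
            Replicon(f"background_{i + 1:02d}", random_dna(rng, int(rng.integers(lo, hi + 1))))
        )
    return out


def simulate_reads(
    replicons: list[Replicon],
    weights: dict[str, float],
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator | int,
    sample_id: str = "s",
    chunk: int = 20_000,
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Shotgun reads drawn proportionally to weight x length, uniform error.

    Reads from circular replicons wrap around the underlying circle;
    linear replicons shorter than the read length contribute no reads
    (with a warning). Returns (records, per-replicon read counts); each
    record is (id, sequence, quality) with the source replicon carried in
    the FASTQ description, not in the id.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    w = np.array([max(0.0, float(weights.get(r.id, 0.0))) for r in replicons])
    if (w < 0).any() or not (w > 0).any():
        raise ValueError("weights must be non-negative and not all zero")
    eff_len = np.array(
        [r.core_length if r.circular else len(r.sequence) for r in replicons], dtype=float
    )
    for i, r in enumerate(replicons):
        if not r.circular and len(r.sequence) < read_length and w[i] > 0:
            warnings.warn(
                f"replicon {r.id} shorter than read length; contributes no reads"
            )
            w[i] = 0.0
    if not (w > 0).any():
        raise ValueError("no replicon long enough to draw reads from")
    p = w * eff_len
    p = p / p.sum()
    counts = rng.multinomial(n_reads, p)

    records: list[tuple[str, str, str]] = []
    qual = "I" * read_length
    idx_offsets = np.arange(read_length)
    read_no = 0
    for r, c in zip(replicons, counts):
        if c == 0:
            continue
        core = r.sequence[: r.core_length] if r.circular else r.sequence
        codes = _CODE[np.frombuffer(core.encode(), dtype=np.uint8)]
        clen = len(codes)
        done = 0
        while done < c:
            b = int(min(chunk, c - done))
            if r.circular:
                starts = rng.integers(0, clen, size=b)
                mat = codes[(starts[:, None] + idx_offsets) % clen]
            else:
                starts = rng.integers(0, clen - read_length + 1, size=b)
                mat = codes[starts[:, None] + idx_offsets]
            rc = rng.random(b) < 0.5
            mat[rc] = (3 - mat[rc])[:, ::-1]
            if error_rate > 0:
                err = rng.random((b, read_length)) < error_rate
                shift = rng.integers(1, 4, size=(b, read_length))
                mat = np.where(err, (mat + shift) % 4, mat)
            ascii_mat = _ASCII[mat]
            for row in ascii_mat:
                records.append(
                    (
                        f"{sample_id}.r{read_no:07d} source={r.id}",
                        row.tobytes().decode("ascii"),
                        qual,
                    )
                )
                read_no += 1
            done += b
    return records, {r.id: int(c) for r, c in zip(replicons, counts)}


@dataclass
class SampleData:
    sample_id: str
    reads: list[tuple[str, str, str]]
    weights: dict[str, float]
    truth: dict


@dataclass
class SyntheticCommunity:
    config: CommunityConfig
    dr: str
    viruses: list[Replicon]
    backgrounds: list[Replicon]
    protospacers: list[ProtospacerTruth]
    mini_arrays: list[dict]
    host_genomes: dict[str, Replicon]  # per timepoint label
    samples: list[SampleData]

    @property
    def reference_replicons(self) -> list[Replicon]:
        """Mapping references: timepoint-0 host first, then viruses, then backgrounds."""
        first = self.samples[0].sample_id
        return [self.host_genomes[first]] + self.viruses + self.backgrounds

    @property
    def scaffolds(self) -> list[Replicon]:
        """Candidate scaffolds for classification (everything but the host)."""
        return self.viruses + self.backgrounds


def simulate_timeseries(config: CommunityConfig) -> SyntheticCommunity:
    """Full multi-timepoint simulation with per-timepoint ground truth."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.timepoints))
    rng = np.random.default_rng(children[0])

    host_model = _build_host_model(config, rng)
    host_truth = {
        "dr": host_model.dr,
        "spacers": [{"id": sid, "seq": s} for sid, s in host_model.spacers],
    }
    viruses, proto_truth, mini_truth = generate_viruses(config, host_truth, rng)
    backgrounds = generate_backgrounds(config, rng)

    weights = config.resolve_weights()
    lo, hi = config.spacer_len_range
    samples: list[SampleData] = []
    host_genomes: dict[str, Replicon] = {}
    for ti, tp in enumerate(config.timepoints):
        if ti > 0:
            if tp.n_lost_spacers > len(host_model.spacers):
                raise ValueError(
                    f"{tp.label}: cannot lose {tp.n_lost_spacers} of "
                    f"{len(host_model.spacers)} spacers"
                )
            if tp.n_lost_spacers:
                drop = set(
                    rng.choice(
                        len(host_model.spacers), size=tp.n_lost_spacers, replace=False
                    ).tolist()
                )
                host_model.spacers = [
                    s for k, s in enumerate(host_model.spacers) if k not in drop
                ]
            new: list[tuple[str, str]] = []
            for k in range(tp.n_new_spacers):
                length = int(rng.integers(lo, hi + 1))
                sid = f"sp_{tp.label}_{k + 1:04d}"
                if viruses and rng.random() < config.acquisition_from_virus_fraction:
                    v = viruses[int(rng.integers(0, len(viruses)))]
                    start = int(rng.integers(0, v.core_length - length + 1))
                    seq = v.sequence[start : start + length]
                    if rng.random() < 0.5:
                        seq = revcomp(seq)
                else:
                    seq = random_dna(rng, length)
                new.append((sid, seq))
            # leader-polarized acquisition: new units enter at the array start
            host_model.spacers = new + host_model.spacers
            for vid in [v.id for v in viruses]:
                weights[vid] = weights[vid] * tp.virus_weight_scale
            weights.update(tp.abundance_overrides)

        genome, a, b = host_model.genome()
        host = Replicon("host", genome)
        host_genomes[tp.label] = host
        replicons = [host] + viruses + backgrounds
        read_rng = np.random.default_rng(children[1 + ti])
        records, counts = simulate_reads(
            replicons,
            weights,
            config.n_reads,
            config.read_length,
            config.read_error_rate,
            read_rng,
            sample_id=tp.label,
        )
        truth = {
            "sample_id": tp.label,
            "dr": host_model.dr,
            "host_locus": [a, b],
            "spacers": [{"id": sid, "seq": s} for sid, s in host_model.spacers],
            "weights": dict(weights),
            "read_counts": counts,
            "expected_coverage": {
                r.id: counts[r.id] * config.read_length / len(r.sequence)
                for r in replicons
            },
            "protospacers": [asdict(p) for p in proto_truth],
            "mini_crispr": mini_truth,
        }
        samples.append(SampleData(tp.label, records, dict(weights), truth))
    return SyntheticCommunity(
        config,
        host_model.dr,
        viruses,
        backgrounds,
        proto_truth,
        mini_truth,
        host_genomes,
        samples,
    )


def annotation_table(community: SyntheticCommunity):
    """Synthetic gene-annotation table mirroring external database evidence.

    Circular viruses carry hallmark genes and VOG hits (the profile of
    genomes the classifier may call 'virus'); linear viruses carry no
    annotation and can only become putative viruses; background genomes
    carry bacterial database hits.
    """
    import pandas as pd

    rows = []
    gene_no = 0
    for v in community.viruses:
        if v.circular:
            for _ in range(2):
                gene_no += 1
                rows.append((f"g{gene_no:04d}", v.id, 1, 1, 0))
    for b in community.backgrounds:
        for _ in range(5):
            gene_no += 1
            rows.append((f"g{gene_no:04d}", b.id, 0, 0, 1))
    return pd.DataFrame(
        rows, columns=["gene_id", "scaffold_id", "is_hallmark", "is_vog_hit", "is_bacterial"]
    )


def write_community(community: SyntheticCommunity, outdir: str | Path) -> None:
    """Write FASTQ/FASTA/JSON artifacts: <sample>.reads.fastq, <sample>.truth.json."""
    from .io import write_fasta, write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in community.samples:
        write_fastq(outdir / f"{s.sample_id}.reads.fastq", s.reads)
        with open(outdir / f"{s.sample_id}.truth.json", "w") as fh:
            json.dump(s.truth, fh, indent=1)
    write_fasta(
        outdir / "references.fasta",
        [(r.id, r.sequence) for r in community.reference_replicons],
    )
    write_fasta(
        outdir / "scaffolds.fasta", [(r.id, r.sequence) for r in community.scaffolds]
    )
    with open(outdir / "dr.txt", "w") as fh:
        fh.write(community.dr + "\n")
    annotation_table(community).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False
    )
    import yaml

    cfg = json.loads(json.dumps(asdict(community.config)))  # tuples -> lists
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
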