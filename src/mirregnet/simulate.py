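"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates every data source the pipeline consumes — genome
and annotations, TSS-tag/ChIP-seq coverage, core-promoter motif sites,
expression matrices, PWMs and promoters, miRNA-target interactions,
gene-gene interaction edges and GO annotations — with known planted
structure, so training, scanning, enrichment and network assembly are
all testable without any download.

Planted structure:

* each miRNA precursor has one true TSS in its 10-kb upstream region;
  coverage tracks carry Gaussian enrichment (TSS tags, H3K4me3, H3K9ac)
  or depletion (nucleosome H3) there, with Poisson counting noise, and
  core motifs cluster near TSSs;
* a subset of precursors is intragenic: embedded on the same strand of
  a host gene whose TSS is the miRNA's true TSS;
* each of the first miRNAs owns a coexpressed gene block sharing its
  latent condition profile, and one planted TF whose consensus site is
  inserted in most of the group's promoters;
* planted miRNA-target interactions give targets the negated miRNA
  profile; targets root guaranteed chains in a random gene graph; and
  one GO term annotates most of the miRNA-mediated gene set.

Everything is deterministic for a fixed seed; per-stage generators are
spawned from (seed, stage-index) pairs so stages stay independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomic
from .genomic import (GenomicInterval, MotifAnnotation, PreMiRNA, SignalTrack,
                      MOTIF_CLASSES)
from .network import MTI, GeneGraph
from .tfbs import PWM, write_jaspar
from .tss import TssRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedData",
    "simulate_genome_and_annotations",
    "simulate_signal_tracks",
    "simulate_expression",
    "simulate_regulatory_layer",
    "simulate_all",
    "write_all",
]

_BASES = np.array(list("ACGT"))


@dataclass
class TrackShape:
    """Gaussian bump (or dip) parameters for one coverage track."""

    height: float
    sd: float
    background: float


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are sized for desk-scale runs: 2 chromosomes of 300 kb,
    20 miRNAs, 500 expression-profiled genes, 11 conditions.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_mirnas: int = 20
    intragenic_fraction: float = 0.15
    mirna_tile: int = 22_000          # genome allotted per precursor
    precursor_length: int = 120
    tss_min_distance: int = 500       # true TSS offset range upstream
    tss_max_distance: int = 9_500
    gene_spacing: int = 4_000         # protein-coding genes in the gene zone
    gene_length: int = 1_500
    n_multi_tss_genes: int = 3        # genes given a second recorded TSS
    n_genes: int = 500                # expression-profiled gene pool
    n_conditions: int = 11

    track_shapes: dict = field(default_factory=lambda: {
        "tss_tags": TrackShape(height=40.0, sd=25.0, background=0.05),
        "h3k4me3": TrackShape(height=25.0, sd=150.0, background=0.5),
        "h3k9ac": TrackShape(height=25.0, sd=150.0, background=0.5),
    })
    h3_baseline: float = 8.0
    h3_depletion: float = 6.0
    h3_sd: float = 150.0
    poisson_noise: bool = True
    motif_near_rate: float = 2.0      # expected sites per class within +/-100
    motif_near_span: int = 100
    motif_background_rate: float = 1 / 3000.0   # per base per class
    motif_length: int = 6

    coexpr_block_size: int = 20
    coexpr_noise_sd: float = 0.1
    mti_noise_sd: float = 0.05

    n_tf_pairs: int = 3
    n_decoy_pwms: int = 3
    pwm_length: int = 10
    pwm_dominance: float = 0.91
    plant_fraction: float = 0.8       # of a group's promoters get the site
    cross_group_rate: float = 0.1
    decoy_rate: float = 0.3
    promoter_length: int = 1_000

    n_mti_mirnas: int = 3
    targets_per_mirna: int = 4
    n_extra_graph_genes: int = 30
    graph_density: float = 0.05
    chain_length: int = 3             # guaranteed indirect chain per target
    go_planted_share: float = 0.9
    go_term: str = "GO:9999999"
    n_background_go_terms: int = 20
    go_background_rate: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length, self.n_mirnas,
               self.n_genes, self.n_conditions) <= 0:
            raise ValueError("counts must be positive")
        if self.coexpr_noise_sd < 0 or self.mti_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for p in (self.intragenic_fraction, self.plant_fraction,
                  self.cross_group_rate, self.decoy_rate,
                  self.go_planted_share, self.go_background_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for test assertions."""

    true_tss: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    host_gene: dict[str, str] = field(default_factory=dict)
    tf_pairs: dict[str, str] = field(default_factory=dict)   # miRNA -> PWM id
    mtis: list[tuple[str, str]] = field(default_factory=list)
    blocks: dict[str, list[str]] = field(default_factory=dict)
    chains: dict[str, list[str]] = field(default_factory=dict)
    go_term: str = ""
    go_term_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["true_tss"] = {k: tuple(v) for k, v in d["true_tss"].items()}
        d["mtis"] = [tuple(m) for m in d["mtis"]]
        return cls(**d)


@dataclass
class SimulatedData:
    """In-memory bundle of every simulated input."""

    config: SimulationConfig
    truth: GroundTruth
    genome: dict[str, str]
    mirnas: list[PreMiRNA]
    genes: list[tuple[str, GenomicInterval]]
    tss_records: list[TssRecord]
    tracks: dict[str, SignalTrack]
    motifs: dict[str, MotifAnnotation]
    mirna_expr: pd.DataFrame
    gene_expr: pd.DataFrame
    pwms: list[PWM]
    group_promoters: dict[str, dict[str, str]]
    mtis: list[MTI]
    gene_graph: GeneGraph
    go_annotations: dict[str, set[str]]

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.genome.items()}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, config.n_genes + 1)]


def simulate_genome_and_annotations(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[PreMiRNA],
           list[tuple[str, GenomicInterval]], list[TssRecord], GroundTruth]:
    """Uniform-background genome with precursor and gene annotations.

    Each chromosome holds a run of non-overlapping precursor tiles
    (one true TSS planted in the 10-kb upstream region of each) followed
    by a gene zone of regularly spaced protein-coding genes whose TSSs
    train the classifier. Precursor loci are at least
    ``mirna_tile - tss_max_distance`` > 12 kb apart within the tile run.
    """
    rng = _rng(config, 1)
    n_chrom = config.n_chromosomes
    per_chr = [config.n_mirnas // n_chrom + (1 if c < config.n_mirnas % n_chrom
                                             else 0)
               for c in range(n_chrom)]
    for c, k in enumerate(per_chr):
        need = k * config.mirna_tile + 2 * config.gene_spacing
        if need > config.chromosome_length:
            raise ValueError(
                f"cannot fit {k} precursor tiles of {config.mirna_tile} bp "
                f"on a {config.chromosome_length} bp chromosome; use longer "
                "chromosomes or fewer miRNAs")

    genome: dict[str, str] = {}
    mirnas: list[PreMiRNA] = []
    genes: list[tuple[str, GenomicInterval]] = []
    tss_records: list[TssRecord] = []
    truth = GroundTruth()

    n_intra = int(np.floor(config.intragenic_fraction * config.n_mirnas
                           + 0.5))
    intragenic_idx = set(
        rng.choice(config.n_mirnas, size=n_intra, replace=False).tolist())

    gene_pool = iter(_gene_ids(config))
    mi = 0
    for c in range(n_chrom):
        seqid = f"Chr{c + 1}"
        L = config.chromosome_length
        genome[seqid] = "".join(_BASES[rng.integers(0, 4, size=L)])
        # precursor tiles
        for j in range(per_chr[c]):
            tile = j * config.mirna_tile
            p_start = tile + 11_000
            p_end = p_start + config.precursor_length
            strand = "+" if mi % 2 == 0 else "-"
            mirna_id = f"ath-MIRsim{mi + 1:03d}"
            d = int(rng.integers(config.tss_min_distance,
                                 config.tss_max_distance))
            if strand == "+":
                tss = p_start - d
            else:
                tss = p_end - 1 + d
            if mi in intragenic_idx:
                host_id = next(gene_pool)
                h_start = max(0, p_start - 2_000)
                h_end = min(L, p_end + 2_000)
                host = GenomicInterval(seqid, h_start, h_end, strand)
                genes.append((host_id, host))
                tss = host.five_prime
                tss_records.append(TssRecord(host_id, seqid, tss, strand))
                mirnas.append(PreMiRNA(
                    mirna_id, GenomicInterval(seqid, p_start, p_end, strand),
                    intragenic=True, host_gene=host_id))
                truth.host_gene[mirna_id] = host_id
            else:
                mirnas.append(PreMiRNA(
                    mirna_id, GenomicInterval(seqid, p_start, p_end, strand)))
            truth.true_tss[mirna_id] = (seqid, int(tss), strand)
            mi += 1
        # gene zone
        zone_start = per_chr[c] * config.mirna_tile + config.gene_spacing // 2
        pos = zone_start
        gi = 0
        while pos + config.gene_length < L:
            gid = next(gene_pool, None)
            if gid is None:
                break
            strand = "+" if gi % 2 == 0 else "-"
            iv = GenomicInterval(seqid, pos, pos + config.gene_length, strand)
            genes.append((gid, iv))
            tss_records.append(TssRecord(gid, seqid, iv.five_prime, strand))
            pos += config.gene_spacing
            gi += 1

    # a few genes get a second recorded TSS (they must not train the model)
    multi = [r for r in tss_records
             if r.gene_id not in truth.host_gene.values()]
    for r in multi[: config.n_multi_tss_genes]:
        tss_records.append(TssRecord(r.gene_id, r.seqid,
                                     r.position + 300, r.strand))
    return genome, mirnas, genes, tss_records, truth


def _gaussian_bump(length: int, center: int, height: float,
                   sd: float) -> tuple[slice, np.ndarray]:
    half = int(4 * sd)
    lo, hi = max(0, center - half), min(length, center + half + 1)
    x = np.arange(lo, hi)
    return slice(lo, hi), height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_signal_tracks(
    config: SimulationConfig, truth: GroundTruth,
    tss_records: list[TssRecord], genome_lengths: dict[str, int],
) -> tuple[dict[str, SignalTrack], dict[str, MotifAnnotation]]:
    """Coverage tracks and motif sites with planted TSS-centred structure.

    TSS tags / H3K4me3 / H3K9ac get a Gaussian bump at every true TSS
    (gene and miRNA); nucleosome H3 gets a baseline with a Gaussian dip,
    floored at zero. Poisson sampling on top models read-count noise.
    Motif sites of each class appear at an elevated rate within
    +/- ``motif_near_span`` bp of TSSs and at a background rate
    elsewhere.
    """
    rng = _rng(config, 2)
    anchors: dict[str, list[int]] = {sid: [] for sid in genome_lengths}
    seen = set()
    for r in tss_records:
        if (r.seqid, r.position) not in seen:
            seen.add((r.seqid, r.position))
            anchors[r.seqid].append(r.position)
    for sid, pos, _ in truth.true_tss.values():
        if (sid, pos) not in seen:
            seen.add((sid, pos))
            anchors[sid].append(pos)

    tracks: dict[str, SignalTrack] = {}
    for name, shape in config.track_shapes.items():
        values = {}
        for sid, L in sorted(genome_lengths.items()):
            lam = np.full(L, shape.background)
            for tss in anchors[sid]:
                sl, bump = _gaussian_bump(L, tss, shape.height, shape.sd)
                lam[sl] += bump
            values[sid] = (rng.poisson(lam).astype(float)
                           if config.poisson_noise else lam)
        tracks[name] = SignalTrack(name, values)

    values = {}
    for sid, L in sorted(genome_lengths.items()):
        lam = np.full(L, config.h3_baseline)
        for tss in anchors[sid]:
            sl, dip = _gaussian_bump(L, tss, config.h3_depletion, config.h3_sd)
            lam[sl] -= dip
        lam = np.maximum(lam, 0.0)
        values[sid] = (rng.poisson(lam).astype(float)
                       if config.poisson_noise else lam)
    tracks["h3"] = SignalTrack("h3", values)

    motifs: dict[str, MotifAnnotation] = {}
    for mclass in MOTIF_CLASSES:
        sites = []
        for sid, L in sorted(genome_lengths.items()):
            for tss in anchors[sid]:
                for _ in range(rng.poisson(config.motif_near_rate)):
                    s = int(rng.integers(tss - config.motif_near_span,
                                         tss + config.motif_near_span))
                    s = int(np.clip(s, 0, L - config.motif_length - 1))
                    sites.append(GenomicInterval(
                        sid, s, s + config.motif_length))
            n_bg = rng.poisson(L * config.motif_background_rate)
            for s in sorted(rng.integers(0, L - config.motif_length,
                                         size=n_bg).tolist()):
                sites.append(GenomicInterval(sid, s, s + config.motif_length))
        motifs[mclass] = MotifAnnotation(mclass, sites)
    return tracks, motifs


def _allocate_gene_sets(config: SimulationConfig,
                        genes: list[tuple[str, GenomicInterval]]
                        ) -> tuple[list[str], dict[str, list[str]],
                                   dict[str, list[str]], list[str]]:
    """Split the gene-id pool into genomic, block, target and free genes."""
    all_ids = _gene_ids(config)
    genomic_ids = {g for g, _ in genes}
    free = [g for g in all_ids if g not in genomic_ids]
    mirna_ids = [f"ath-MIRsim{i + 1:03d}" for i in range(config.n_mirnas)]
    blocks: dict[str, list[str]] = {}
    it = iter(free)
    for m in mirna_ids[: config.n_tf_pairs]:
        blocks[m] = [next(it) for _ in range(config.coexpr_block_size)]
    targets: dict[str, list[str]] = {}
    for m in mirna_ids[: config.n_mti_mirnas]:
        targets[m] = [next(it) for _ in range(config.targets_per_mirna)]
    rest = list(it)
    return mirna_ids, blocks, targets, rest


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth,
    blocks: dict[str, list[str]], targets: dict[str, list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrices with planted coexpression and repression.

    Each miRNA's profile is a latent standard-normal condition vector.
    Block genes share the latent profile plus N(0, coexpr_noise_sd);
    planted targets get the negated profile plus N(0, mti_noise_sd);
    every other gene is independent noise.
    """
    if config.n_conditions < 5:
        raise ValueError("need at least 5 conditions")
    rng = _rng(config, 3)
    conditions = [f"stage_{i + 1:02d}" for i in range(config.n_conditions)]
    mirna_ids = [f"ath-MIRsim{i + 1:03d}" for i in range(config.n_mirnas)]
    latent = {m: rng.normal(0.0, 1.0, config.n_conditions)
              for m in mirna_ids}
    mirna_expr = pd.DataFrame(
        np.vstack([latent[m] for m in mirna_ids]),
        index=mirna_ids, columns=conditions)

    rows: dict[str, np.ndarray] = {}
    for m, genes_ in blocks.items():
        for g in genes_:
            rows[g] = latent[m] + rng.normal(
                0.0, config.coexpr_noise_sd, config.n_conditions)
        truth.blocks[m] = list(genes_)
    for m, genes_ in targets.items():
        for g in genes_:
            rows[g] = -latent[m] + rng.normal(
                0.0, config.mti_noise_sd, config.n_conditions)
    for g in _gene_ids(config):
        if g not in rows:
            rows[g] = rng.normal(0.0, 1.0, config.n_conditions)
    all_ids = _gene_ids(config)
    gene_expr = pd.DataFrame(np.vstack([rows[g] for g in all_ids]),
                             index=all_ids, columns=conditions)
    return mirna_expr, gene_expr


def _random_pwm(rng: np.random.Generator, pwm_id: str,
                length: int, dominance: float) -> PWM:
    rest = (1.0 - dominance) / 3.0
    mat = np.full((length, 4), rest)
    for i, b in enumerate(rng.integers(0, 4, size=length)):
        mat[i, b] = dominance
    return PWM(pwm_id, mat)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_regulatory_layer(
    config: SimulationConfig, truth: GroundTruth,
    blocks: dict[str, list[str]], targets: dict[str, list[str]],
    free_genes: list[str],
) -> tuple[list[PWM], dict[str, dict[str, str]], list[MTI], GeneGraph,
           dict[str, set[str]]]:
    """PWMs, group promoters, MTIs, gene graph and GO annotations.

    Each planted TF's consensus is inserted into ``plant_fraction`` of
    its group's promoters (and into other groups at the low
    cross-group rate); decoy PWMs are inserted uniformly at the decoy
    rate, common enough to be seen but spread evenly so they carry no
    group-specific signal. The gene graph is an Erdos-Renyi digraph
    plus one guaranteed chain per direct target; one GO term annotates
    most of the miRNA-mediated gene set.
    """
    rng = _rng(config, 4)
    if config.pwm_length > config.promoter_length:
        raise ValueError("PWM consensus longer than the promoter")

    planted = [_random_pwm(rng, f"TF{t + 1}", config.pwm_length,
                           config.pwm_dominance)
               for t in range(config.n_tf_pairs)]
    decoys = [_random_pwm(rng, f"DEC{t + 1}", config.pwm_length,
                          config.pwm_dominance)
              for t in range(config.n_decoy_pwms)]
    pwms = planted + decoys

    group_promoters: dict[str, dict[str, str]] = {}
    group_ids = list(blocks)
    for gi, m in enumerate(group_ids):
        members = [m] + blocks[m]       # the miRNA's own promoter included
        proms = {pid: _random_seq(rng, config.promoter_length)
                 for pid in members}

        def insert(pid: str, consensus: str) -> None:
            off = int(rng.integers(
                0, config.promoter_length - len(consensus)))
            s = proms[pid]
            proms[pid] = s[:off] + consensus + s[off + len(consensus):]

        own = planted[gi]
        truth.tf_pairs[m] = own.id
        n_plant = int(np.ceil(config.plant_fraction * len(members)))
        chosen = rng.choice(members, size=n_plant, replace=False)
        for pid in chosen:
            insert(pid, own.consensus)
        for other_gi, other in enumerate(planted):
            if other_gi == gi:
                continue
            for pid in members:
                if rng.random() < config.cross_group_rate:
                    insert(pid, other.consensus)
        for dec in decoys:
            for pid in members:
                if rng.random() < config.decoy_rate:
                    insert(pid, dec.consensus)
        group_promoters[m] = proms

    mtis: list[MTI] = []
    for m, tg in targets.items():
        for i, g in enumerate(tg):
            evidence = "verified" if i < 2 else "putative"
            mtis.append(MTI(m, g, evidence, "simulated"))
            truth.mtis.append((m, g))

    direct = sorted({g for tg in targets.values() for g in tg})
    extra = free_genes[: config.n_extra_graph_genes]
    chain_pool = iter(free_genes[config.n_extra_graph_genes:])
    edges: list[tuple[str, str]] = []
    for d in direct:
        chain = [d]
        for _ in range(config.chain_length):
            nxt = next(chain_pool, None)
            if nxt is None:
                raise ValueError("gene pool exhausted while planting chains")
            edges.append((chain[-1], nxt))
            chain.append(nxt)
        truth.chains[d] = chain[1:]
    nodes = sorted(set(direct) | set(extra))
    for u in nodes:
        for v in nodes:
            if rng.random() < config.graph_density:
                edges.append((u, v))
    graph = GeneGraph(edges, nodes=nodes)

    # mediated gene set of the first MTI miRNA: direct targets + reachable
    focal = list(targets)[0]
    mediated = set(targets[focal])
    frontier = list(targets[focal])
    while frontier:
        node = frontier.pop()
        for child in graph.adj.get(node, ()):
            if child not in mediated:
                mediated.add(child)
                frontier.append(child)
    mediated = sorted(mediated)
    n_annot = int(np.ceil(config.go_planted_share * len(mediated)))
    planted_genes = sorted(rng.choice(mediated, size=n_annot,
                                      replace=False).tolist())
    annotations: dict[str, set[str]] = {g: {config.go_term}
                                        for g in planted_genes}
    truth.go_term = config.go_term
    truth.go_term_genes = planted_genes
    bg_terms = [f"GO:{i + 1:07d}" for i in range(config.n_background_go_terms)]
    for g in _gene_ids(config):
        for t in bg_terms:
            if rng.random() < config.go_background_rate:
                annotations.setdefault(g, set()).add(t)
    return pwms, group_promoters, mtis, graph, annotations


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every generator stage and bundle the results."""
    genome, mirnas, genes, tss_records, truth = \
        simulate_genome_and_annotations(config)
    genome_lengths = {k: len(v) for k, v in genome.items()}
    tracks, motifs = simulate_signal_tracks(config, truth, tss_records,
                                            genome_lengths)
    _, blocks, targets, free = _allocate_gene_sets(config, genes)
    mirna_expr, gene_expr = simulate_expression(config, truth, blocks,
                                                targets)
    pwms, group_promoters, mtis, graph, annotations = \
        simulate_regulatory_layer(config, truth, blocks, targets, free)
    return SimulatedData(config, truth, genome, mirnas, genes, tss_records,
                         tracks, motifs, mirna_expr, gene_expr, pwms,
                         group_promoters, mtis, graph, annotations)


def write_all(config: SimulationConfig, outdir) -> SimulatedData:
    """Emit every simulated input as files in ``outdir``.

    Formats match what the pipeline reads: FASTA, GFF3, BED, bedGraph,
    TSV and JASPAR matrices, plus the ground truth as JSON and the
    configuration as YAML. Output is byte-identical across runs with
    the same config.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_all(config)

    genomic.write_fasta(data.genome, out / "genome.fa")
    with open(out / "annotations.gff3", "wt") as fh:
        fh.write("##gff-version 3\n")
        for gid, iv in data.genes:
            fh.write(f"{iv.seqid}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\tID={gid}\n")
        for m in data.mirnas:
            iv = m.locus
            attrs = f"ID={m.id}"
            if m.intragenic:
                attrs += f";host_gene={m.host_gene}"
            fh.write(f"{iv.seqid}\tsim\tmiRNA_primary_transcript\t"
                     f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n")
    with open(out / "tss.bed", "wt") as fh:
        for r in data.tss_records:
            fh.write(f"{r.seqid}\t{r.position}\t{r.position + 1}\t"
                     f"{r.gene_id}\t0\t{r.strand}\n")
    for name, track in data.tracks.items():
        genomic.write_bedgraph(track, out / f"{name}.bedgraph")
    for mclass, ann in data.motifs.items():
        genomic.write_bed(ann.sites, out / f"motif_{mclass}.bed")
    data.mirna_expr.to_csv(out / "mirna_expression.tsv", sep="\t")
    data.gene_expr.to_csv(out / "gene_expression.tsv", sep="\t")
    write_jaspar(data.pwms, out / "pwms.jaspar")
    with open(out / "promoters.fa", "wt") as fh:
        for gid in sorted(data.group_promoters):
            for pid, seq in data.group_promoters[gid].items():
                fh.write(f">{gid}|{pid}\n{seq}\n")
    with open(out / "mti.tsv", "wt") as fh:
        fh.write("mirna\ttarget\tevidence\tsource\n")
        for m in data.mtis:
            fh.write(f"{m.mirna}\t{m.target}\t{m.evidence}\t{m.source}\n")
    with open(out / "gene_edges.tsv", "wt") as fh:
        for u, v in data.gene_graph.edges:
            fh.write(f"{u}\t{v}\n")
    with open(out / "go_annotations.tsv", "wt") as fh:
        for g in sorted(data.go_annotations):
            for t in sorted(data.go_annotations[g]):
                fh.write(f"{g}\t{t}\n")
    data.truth.to_json(out / "ground_truth.json")
    cfg = dataclasses.asdict(config)
    with open(out / "config.yaml", "wt") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return data
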