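"""End-to-end orchestration of the three-layer patriline analysis.

Stages (in dependency order): ``simulate`` → ``haplotypes`` → ``cnv_call`` →
``ascnv_resolve`` → ``refine`` → ``diversity`` → ``network`` / ``upgma``.
Each stage is an ordinary function over the library types; :func:`run_all`
chains them from a single :class:`RunConfig` and writes deterministic,
provenance-stamped TSV/Newick/GML outputs into a run directory.  All
randomness flows from the one config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .ascnv import AlleleSplit, PyroMeasurement, resolve_split, pattern_census, write_splits_table
from .cnv import CopyNumberCall, QpcrMeasurement, call_copy_number, cn_summary, cnv_polymorphism
from .diversity import (
    FrequencySpectrum,
    count_segregating_sites,
    haplotype_diversity,
    nucleotide_diversity,
)
from .layers import LayeredDistanceSpec, layered_distance, refine
from .markers import Haplotype, Locus, SampleRecord, collapse_haplotypes, to_fasta
from .phylo import DistanceMatrix, export_network, hamming_matrix, mjn, mp_prune, upgma
from .simulate import SimConfig, SimResult, simulate

__all__ = ["RunConfig", "PipelineResult", "run_all", "provenance_header"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs: seed, output directory, parameters."""

    seed: int
    outdir: Path
    sim: dict = field(default_factory=dict)
    qc_threshold: float = 0.3
    split_tolerance: float = 0.02
    pi_sites: int | None = None  # default: panel length
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    epsilon: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw["outdir"] = Path(raw["outdir"])
        if "weights" in raw:
            raw["weights"] = tuple(raw["weights"])
        return cls(**raw)


def provenance_header(config: RunConfig, stage: str) -> list[str]:
    return [
        f"ylineage {__version__} stage={stage} seed={config.seed}",
        f"params qc_threshold={config.qc_threshold} "
        f"split_tolerance={config.split_tolerance} epsilon={config.epsilon} "
        f"weights={','.join(f'{w:g}' for w in config.weights)}",
    ]


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    sim: SimResult
    haplotypes: list[Haplotype]
    cn_calls: list[CopyNumberCall]
    splits: list[tuple[str, AlleleSplit]]
    profiles: list
    diversity_table: list[dict]
    census: dict[str, list[str]]
    cn_table: object
    newick_snp: str
    newick_layered: str
    paths: dict[str, Path]


def _stage_cnv(
    sim: SimResult, config: RunConfig
) -> list[CopyNumberCall]:
    ladder_of = {l.locus_id: l.cn_ladder for l in sim.panel if l.multi_copy}
    grouped: dict[tuple[str, str], dict[int, tuple[float, float]]] = {}
    for row in sim.qpcr_rows:
        grouped.setdefault((row["sample_id"], row["locus_id"]), {})[row["rep"]] = (
            row["ct_target"],
            row["ct_reference"],
        )
    calls = []
    for (sid, lid), reps in sorted(grouped.items()):
        m = QpcrMeasurement(
            sample_id=sid,
            locus_id=lid,
            ct_target=tuple(reps[r][0] for r in (1, 2, 3)),
            ct_reference=tuple(reps[r][1] for r in (1, 2, 3)),
        )
        calls.append(call_copy_number(m, ladder_of[lid], config.qc_threshold))
    n_retest = sum(1 for c in calls if c.qc_flag == "retest")
    logger.info("cnv_call: %d calls, %d flagged retest", len(calls), n_retest)
    return calls


def _stage_ascnv(
    sim: SimResult, cn_calls: Sequence[CopyNumberCall], config: RunConfig
) -> list[tuple[str, AlleleSplit]]:
    cn_of = {
        (c.sample_id, c.locus_id): c.cn_integer
        for c in cn_calls
        if c.qc_flag == "pass"
    }
    alleles_of = {l.locus_id: l.allele_set for l in sim.panel}
    out: list[tuple[str, AlleleSplit]] = []
    skipped = 0
    for row in sim.pyro_rows:
        total = cn_of.get((row["sample_id"], row["locus_id"]))
        if total is None or total < 2:
            skipped += 1  # retest CN blocks allele-split resolution
            continue
        out.append(
            (
                row["sample_id"],
                resolve_split(
                    total,
                    row["rbv"],
                    alleles=alleles_of[row["locus_id"]],
                    tolerance=config.split_tolerance,
                    locus_id=row["locus_id"],
                ),
            )
        )
    logger.info("ascnv_resolve: %d splits resolved, %d blocked by QC", len(out), skipped)
    return out


def _stage_diversity(
    records: Sequence[SampleRecord],
    haplotypes: Sequence[Haplotype],
    panel: Sequence[Locus],
    L: int,
) -> list[dict]:
    by_pop: dict[str, list[int]] = {}
    carriers = {h.name: h for h in haplotypes}
    pop_hap: dict[str, dict[str, int]] = {}
    rec_by_id = {r.sample_id: r for r in records}
    for h in haplotypes:
        for sid in h.carrier_ids:
            pop = rec_by_id[sid].population
            pop_hap.setdefault(pop, {}).setdefault(h.name, 0)
            pop_hap[pop][h.name] += 1
    rows = []
    for pop in sorted(pop_hap):
        counts = tuple(sorted(pop_hap[pop].values(), reverse=True))
        n = sum(counts)
        row = {"population": pop, "k": len(counts), "N": n,
               "haplotypes": ",".join(sorted(pop_hap[pop]))}
        if n >= 2:
            h, h_se = haplotype_diversity(FrequencySpectrum(counts))
            haps = [
                (carriers[name].call_vector, cnt)
                for name, cnt in sorted(pop_hap[pop].items())
            ]
            pi, pi_se = nucleotide_diversity(haps, L)
            row.update(h=h, h_se=h_se, pi=pi, pi_se=pi_se)
        rows.append(row)
    return rows


def run_all(config: RunConfig) -> PipelineResult:
    """Run every stage in dependency order; outputs land in ``config.outdir``.

    Identical configs (same seed) produce byte-identical result files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sim = simulate(SimConfig(seed=config.seed, **config.sim))
    paths.update(sim.write(outdir / "sim"))

    haplotypes = collapse_haplotypes(sim.records, sim.panel)
    paths["haplotypes_fasta"] = to_fasta(
        haplotypes, sim.panel, outdir / "haplotypes.fasta"
    )

    cn_calls = _stage_cnv(sim, config)
    groups = {r.sample_id: r.group for r in sim.records}
    cn_table = cn_summary(cn_calls, groups)
    paths["cn_summary"] = outdir / "cn_summary.tsv"
    cn_table.to_csv(paths["cn_summary"], sep="\t", index=False)

    splits = _stage_ascnv(sim, cn_calls, config)
    paths["splits"] = write_splits_table(
        splits, outdir / "splits.tsv", provenance_header(config, "ascnv_resolve")
    )
    census = pattern_census(s for _, s in splits)

    profiles = refine(sim.records, sim.panel, cn_calls, splits, haplotypes)
    paths["lines"] = outdir / "lines.tsv"
    with open(paths["lines"], "w", encoding="utf-8") as fh:
        for line in provenance_header(config, "refine"):
            fh.write(f"# {line}\n")
        fh.write("sample_id\tbase_name\tfull_name\n")
        for p in sorted(profiles, key=lambda p: p.sample_id):
            fh.write(f"{p.sample_id}\t{p.base_name}\t{p.full_name}\n")

    L = config.pi_sites or len(sim.panel)
    div = _stage_diversity(sim.records, haplotypes, sim.panel, L)
    paths["diversity"] = outdir / "diversity.tsv"
    with open(paths["diversity"], "w", encoding="utf-8") as fh:
        for line in provenance_header(config, "diversity"):
            fh.write(f"# {line}\n")
        fh.write("population\tk\tN\thaplotypes\tpi\tpi_se\th\th_se\n")
        for row in div:
            fh.write(
                f"{row['population']}\t{row['k']}\t{row['N']}\t{row['haplotypes']}\t"
                f"{row.get('pi', float('nan')):.6f}\t{row.get('pi_se', float('nan')):.6f}\t"
                f"{row.get('h', float('nan')):.4f}\t{row.get('h_se', float('nan')):.4f}\n"
            )

    hap_vectors = {h.name: h.call_vector for h in haplotypes}
    site_labels = [l.locus_id for l in sim.panel]
    counts = {h.name: h.count for h in haplotypes}
    net = mp_prune(
        mjn(hap_vectors, epsilon=config.epsilon, counts=counts, site_labels=site_labels)
    )
    paths["network_edges"], paths["network_gml"] = export_network(
        net, outdir / "network", provenance_header(config, "network")
    )

    dm = hamming_matrix(hap_vectors)
    tree = upgma(dm)
    newick_snp = tree.to_newick()
    paths["upgma_snp"] = outdir / "upgma_snp.nwk"
    paths["upgma_snp"].write_text(newick_snp + "\n", encoding="utf-8")

    # joint tree over refined lines (one representative profile per line)
    reps = {}
    for p in profiles:
        reps.setdefault(p.full_name, p)
    spec = LayeredDistanceSpec(*config.weights)
    labels = sorted(reps)
    import numpy as np

    n_lines = len(labels)
    d = np.zeros((n_lines, n_lines))
    for i in range(n_lines):
        for j in range(i + 1, n_lines):
            d[i, j] = d[j, i] = layered_distance(reps[labels[i]], reps[labels[j]], spec)
    newick_layered = ""
    if n_lines >= 2:
        safe = {lab: f"LINE{i + 1}" for i, lab in enumerate(labels)}
        tree2 = upgma(DistanceMatrix([safe[lab] for lab in labels], d))
        newick_layered = tree2.to_newick()
        paths["upgma_layered"] = outdir / "upgma_layered.nwk"
        with open(paths["upgma_layered"], "w", encoding="utf-8") as fh:
            fh.write(newick_layered + "\n")
        paths["line_key"] = outdir / "line_key.tsv"
        with open(paths["line_key"], "w", encoding="utf-8") as fh:
            fh.write("line\tfull_name\n")
            for lab in labels:
                fh.write(f"{safe[lab]}\t{lab}\n")

    return PipelineResult(
        sim=sim,
        haplotypes=haplotypes,
        cn_calls=cn_calls,
        splits=splits,
        profiles=profiles,
        diversity_table=div,
        census=census,
        cn_table=cn_table,
        newick_snp=newick_snp,
        newick_layered=newick_layered,
        paths=paths,
    )
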