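"""Synthetic patrilineal datasets with known truth.

Emulates the statistical structure of the real study system — a set of
stallions whose Y chromosomes descend through a single genealogy — without
any real data: SNP mutations are placed on a random bifurcating genealogy
under an infinite-sites model (each site mutates at most once, so the true
haplotypes admit a perfect phylogeny); integer copy numbers on repeated
fragments evolve by stepwise moves on a geometric ladder; a mutation landing
on a multi-copy fragment hits a subset of its repeat copies, producing a
double base call with a true allele split; qPCR Ct values and pyrosequencing
allele ratios are then emitted with bounded noise.

Defaults are the study's stated world: 302 samples, a 14-site SNP panel,
copy-number ladder {1, 2, 5, 10, 20}, Ct noise 0.1 cycles, allele-ratio
noise within ±1/(4·CN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .markers import Locus, SampleRecord, MISSING

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate", "table_fixture"]

#: Copy numbers observed across the study's multi-copy fragments.
DEFAULT_LADDER = (1, 2, 5, 10, 20)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    ``theta`` is the expected number of SNP mutations per genealogy branch;
    its default places ~14 mutations on the whole tree (the panel size), so
    simulated samples segregate at about as many sites as the panel holds.
    """

    seed: int
    n_samples: int = 302
    n_populations: int = 5
    n_snp_loci: int = 14
    n_multi_copy: int = 6
    cn_ladder: tuple[int, ...] = DEFAULT_LADDER
    cn_change_rate: float = 0.05
    split_change_rate: float = 0.05
    theta: float | None = None
    ct_noise_sd: float = 0.1
    ct_reference_mean: float = 20.0
    rbv_noise_quarter: bool = True
    dropout_rate: float = 0.02
    #: lab protocol: a triplicate whose Ct range exceeds the QC threshold is
    #: re-run; this caps the total number of attempts per sample-locus.
    max_qc_attempts: int = 3
    qc_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("cn_change_rate", "split_change_rate", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_multi_copy > self.n_snp_loci:
            raise ValueError("n_multi_copy cannot exceed n_snp_loci")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")

    @property
    def branch_theta(self) -> float:
        if self.theta is not None:
            return self.theta
        return self.n_snp_loci / (2 * self.n_samples - 2)


@dataclass
class SimTruth:
    """The generator's hidden state, for recovery tests.

    ``parent`` holds the genealogy as child->parent indices over internal
    nodes and leaves; ``mutations`` maps panel site index -> branch (child
    node) where the single mutation happened.
    """

    parent: dict[int, int]
    mutations: dict[int, int]
    sample_node: dict[str, int]
    haplotype: dict[str, tuple[str, ...]]
    cn: dict[str, dict[str, int]]
    split: dict[str, dict[str, tuple[int, int]]]
    population: dict[str, str]

    def line_partition(self) -> dict[tuple, tuple[str, ...]]:
        """Samples grouped by their full true three-layer profile."""
        groups: dict[tuple, list[str]] = {}
        for sid in self.haplotype:
            key = (
                self.haplotype[sid],
                tuple(sorted(self.cn[sid].items())),
                tuple(sorted(self.split[sid].items())),
            )
            groups.setdefault(key, []).append(sid)
        return {k: tuple(sorted(v)) for k, v in groups.items()}


@dataclass
class SimResult:
    """Generated dataset: panel, genotype records, plate tables, and truth."""

    config: SimConfig
    panel: list[Locus]
    records: list[SampleRecord]
    qpcr_rows: list[dict]
    pyro_rows: list[dict]
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genotype/qPCR/pyro TSVs plus truth tables; returns the paths."""
        from .markers import write_genotype_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.tsv",
            "qpcr": outdir / "qpcr.tsv",
            "pyro": outdir / "pyro.tsv",
            "truth_cn": outdir / "truth_cn.tsv",
            "truth_haplotypes": outdir / "truth_haplotypes.tsv",
        }
        write_genotype_table(self.records, self.panel, paths["genotypes"])
        with open(paths["qpcr"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\tlocus_id\trep\tct_target\tct_reference\n")
            for row in self.qpcr_rows:
                fh.write(
                    f"{row['sample_id']}\t{row['locus_id']}\t{row['rep']}\t"
                    f"{row['ct_target']:.6f}\t{row['ct_reference']:.6f}\n"
                )
        with open(paths["pyro"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\tlocus_id\trbv\n")
            for row in self.pyro_rows:
                fh.write(f"{row['sample_id']}\t{row['locus_id']}\t{row['rbv']:.6f}\n")
        with open(paths["truth_cn"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\tlocus_id\tcn\ta_copies\tb_copies\n")
            for sid in sorted(self.truth.cn):
                for lid in sorted(self.truth.cn[sid]):
                    a, b = self.truth.split.get(sid, {}).get(lid, ("", ""))
                    fh.write(f"{sid}\t{lid}\t{self.truth.cn[sid][lid]}\t{a}\t{b}\n")
        with open(paths["truth_haplotypes"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\tpopulation\thaplotype\n")
            for sid in sorted(self.truth.haplotype):
                fh.write(
                    f"{sid}\t{self.truth.population[sid]}\t"
                    f"{''.join(c if len(c) == 1 else f'[{c}]' for c in self.truth.haplotype[sid])}\n"
                )
        return paths


def _simulate_genealogy(n: int, rng: np.random.Generator) -> dict[int, int]:
    """Random bifurcating genealogy by uniform coalescent-style merging.

    Leaves are nodes 0..n-1; internal nodes get successive indices; the root
    has no parent entry.  Returns child -> parent.
    """
    parent: dict[int, int] = {}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = next_id
        parent[b] = next_id
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return parent


def _step_on_ladder(value: int, ladder: Sequence[int], rng: np.random.Generator) -> int:
    i = ladder.index(value)
    if i == 0:
        return ladder[1]
    if i == len(ladder) - 1:
        return ladder[-2]
    return ladder[i + 1] if rng.random() < 0.5 else ladder[i - 1]


def simulate(config: SimConfig) -> SimResult:
    """Generate a full synthetic dataset plus its hidden truth.

    The emitted tables are deterministic functions of the seed; running the
    generator twice with the same config yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # marker panel: the first n_multi_copy sites sit on repeated fragments
    bases = ("A", "C", "G", "T")
    panel: list[Locus] = []
    site_alleles: list[tuple[str, str]] = []
    for i in range(config.n_snp_loci):
        anc, der = rng.choice(4, size=2, replace=False)
        alleles = (bases[anc], bases[der])
        site_alleles.append(alleles)
        multi = i < config.n_multi_copy
        panel.append(
            Locus(
                locus_id=f"L{i + 1}",
                allele_set=alleles,
                multi_copy=multi,
                cn_ladder=config.cn_ladder if multi else (1,),
            )
        )

    parent = _simulate_genealogy(n, rng)
    root = next(iter(set(parent.values()) - set(parent)))
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    # place at most one mutation per site (infinite sites): each branch draws
    # Poisson(theta) hits; hits beyond the panel's unmutated sites are dropped
    branches = sorted(parent)  # every non-root node subtends one branch
    free_sites = list(range(config.n_snp_loci))
    mutations: dict[int, int] = {}
    order = rng.permutation(len(branches))
    for bi in order:
        b = branches[bi]
        for _ in range(rng.poisson(config.branch_theta)):
            if not free_sites:
                break
            site = free_sites.pop(int(rng.integers(len(free_sites))))
            mutations[site] = b

    # root state: ancestral allele everywhere; multi-copy loci start at a
    # ladder value drawn once per locus (study loci differ in modal CN)
    multi_ids = [l.locus_id for l in panel if l.multi_copy]
    root_cn = {
        lid: int(rng.choice(config.cn_ladder[1:]))  # repeats imply CN >= 2
        for lid in multi_ids
    }

    @dataclass
    class _State:
        calls: dict[str, str]
        cn: dict[str, int]
        split: dict[str, tuple[int, int]]  # (ancestral copies, derived copies)

    root_state = _State(
        calls={l.locus_id: site_alleles[i][0] for i, l in enumerate(panel)},
        cn=dict(root_cn),
        split={},
    )

    site_of_branch: dict[int, list[int]] = {}
    for site, b in mutations.items():
        site_of_branch.setdefault(b, []).append(site)

    states: dict[int, _State] = {}

    def descend(node: int, state: _State) -> None:
        states[node] = state
        for child in sorted(children.get(node, [])):
            calls = dict(state.calls)
            cn = dict(state.cn)
            split = dict(state.split)
            # stepwise CN evolution; a changed total rescales an existing split
            for lid in multi_ids:
                if rng.random() < config.cn_change_rate:
                    new_cn = _step_on_ladder(cn[lid], config.cn_ladder, rng)
                    if lid in split and new_cn >= 2:
                        a_frac = split[lid][0] / cn[lid]
                        a = min(max(int(round(a_frac * new_cn)), 1), new_cn - 1)
                        split[lid] = (a, new_cn - a)
                    elif lid in split:
                        del split[lid]  # collapsed to one copy: allele fixed
                        calls[lid] = calls[lid].split("/")[0]
                    cn[lid] = new_cn
            # split drift: copies convert between alleles, total preserved
            for lid in list(split):
                if rng.random() < config.split_change_rate:
                    a, b = split[lid]
                    total = a + b
                    if total >= 3:
                        if a == 1:
                            a += 1
                        elif b == 1:
                            a -= 1
                        else:
                            a += 1 if rng.random() < 0.5 else -1
                        split[lid] = (a, total - a)
            # SNP mutations on this branch
            for site in sorted(site_of_branch.get(child, [])):
                locus = panel[site]
                anc, der = site_alleles[site]
                lid = locus.locus_id
                if locus.multi_copy and cn[lid] >= 2:
                    k = int(rng.integers(1, cn[lid]))  # derived copies, 1..CN-1
                    calls[lid] = f"{anc}/{der}" if anc < der else f"{der}/{anc}"
                    # split stored as (first-allele, second-allele) copies in
                    # allele_set order = (ancestral, derived)
                    split[lid] = (cn[lid] - k, k)
                else:
                    calls[lid] = der
            descend(child, _State(calls, cn, split))

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    try:
        descend(root, root_state)
    finally:
        sys.setrecursionlimit(old_limit)

    # assemble per-sample outputs
    pop_names = [f"P{i + 1}" for i in range(config.n_populations)]
    group_cycle = ["SC", "NC", "NSC", "IN", "EP"]
    pop_group = {p: group_cycle[i % len(group_cycle)] for i, p in enumerate(pop_names)}
    sample_pop = {
        f"S{i + 1:03d}": pop_names[int(rng.integers(config.n_populations))]
        for i in range(n)
    }

    records: list[SampleRecord] = []
    qpcr_rows: list[dict] = []
    pyro_rows: list[dict] = []
    truth = SimTruth(
        parent=parent,
        mutations=mutations,
        sample_node={},
        haplotype={},
        cn={},
        split={},
        population=dict(sample_pop),
    )

    for i in range(n):
        sid = f"S{i + 1:03d}"
        st = states[i]
        truth.sample_node[sid] = i
        truth.haplotype[sid] = tuple(st.calls[l.locus_id] for l in panel)
        truth.cn[sid] = dict(st.cn)
        truth.split[sid] = dict(st.split)

        calls = dict(st.calls)
        for lid in list(calls):
            if rng.random() < config.dropout_rate:
                calls[lid] = MISSING
        records.append(
            SampleRecord(
                sample_id=sid,
                population=sample_pop[sid],
                group=pop_group[sample_pop[sid]],
                calls=calls,
            )
        )

        for lid in multi_ids:
            true_cn = st.cn[lid]
            # emulate the bench protocol: a triplicate whose Ct range exceeds
            # the QC threshold on either channel is re-run (bounded attempts)
            for _attempt in range(max(config.max_qc_attempts, 1)):
                refs = rng.normal(
                    config.ct_reference_mean, config.ct_noise_sd, size=3
                )
                tgts = refs - math.log2(true_cn / 2.0) + rng.normal(
                    0.0, config.ct_noise_sd, size=3
                )
                if (
                    refs.max() - refs.min() <= config.qc_threshold
                    and tgts.max() - tgts.min() <= config.qc_threshold
                ):
                    break
            for rep in (1, 2, 3):
                qpcr_rows.append(
                    {
                        "sample_id": sid,
                        "locus_id": lid,
                        "rep": rep,
                        "ct_target": float(tgts[rep - 1]),
                        "ct_reference": float(refs[rep - 1]),
                    }
                )

        for lid, (a, b) in sorted(st.split.items()):
            total = a + b
            halfwidth = 1.0 / (4.0 * total) if config.rbv_noise_quarter else 0.0
            rbv = a / total + rng.uniform(-halfwidth, halfwidth)
            rbv = min(max(rbv, 1e-6), 1 - 1e-6)
            pyro_rows.append({"sample_id": sid, "locus_id": lid, "rbv": rbv})

    return SimResult(config, panel, records, qpcr_rows, pyro_rows, truth)


# ---------------------------------------------------------------------------
# fixtures for the published summary rows
# ---------------------------------------------------------------------------

#: Haplotype frequency spectra of selected populations.  The published table
#: prints k/N, h, and SE(h) but not the carrier counts; these partitions are
#: DERIVED — each is the unique integer partition of N into k parts whose
#: unbiased gene diversity and standard error round to the printed values
#: (established by brute-force enumeration, re-run in the test suite).
_TABLE1_SPECTRA = {
    "YQ": (8,),
    "IMG": (6, 1),
    "KZK": (8, 4),
    "YN": (2, 1, 1, 1, 1, 1, 1),
    "GZ-JC": (3, 3, 3, 2, 1, 1),
}

#: Combination patterns of allele-specific copy numbers per locus, as printed
#: (first:second allele copies, allele order per the locus's base variants).
_TABLE4_PATTERNS = {
    "165": ["4:1"],
    "103": ["4:1"],
    "1": ["1:1"],
    "17": ["1:1", "1:4", "2:1", "2:3", "3:2", "4:1"],
    "9": ["1:1", "1:2", "1:4", "2:1", "2:3", "3:2"],
    "102": ["3:2", "4:1", "7:3"],
}

#: AMELY intron-2 allele counts among successfully genotyped samples:
#: 9 carry the ancestral C, 225 the derived T.
_AMELY_COUNTS = {"C": 9, "T": 225}


def table_fixture(name: str):
    """Small in-memory datasets encoding the published summary rows."""
    fixtures = {
        "table1_spectra": {k: tuple(v) for k, v in _TABLE1_SPECTRA.items()},
        "table4_patterns": {k: list(v) for k, v in _TABLE4_PATTERNS.items()},
        "amely_counts": dict(_AMELY_COUNTS),
    }
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(fixtures)}")
    return fixtures[name]
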