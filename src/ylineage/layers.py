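"""Hierarchical patriline refinement across the three marker layers.

Layer 1 is the SNP haplotype (a distinct multi-locus call vector).  Layer 2
splits carriers of the same SNP haplotype by their integer copy numbers on
the multi-copy fragments.  Layer 3 splits heterozygous carriers further by
the allele-specific copy-number pattern (e.g. G3A2 vs G2A3 — same genotype,
same total copy number, different paternal lines).  Refinement is strictly
nested: a finer layer can split a coarser group but never merge two of them.

Unknown layer entries (QC retests, unresolved samples) are agnostic: they
never split a group.  Samples with identical known entries form signature
groups; a group whose entries are a strict subset of exactly one
better-informed group's entries (agreeing wherever both are known) is
absorbed into it.  A partial sample compatible with several groups stays in
its own coarser group — it is unresolved, but it never bridges two
well-resolved lines into one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ascnv import AlleleSplit
from .cnv import CopyNumberCall
from .markers import MISSING, Haplotype, Locus, SampleRecord

__all__ = [
    "LayeredHaplotype",
    "LayeredDistanceSpec",
    "LayerConsistencyError",
    "refine",
    "layered_distance",
]


class LayerConsistencyError(ValueError):
    """An allele split that contradicts the sample's total copy number."""


@dataclass(frozen=True)
class LayeredDistanceSpec:
    """Weights for the joint three-layer distance (defaults 1, 1, 1)."""

    w_snp: float = 1.0
    w_cnv: float = 1.0
    w_ascnv: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_snp, self.w_cnv, self.w_ascnv) < 0:
            raise ValueError("weights must be non-negative")
        if self.w_snp == self.w_cnv == self.w_ascnv == 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class LayeredHaplotype:
    """One sample's three-layer patriline profile.

    ``cn_vector`` maps multi-copy locus ids to integer copy numbers;
    ``split_vector`` maps double-call locus ids to allele-split labels.
    Missing entries are unknown, not zero.  ``full_name`` canonicalizes the
    profile as ``base|locus=value,...|locus=label,...`` in panel order,
    with ``?`` for entries unknown across the sample's refined group.
    """

    sample_id: str
    base_name: str
    call_vector: tuple[str, ...] = ()
    cn_vector: dict[str, int] = field(default_factory=dict)
    split_vector: dict[str, str] = field(default_factory=dict)
    full_name: str = ""


def _canonical(base: str, panel: Sequence[Locus],
               cn: Mapping[str, object], split: Mapping[str, object]) -> str:
    cn_part = ",".join(
        f"{l.locus_id}={cn.get(l.locus_id, '?')}" for l in panel if l.multi_copy
    )
    split_part = ",".join(
        f"{lid}={split.get(lid, '?')}" for lid in sorted(split)
    )
    return f"{base}|{cn_part}|{split_part}"


_Sig = tuple[tuple[tuple[str, int], ...], tuple[tuple[str, str], ...]]


def _signature(p: "LayeredHaplotype") -> _Sig:
    return (
        tuple(sorted(p.cn_vector.items())),
        tuple(sorted(p.split_vector.items())),
    )


def _extends(more: _Sig, less: _Sig) -> bool:
    """True if *more* knows a strict superset of *less*'s entries and agrees
    with every entry *less* knows."""
    m_cn, m_sp = dict(more[0]), dict(more[1])
    l_cn, l_sp = dict(less[0]), dict(less[1])
    if not (set(l_cn) <= set(m_cn) and set(l_sp) <= set(m_sp)):
        return False
    if len(m_cn) + len(m_sp) == len(l_cn) + len(l_sp):
        return False
    return all(m_cn[k] == v for k, v in l_cn.items()) and all(
        m_sp[k] == v for k, v in l_sp.items()
    )


def _merge_partial_groups(sigs: list[_Sig]) -> dict[_Sig, _Sig]:
    """Map each signature to its final (possibly absorbing) signature."""
    target = {s: s for s in sigs}
    # least-informed first; deterministic order
    order = sorted(sigs, key=lambda s: (len(s[0]) + len(s[1]), s))
    changed = True
    while changed:
        changed = False
        roots = sorted(set(target.values()), key=lambda s: (len(s[0]) + len(s[1]), s))
        for s in order:
            root = target[s]
            hosts = [r for r in roots if r != root and _extends(r, root)]
            if len(hosts) == 1:
                for k, v in target.items():
                    if v == root:
                        target[k] = hosts[0]
                changed = True
                break
    return target


def refine(
    records: Sequence[SampleRecord],
    panel: Sequence[Locus],
    cn_calls: Sequence[CopyNumberCall],
    splits: Sequence[tuple[str, AlleleSplit]],
    haplotypes: Sequence[Haplotype] | None = None,
) -> list[LayeredHaplotype]:
    """Assign every sample a layered patriline and a canonical full name.

    Samples sharing a layer-1 haplotype but differing in copy number at any
    multi-copy locus — or in allele split at any double-call locus — receive
    distinct full names.  A split whose copies do not sum to the sample's
    integer CN raises :class:`LayerConsistencyError` naming sample and locus.
    """
    from .markers import collapse_haplotypes

    if haplotypes is None:
        haplotypes = collapse_haplotypes(records, panel)
    base_of: dict[str, str] = {}
    for h in haplotypes:
        for sid in h.carrier_ids:
            base_of[sid] = h.name

    cn_by_sample: dict[str, dict[str, int]] = {}
    for c in cn_calls:
        if c.qc_flag == "pass" and c.cn_integer is not None:
            cn_by_sample.setdefault(c.sample_id, {})[c.locus_id] = c.cn_integer
    split_by_sample: dict[str, dict[str, str]] = {}
    for sid, s in splits:
        if s.ambiguous:
            continue
        known_cn = cn_by_sample.get(sid, {}).get(s.locus_id)
        if known_cn is not None and s.total_cn != known_cn:
            raise LayerConsistencyError(
                f"sample {sid} locus {s.locus_id}: split {s.label} sums to "
                f"{s.total_cn} but the integer copy-number call is {known_cn}"
            )
        split_by_sample.setdefault(sid, {})[s.locus_id] = s.label

    multi_loci = [l.locus_id for l in panel if l.multi_copy]
    profiles: list[LayeredHaplotype] = []
    for rec in records:
        base = base_of.get(rec.sample_id)
        if base is None:
            continue  # incomplete layer-1 calls; excluded upstream
        profiles.append(
            LayeredHaplotype(
                sample_id=rec.sample_id,
                base_name=base,
                call_vector=rec.call_vector(panel),
                cn_vector=dict(cn_by_sample.get(rec.sample_id, {})),
                split_vector=dict(split_by_sample.get(rec.sample_id, {})),
            )
        )

    # Group samples within each layer-1 haplotype by their known-entry
    # signature; absorb partial signatures into their unique extension.
    by_base: dict[str, list[LayeredHaplotype]] = {}
    for p in profiles:
        by_base.setdefault(p.base_name, []).append(p)
    for base, members in by_base.items():
        sigs = sorted({_signature(p) for p in members})
        target = _merge_partial_groups(sigs)
        for p in members:
            final = target[_signature(p)]
            p.full_name = _canonical(base, panel, dict(final[0]), dict(final[1]))
    return profiles


def layered_distance(
    x: LayeredHaplotype,
    y: LayeredHaplotype,
    spec: LayeredDistanceSpec = LayeredDistanceSpec(),
) -> float:
    """Weighted three-layer distance between two patriline profiles.

    SNP layer: Hamming distance over call-strings.  CNV layer: sum of
    |log2 cn_x - log2 cn_y| over loci known in both (copy-number evolution
    is multiplicative, so a 5-vs-10 difference counts as one doubling).
    AS-CNV layer: number of loci whose split labels (known in both) differ.
    Unknown entries contribute zero — agnostic, never infinite.
    """
    d = 0.0
    if spec.w_snp:
        if len(x.call_vector) != len(y.call_vector):
            raise ValueError("profiles must share a SNP panel")
        d += spec.w_snp * sum(
            a != b
            for a, b in zip(x.call_vector, y.call_vector)
            if a != MISSING and b != MISSING
        )
    if spec.w_cnv:
        for lid in set(x.cn_vector) & set(y.cn_vector):
            d += spec.w_cnv * abs(
                math.log2(x.cn_vector[lid]) - math.log2(y.cn_vector[lid])
            )
    if spec.w_ascnv:
        for lid in set(x.split_vector) & set(y.split_vector):
            if x.split_vector[lid] != y.split_vector[lid]:
                d += spec.w_ascnv
    return d
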