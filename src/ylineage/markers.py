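"""Marker panel data model and genotype-table I/O.

The male-specific region of the Y chromosome is haploid, so each marker
normally yields a single base call per stallion.  Markers that sit inside
repeated Y fragments can return *double base calls* (e.g. ``"G/A"``) when
divergent repeat copies carry different bases; such a call is treated as an
atomic third state of the site, not as a diploid genotype.  A haplotype is a
distinct multi-locus vector of call-strings over a fixed marker panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Locus",
    "SampleRecord",
    "Haplotype",
    "MISSING",
    "GenotypeTableError",
    "read_genotype_table",
    "write_genotype_table",
    "collapse_haplotypes",
    "to_fasta",
    "iupac_code",
]

logger = logging.getLogger(__name__)

#: Call string used for a missing genotype.
MISSING = "."

#: Population group codes: south China, north China, non-Chinese/foreign
#: sampled in China, introduced breeds, and the Przewalski outgroup.
GROUPS = ("SC", "NC", "NSC", "IN", "EP")

_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}


class GenotypeTableError(ValueError):
    """Raised for malformed genotype tables or illegal calls."""


@dataclass(frozen=True)
class Locus:
    """One male-specific Y marker.

    Parameters
    ----------
    locus_id:
        Opaque marker name (e.g. ``"9"``, ``"17"``, ``"AMELY"``).
    allele_set:
        Ordered bases observed at the site (1 or 2 entries for biallelic
        markers).  The order fixes which allele is "first" for allele-ratio
        and split reporting.
    multi_copy:
        True if the marker resides in repeated fragments and may therefore
        show double base calls and copy-number variation.
    cn_ladder:
        Admissible integer copy numbers, strictly increasing, minimum >= 1.
    """

    locus_id: str
    allele_set: tuple[str, ...]
    multi_copy: bool = False
    cn_ladder: tuple[int, ...] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValueError("locus_id must be non-empty")
        if not 1 <= len(self.allele_set) <= 2:
            raise ValueError(
                f"locus {self.locus_id}: allele_set must have 1 or 2 entries"
            )
        ladder = tuple(int(v) for v in self.cn_ladder)
        if not ladder or ladder[0] < 1 or any(
            b <= a for a, b in zip(ladder, ladder[1:])
        ):
            raise ValueError(
                f"locus {self.locus_id}: cn_ladder must be strictly "
                "increasing with minimum >= 1"
            )
        object.__setattr__(self, "allele_set", tuple(self.allele_set))
        object.__setattr__(self, "cn_ladder", ladder)

    def validate_call(self, call: str) -> None:
        """Raise :class:`GenotypeTableError` if *call* is illegal here."""
        if call == MISSING:
            return
        bases = call.split("/")
        if len(bases) == 2 and not self.multi_copy:
            raise GenotypeTableError(
                f"double call {call!r} at single-copy locus {self.locus_id}"
            )
        if len(bases) > 2 or any(not b for b in bases):
            raise GenotypeTableError(
                f"malformed call {call!r} at locus {self.locus_id}"
            )
        if len(bases) == 2 and bases[0] == bases[1]:
            raise GenotypeTableError(
                f"degenerate double call {call!r} at locus {self.locus_id}"
            )
        for b in bases:
            if b not in self.allele_set:
                raise GenotypeTableError(
                    f"call {call!r} uses base {b!r} outside the allele set "
                    f"{self.allele_set} of locus {self.locus_id}"
                )


@dataclass
class SampleRecord:
    """One stallion: population label, group code, and per-locus calls."""

    sample_id: str
    population: str
    group: str
    calls: dict[str, str] = field(default_factory=dict)

    def is_complete(self, panel: Sequence[Locus]) -> bool:
        return all(self.calls.get(l.locus_id, MISSING) != MISSING for l in panel)

    def call_vector(self, panel: Sequence[Locus]) -> tuple[str, ...]:
        return tuple(self.calls.get(l.locus_id, MISSING) for l in panel)


@dataclass
class Haplotype:
    """A distinct multi-locus call vector with its carrier count.

    Names are assigned ``SHT1``, ``SHT2``, ... in descending carrier
    frequency, ties broken by lexicographic call vector, so naming is a
    deterministic function of the data.
    """

    name: str
    call_vector: tuple[str, ...]
    count: int
    carrier_ids: tuple[str, ...] = ()


def _validate_record(rec: SampleRecord, panel: Sequence[Locus]) -> None:
    for locus in panel:
        call = rec.calls.get(locus.locus_id, MISSING)
        try:
            locus.validate_call(call)
        except GenotypeTableError as exc:
            raise GenotypeTableError(f"sample {rec.sample_id}: {exc}") from None


def read_genotype_table(path: str | Path, panel: Sequence[Locus]) -> list[SampleRecord]:
    """Read a tab-separated genotype table into sample records.

    Expected header: ``sample_id``, ``population``, ``group``, then one
    column per panel locus.  Missing calls are encoded ``"."``.  Columns
    not in the panel are rejected; every call is checked against its locus.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(MISSING)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeTableError(f"cannot parse {path}: {exc}") from exc
    meta_cols = ["sample_id", "population", "group"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise GenotypeTableError(f"{path}: missing required columns {missing}")
    by_id = {l.locus_id: l for l in panel}
    unknown = [c for c in df.columns if c not in meta_cols and c not in by_id]
    if unknown:
        raise GenotypeTableError(f"{path}: unknown locus columns {unknown}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        rec = SampleRecord(
            sample_id=row["sample_id"],
            population=row["population"],
            group=row["group"],
            calls={
                lid: row[lid] for lid in by_id if lid in df.columns
            },
        )
        try:
            _validate_record(rec, panel)
        except GenotypeTableError as exc:
            raise GenotypeTableError(f"{path} line {i + 2}: {exc}") from None
        records.append(rec)
    return records


def write_genotype_table(
    records: Iterable[SampleRecord],
    panel: Sequence[Locus],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> Path:
    """Write records as a genotype TSV (inverse of :func:`read_genotype_table`)."""
    path = Path(path)
    cols = ["sample_id", "population", "group"] + [l.locus_id for l in panel]
    rows = []
    for rec in records:
        row = [rec.sample_id, rec.population, rec.group]
        row += [rec.calls.get(l.locus_id, MISSING) for l in panel]
        rows.append(row)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


def collapse_haplotypes(
    records: Sequence[SampleRecord], panel: Sequence[Locus]
) -> list[Haplotype]:
    """Collapse samples into haplotypes (distinct call vectors).

    Samples with any missing panel call are excluded (and logged); counts
    over the returned haplotypes sum to the number of included samples.
    """
    if not records:
        logger.warning("collapse_haplotypes: empty input")
        return []
    included: dict[tuple[str, ...], list[str]] = {}
    excluded: list[str] = []
    for rec in records:
        _validate_record(rec, panel)
        if rec.is_complete(panel):
            included.setdefault(rec.call_vector(panel), []).append(rec.sample_id)
        else:
            excluded.append(rec.sample_id)
    if excluded:
        logger.info(
            "collapse_haplotypes: excluded %d sample(s) with missing calls: %s",
            len(excluded),
            ", ".join(excluded),
        )
    ordered = sorted(included.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Haplotype(
            name=f"SHT{i}",
            call_vector=vec,
            count=len(ids),
            carrier_ids=tuple(sorted(ids)),
        )
        for i, (vec, ids) in enumerate(ordered, start=1)
    ]


def iupac_code(call: str) -> str:
    """Single character for a call-string: base, or IUPAC code for a double call."""
    bases = call.split("/")
    if len(bases) == 1:
        return bases[0]
    code = _IUPAC.get(frozenset(bases))
    if code is None:
        raise ValueError(f"no IUPAC ambiguity code for double call {call!r}")
    return code


def to_fasta(
    haplotypes: Sequence[Haplotype], panel: Sequence[Locus], path: str | Path
) -> Path:
    """Export haplotypes as pseudo-sequences (one character per panel site).

    Double calls are emitted as IUPAC ambiguity codes so the file can feed
    external alignment/phylogenetics tools.
    """
    path = Path(path)
    seqs = [
        SeqRecord(
            Seq("".join(iupac_code(c) for c in h.call_vector)),
            id=h.name,
            description="",
        )
        for h in haplotypes
    ]
    SeqIO.write(seqs, str(path), "fasta")
    return path
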