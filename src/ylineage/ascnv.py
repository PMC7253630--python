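"""Allele-specific copy number from pyrosequencing allele ratios.

At a double-call site on a multi-copy Y fragment the two alleles are split
across the repeat copies, not necessarily 1:1.  Pyrosequencing reports the
ratio of base variants (RBV): the fraction of signal carried by the locus's
first allele.  Given the sample's integer total copy number N, the split
(a, b) with a + b = N, a,b >= 1 whose expected ratio a/N is closest to the
observed RBV is the allele-specific copy-number call, labelled e.g. "G3A2"
(3 G-copies plus 2 A-copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PyroMeasurement",
    "AlleleSplit",
    "DEFAULT_TOLERANCE",
    "enumerate_splits",
    "resolve_split",
    "pattern_census",
    "read_pyro_table",
    "write_splits_table",
]

#: Two candidate splits closer than this in |a/N - RBV| are reported ambiguous.
#: Pyrosequencing allele quantification is accurate to a few percent.
DEFAULT_TOLERANCE = 0.02


@dataclass(frozen=True)
class PyroMeasurement:
    """One sample's allele ratio at one double-call locus."""

    sample_id: str
    locus_id: str
    rbv: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rbv < 1.0:
            raise ValueError(f"rbv must be in (0, 1), got {self.rbv}")


@dataclass(frozen=True)
class AlleleSplit:
    """Integer split of a locus's total copies between its two alleles."""

    locus_id: str
    allele_a: str
    allele_b: str
    a_copies: int
    b_copies: int
    ambiguous: bool = False
    #: runner-up (a, b) when ambiguous, else None
    alternative: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.a_copies < 1 or self.b_copies < 1:
            raise ValueError("each allele of a heterozygous site needs >= 1 copy")

    @property
    def total_cn(self) -> int:
        return self.a_copies + self.b_copies

    @property
    def label(self) -> str:
        return f"{self.allele_a}{self.a_copies}{self.allele_b}{self.b_copies}"

    @property
    def ratio(self) -> str:
        return f"{self.a_copies}:{self.b_copies}"


def enumerate_splits(total_cn: int) -> list[tuple[int, int]]:
    """All (a, b) with a + b = total_cn and a, b >= 1, in descending a.

    A heterozygous site needs at least one copy of each allele, so
    total_cn must be >= 2; the list has total_cn - 1 entries.
    """
    if total_cn < 2:
        raise ValueError(
            f"a heterozygous multi-copy site needs total CN >= 2, got {total_cn}"
        )
    return [(a, total_cn - a) for a in range(total_cn - 1, 0, -1)]


def resolve_split(
    total_cn: int,
    rbv: float,
    alleles: tuple[str, str] = ("G", "A"),
    tolerance: float = DEFAULT_TOLERANCE,
    locus_id: str = "",
) -> AlleleSplit:
    """Pick the split whose expected first-allele fraction a/N best matches *rbv*.

    If the best and second-best candidates differ by less than *tolerance*
    in the |a/N - rbv| objective, the call is flagged ambiguous and the
    runner-up is reported alongside.  Exact objective ties break toward the
    larger a (then the runner-up carries the mirror).
    """
    if not 0.0 < rbv < 1.0:
        raise ValueError(f"rbv must be in (0, 1), got {rbv}")
    candidates = enumerate_splits(total_cn)
    scored = sorted(
        ((abs(a / total_cn - rbv), a, b) for a, b in candidates),
        key=lambda t: (t[0], -t[1]),
    )
    best = scored[0]
    ambiguous = len(scored) > 1 and (scored[1][0] - best[0]) < tolerance
    alternative = (scored[1][1], scored[1][2]) if ambiguous else None
    return AlleleSplit(
        locus_id=locus_id,
        allele_a=alleles[0],
        allele_b=alleles[1],
        a_copies=best[1],
        b_copies=best[2],
        ambiguous=ambiguous,
        alternative=alternative,
    )


def pattern_census(splits: Iterable[AlleleSplit]) -> dict[str, list[str]]:
    """Distinct a:b combination patterns per locus, unambiguous calls only.

    Patterns are keyed by allele order as given in the locus allele set, so
    3:2 and 2:3 are distinct patterns; within a locus they are listed in
    ascending (a, b) order.
    """
    seen: dict[str, set[tuple[int, int]]] = {}
    for s in splits:
        if s.ambiguous:
            continue
        seen.setdefault(s.locus_id, set()).add((s.a_copies, s.b_copies))
    return {
        lid: [f"{a}:{b}" for a, b in sorted(pairs)]
        for lid, pairs in sorted(seen.items())
    }


def read_pyro_table(path: str | Path) -> list[PyroMeasurement]:
    """Read a pyrosequencing TSV: sample_id, locus_id, rbv."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "locus_id": str})
    required = {"sample_id", "locus_id", "rbv"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pyro table needs columns {sorted(required)}")
    return [
        PyroMeasurement(row.sample_id, row.locus_id, float(row.rbv))
        for row in df.itertuples(index=False)
    ]


def write_splits_table(
    splits: Sequence[tuple[str, AlleleSplit]], path: str | Path,
    header_lines: Sequence[str] = (),
) -> Path:
    """Write resolved (sample_id, split) pairs as a TSV."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "sample_id\tlocus_id\ta_copies\tb_copies\tlabel\tambiguous\n"
        )
        for sid, s in splits:
            fh.write(
                f"{sid}\t{s.locus_id}\t{s.a_copies}\t{s.b_copies}\t"
                f"{s.label}\t{str(s.ambiguous).lower()}\n"
            )
    return path
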