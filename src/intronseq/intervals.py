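"""Half-open genomic intervals and the sweep primitives the catalog is built on.

All coordinates in this package are 0-based, half-open ``[start, end)``.
GFF3 input (1-based, closed) is converted at the parsing boundary and BED
output needs no conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous genomic region on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name. Must be non-empty.
    start, end : int
        0-based half-open bounds; ``start < end``.
    strand : str
        ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent ``(start, end)`` spans into a sorted,
    disjoint, non-adjacent list."""
    ordered = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged]


def subtract_spans(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference a \\ b for two span lists; ``a`` need not be merged.

    Returns a merged, sorted list; zero-length remnants are dropped.
    """
    a = merge_spans(a)
    b = merge_spans(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(spans: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_spans(spans))
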