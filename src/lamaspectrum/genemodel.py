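"""Transcript gene model: mapping cDNA coordinates to exon/intron regions.

A :class:`GeneModel` is an ordered list of exons given as contiguous,
non-overlapping cDNA intervals (exon k+1 starts where exon k ends, +1).
Intron ``k`` is the intron between exon ``k`` and exon ``k+1``; intronic
positions are addressed HGVS-style through an exonic anchor plus a signed
offset (``+`` past a donor site, ``-`` before an acceptor site).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .hgvs import CdnaEvent, VariantDescription

__all__ = ["GeneModel", "RegionAssignment", "assign_region", "positional_histogram",
           "region_counts_from_labels", "crosscheck_labels"]


@dataclass(frozen=True, order=True)
class RegionAssignment:
    """An exon or intron of the transcript, 1-based."""

    kind: str  # "exon" | "intron"
    index: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"region kind must be exon|intron, got {self.kind!r}")
        if self.index < 1:
            raise ValueError("region index is 1-based")

    def __str__(self) -> str:
        return f"{self.kind} {self.index}"


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript in cDNA coordinates."""

    transcript_id: str
    exons: tuple[tuple[int, int, int], ...]  # (index, cdna_start, cdna_end)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = 0
        for i, (idx, start, end) in enumerate(self.exons, start=1):
            if idx != i:
                raise ValueError(f"exon indices must run 1..n, got {idx} at slot {i}")
            if start != prev_end + 1:
                raise ValueError(
                    f"exon {idx} starts at {start}, expected {prev_end + 1} (contiguous cDNA)"
                )
            if end < start:
                raise ValueError(f"exon {idx} has end {end} < start {start}")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cdna_length(self) -> int:
        return self.exons[-1][2]

    @classmethod
    def from_boundaries(cls, transcript_id: str, exon_ends: Sequence[int]) -> "GeneModel":
        """Build from the cumulative cDNA end coordinate of each exon."""
        exons, start = [], 1
        for i, end in enumerate(exon_ends, start=1):
            exons.append((i, start, end))
            start = end + 1
        return cls(transcript_id, tuple(exons))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, transcript_id: str = "custom") -> "GeneModel":
        required = {"exon_index", "cdna_start", "cdna_end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene model table missing column(s) {sorted(missing)}")
        rows = df.sort_values("exon_index")
        return cls(
            transcript_id,
            tuple((int(r.exon_index), int(r.cdna_start), int(r.cdna_end)) for r in rows.itertuples()),
        )


def _exon_of(model: GeneModel, pos: int) -> int:
    if pos < 1 or pos > model.cdna_length:
        raise ValueError(
            f"cDNA position {pos} outside transcript {model.transcript_id} "
            f"(1..{model.cdna_length})"
        )
    for idx, start, end in model.exons:
        if start <= pos <= end:
            return idx
    raise AssertionError("unreachable: contiguous exons cover 1..length")


def _assign_point(model: GeneModel, anchor: int, offset: int) -> RegionAssignment:
    exon = _exon_of(model, anchor)
    start, end = model.exons[exon - 1][1], model.exons[exon - 1][2]
    if offset == 0:
        return RegionAssignment("exon", exon)
    if offset > 0:
        if anchor != end:
            raise ValueError(
                f"positive intronic offset at {anchor}{offset:+d}: anchor is not the end of exon {exon}"
            )
        if exon == model.n_exons:
            raise ValueError(f"no intron after terminal exon {exon}")
        return RegionAssignment("intron", exon)
    if anchor != start:
        raise ValueError(
            f"negative intronic offset at {anchor}{offset:+d}: anchor is not the start of exon {exon}"
        )
    if exon == 1:
        raise ValueError("no intron before exon 1")
    return RegionAssignment("intron", exon - 1)


def assign_region(model: GeneModel, e: CdnaEvent) -> tuple[RegionAssignment, ...]:
    """All regions touched by a cDNA event, in transcript order.

    Point events yield one region; range events yield every exon and
    intron between their endpoints; exon-level events yield their exon
    span directly.
    """
    if e.is_exon_level:
        n = model.n_exons
        for idx in e.exon_span:
            if idx > n:
                raise ValueError(f"exon {idx} outside model with {n} exons")
        return tuple(RegionAssignment("exon", idx) for idx in e.exon_span)
    first = _assign_point(model, e.start_anchor, e.start_offset)
    last = _assign_point(model, e.end_anchor, e.end_offset)
    if first == last:
        return (first,)
    # enumerate exon k, intron k, exon k+1, ... between the two endpoints
    order = lambda r: 2 * r.index - (1 if r.kind == "exon" else 0)
    lo, hi = sorted((order(first), order(last)))
    out = []
    for code in range(lo, hi + 1):
        if code % 2 == 1:
            out.append(RegionAssignment("exon", (code + 1) // 2))
        else:
            out.append(RegionAssignment("intron", code // 2))
    return tuple(out)


def positional_histogram(
    model: GeneModel, variants: Iterable[VariantDescription]
) -> "pd.Series":
    """Distinct-variant counts per exon/intron bin of the model.

    Every exon and intron appears as a bin (zero-filled). A variant
    touching several regions (a range or an exon-level event) adds one
    count to each touched bin, so the total mass equals the number of
    single-region variants plus the span sizes of multi-region events.
    """
    bins: list[RegionAssignment] = []
    for k in range(1, model.n_exons + 1):
        bins.append(RegionAssignment("exon", k))
        if k < model.n_exons:
            bins.append(RegionAssignment("intron", k))
    counts = Counter()
    for v in variants:
        for region in assign_region(model, v.cdna):
            counts[region] += 1
    return pd.Series([counts.get(b, 0) for b in bins], index=[str(b) for b in bins], name="variants")


_LABEL_INTRON = "intron"


def _parse_label(label: str) -> tuple[RegionAssignment, ...]:
    s = label.strip().lower()
    if s.startswith(_LABEL_INTRON):
        return (RegionAssignment("intron", int(s[len(_LABEL_INTRON):].strip())),)
    return tuple(
        RegionAssignment("exon", int(tok)) for tok in s.replace(",", " ").split() if tok
    )


def region_counts_from_labels(labels: Iterable[str]) -> Counter:
    """Distinct-variant counts per region taken from a table's own
    ``region_label`` column (e.g. ``"54"``, ``"Intron 58"``, ``"57,58"``).

    This is the model-independent route: it needs no exon coordinates and
    serves as the oracle against which model-derived assignments are
    cross-checked.
    """
    counts: Counter = Counter()
    for label in labels:
        for region in _parse_label(label):
            counts[region] += 1
    return counts


def crosscheck_labels(
    model: GeneModel, variants: Iterable[VariantDescription]
) -> list[tuple[str, str, str]]:
    """Compare model-derived region assignments against each variant's
    stated label; return (cdna, stated, computed) for every mismatch.

    Mismatches are reported, not fatal: published tables occasionally
    carry label typos, and the model itself may be approximate.
    """
    mismatches = []
    for v in variants:
        stated = set(_parse_label(v.region_label)) if v.region_label else set()
        computed = set(assign_region(model, v.cdna))
        if stated and stated != computed:
            mismatches.append(
                (v.key, v.region_label, ", ".join(str(r) for r in sorted(computed)))
            )
    return mismatches
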