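"""Allele-spectrum statistics for a biallelic recessive cohort.

The central object is the :class:`AlleleSpectrum`: the distinct
pathogenic variants of a cohort with their chromosome (allele) counts.
From it the module derives the consequence-type distribution over
distinct variants, the recurrent-variant list with cumulative allele
shares, and per-variant shares — the quantities a national
variant-spectrum survey reports.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .hgvs import Consequence, VariantDescription, describe_variant

__all__ = [
    "SpectrumError",
    "SpectrumConsistencyWarning",
    "AlleleSpectrum",
    "SpectrumSummary",
    "build_spectrum",
    "type_distribution",
    "top_variants",
    "variant_share",
    "summarize",
    "summarize_cohort",
    "spectrum_from_cohort",
    "round_half_up",
]


class SpectrumError(ValueError):
    """Inconsistent or unusable spectrum input."""


class SpectrumConsistencyWarning(UserWarning):
    """Soft consistency problem (e.g. allele total != 2 x patients)."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed clinical
    tables (Python's built-in round is banker's rounding)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class AlleleSpectrum:
    """Distinct variants with allele counts over a cohort of chromosomes."""

    entries: tuple[tuple[VariantDescription, int], ...]
    total_alleles: int
    n_patients: int | None = None

    def __post_init__(self) -> None:
        if not self.entries:
            raise SpectrumError("empty spectrum")
        if any(c < 1 for _, c in self.entries):
            raise SpectrumError("allele counts must be >= 1")
        if sum(c for _, c in self.entries) != self.total_alleles:
            raise SpectrumError("allele counts do not sum to total_alleles")
        keys = [v.key for v, _ in self.entries]
        if len(set(keys)) != len(keys):
            raise SpectrumError("duplicate variants in spectrum entries")

    @property
    def n_distinct(self) -> int:
        return len(self.entries)

    def count_of(self, cdna_key: str) -> int | None:
        for v, c in self.entries:
            if v.key == cdna_key:
                return c
        return None


@dataclass(frozen=True)
class SpectrumSummary:
    """Derived spectrum statistics (counts over *distinct* variants)."""

    class_counts: Mapping[Consequence, int]
    class_fractions: Mapping[Consequence, float]
    top_variants: tuple[tuple[VariantDescription, int, float], ...]
    cumulative_top_share: float
    allele_weighted_fractions: Mapping[Consequence, float] = field(default_factory=dict)


def build_spectrum(
    rows: pd.DataFrame,
    n_patients: int | None = None,
    strict_2n: bool = False,
) -> AlleleSpectrum:
    """Build an :class:`AlleleSpectrum` from a variant table.

    Parameters
    ----------
    rows
        Variant table with columns ``cdna``, ``protein``, ``allele_count``
        and optionally ``region_label``. Duplicate cDNA strings are merged
        by summing counts, provided their protein strings agree.
    n_patients
        If given, the allele total is checked against ``2 * n_patients``;
        a mismatch warns (or raises when ``strict_2n``).
    """
    if rows is None or len(rows) == 0:
        raise SpectrumError("variant table is empty")
    merged: dict[str, tuple[VariantDescription, int]] = {}
    for i, row in enumerate(rows.itertuples(), start=1):
        count = int(row.allele_count)
        if count < 1:
            raise SpectrumError(f"row {i}: allele_count must be >= 1, got {count}")
        v = describe_variant(row.cdna, row.protein, getattr(row, "region_label", "") or "")
        if v.key in merged:
            prev, prev_count = merged[v.key]
            if prev.protein != v.protein:
                raise SpectrumError(
                    f"row {i}: {v.key} already seen with protein "
                    f"{prev.protein.raw!r}, now {v.protein.raw!r}"
                )
            merged[v.key] = (prev, prev_count + count)
        else:
            merged[v.key] = (v, count)
    total = sum(c for _, c in merged.values())
    if n_patients is not None and total != 2 * n_patients:
        msg = f"allele total {total} != 2 x {n_patients} patients"
        if strict_2n:
            raise SpectrumError(msg)
        warnings.warn(msg, SpectrumConsistencyWarning, stacklevel=2)
    return AlleleSpectrum(tuple(merged.values()), total, n_patients)


def type_distribution(s: AlleleSpectrum) -> tuple[dict[Consequence, int], dict[Consequence, float]]:
    """Consequence-class counts and fractions over *distinct* variants.

    The denominator is the number of distinct variants, not alleles: a
    variant seen on 27 chromosomes still counts once. (The allele-weighted
    version is available through :func:`summarize`.)
    """
    counts: dict[Consequence, int] = {}
    for v, _ in s.entries:
        counts[v.consequence] = counts.get(v.consequence, 0) + 1
    fractions = {k: c / s.n_distinct for k, c in counts.items()}
    return counts, fractions


def _allele_weighted(s: AlleleSpectrum) -> dict[Consequence, float]:
    weighted: dict[Consequence, float] = {}
    for v, c in s.entries:
        weighted[v.consequence] = weighted.get(v.consequence, 0.0) + c / s.total_alleles
    return weighted


def top_variants(
    s: AlleleSpectrum, min_count: int = 2
) -> tuple[tuple[tuple[VariantDescription, int, float], ...], float]:
    """Recurrent variants with count >= ``min_count``, sorted by count
    descending (ties by canonical cDNA string), plus their cumulative
    share of all patient chromosomes."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    selected = [(v, c) for v, c in s.entries if c >= min_count]
    selected.sort(key=lambda vc: (-vc[1], vc[0].key))
    out = tuple((v, c, c / s.total_alleles) for v, c in selected)
    cumulative = sum(c for _, c in selected) / s.total_alleles
    return out, cumulative


def variant_share(s: AlleleSpectrum, cdna: str) -> tuple[int, float]:
    """Allele count and share of one variant, looked up by canonical cDNA
    string (the query is itself parsed and canonicalised first)."""
    key = describe_variant(cdna, "p.?").key if not _in_keys(s, cdna) else cdna
    count = s.count_of(key)
    if count is None:
        raise KeyError(f"variant {cdna!r} not present in spectrum")
    return count, count / s.total_alleles


def _in_keys(s: AlleleSpectrum, cdna: str) -> bool:
    return any(v.key == cdna for v, _ in s.entries)


def summarize(s: AlleleSpectrum, min_count: int = 2) -> SpectrumSummary:
    counts, fractions = type_distribution(s)
    top, cumulative = top_variants(s, min_count)
    return SpectrumSummary(
        class_counts=counts,
        class_fractions=fractions,
        top_variants=top,
        cumulative_top_share=cumulative,
        allele_weighted_fractions=_allele_weighted(s),
    )


# --------------------------------------------------------------------------
# cohort-level descriptive summary
# --------------------------------------------------------------------------


def summarize_cohort(patients: pd.DataFrame) -> dict:
    """Descriptive counts for a genotype table: sex and phenotype splits
    and homozygote counts per variant.

    Fractions use as denominator only the patients with the field present;
    an all-missing column yields counts of 0 and no fractions. A patient
    with zygosity ``unknown`` but a single listed variant is counted as a
    homozygote (and flagged in the output), matching the convention of
    assuming homozygosity where consanguinity makes it likely.
    """
    n = len(patients)
    out: dict = {"n_patients": n}

    def _split(col: str) -> dict:
        if col not in patients.columns:
            return {"counts": {}, "fractions": {}}
        values = patients[col].dropna()
        values = values[values.astype(str).str.strip() != ""]
        counts = values.value_counts().to_dict()
        denom = int(sum(counts.values()))
        fractions = {k: v / denom for k, v in counts.items()} if denom else {}
        return {"counts": {k: int(v) for k, v in counts.items()}, "fractions": fractions}

    out["sex"] = _split("sex")
    out["phenotype"] = _split("phenotype")

    homo: dict[str, int] = {}
    assumed = 0
    incomplete = 0
    for row in patients.itertuples():
        a1 = str(getattr(row, "allele1_cdna", "") or "").strip()
        a2 = str(getattr(row, "allele2_cdna", "") or "").strip()
        zyg = str(getattr(row, "zygosity", "") or "").strip().lower()
        if not a1 and not a2:
            incomplete += 1
            continue
        if zyg == "hom" or (a1 and a1 == a2):
            homo[a1 or a2] = homo.get(a1 or a2, 0) + 1
        elif zyg == "unknown" and bool(a1) != bool(a2):
            variant = a1 or a2
            homo[variant] = homo.get(variant, 0) + 1
            assumed += 1
            warnings.warn(
                f"patient {getattr(row, 'patient_id', '?')}: single variant with unknown "
                "zygosity counted as homozygous",
                SpectrumConsistencyWarning,
                stacklevel=2,
            )
        elif not a1 or not a2:
            incomplete += 1
            warnings.warn(
                f"patient {getattr(row, 'patient_id', '?')}: missing allele slot",
                SpectrumConsistencyWarning,
                stacklevel=2,
            )
    out["homozygotes"] = homo
    out["homozygotes_assumed_from_unknown_zygosity"] = assumed
    out["incomplete_records"] = incomplete
    return out


def spectrum_from_cohort(patients: pd.DataFrame) -> pd.DataFrame:
    """Collapse a genotype table (two allele slots per patient) into a
    variant-table frame suitable for :func:`build_spectrum`.

    Homozygous and assumed-homozygous genotypes contribute two alleles.
    Protein strings are not known from a genotype table, so ``p.?`` is
    used throughout; consequence classes then rely on the cDNA side only.
    """
    counts: dict[str, int] = {}
    for row in patients.itertuples():
        a1 = str(getattr(row, "allele1_cdna", "") or "").strip()
        a2 = str(getattr(row, "allele2_cdna", "") or "").strip()
        zyg = str(getattr(row, "zygosity", "") or "").strip().lower()
        alleles: list[str]
        if a1 and a2:
            alleles = [a1, a2]
        elif (a1 or a2) and zyg in ("hom", "unknown"):
            alleles = [a1 or a2] * 2
        else:
            alleles = [a for a in (a1, a2) if a]
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
    return pd.DataFrame(
        {"cdna": list(counts), "protein": "p.?", "allele_count": list(counts.values())}
    )
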