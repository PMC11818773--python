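"""ACMG/AMP 2015 pathogenic-side evidence combination.

Evidence codes (PVS1; PS1-PS4; PM1-PM6; PP1-PP5) default to the strength
of their prefix class (very strong / strong / moderate / supporting) and
are combined by the 2015 guideline's fixed rules into Pathogenic, Likely
pathogenic or VUS. Benign-side codes (BA1, BS1-BS4, BP1-BP7) are accepted
syntactically but take no part in combining: conflicting-evidence
resolution is out of scope. Strength modulation (e.g. ``PVS1_Moderate``)
is supported through explicit overrides and is off by default.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AcmgError",
    "Strength",
    "Verdict",
    "EvidenceSet",
    "Classification",
    "parse_codes",
    "combine",
    "classify_table",
    "PATHOGENIC_CODES",
    "BENIGN_CODES",
]


class AcmgError(ValueError):
    """Unknown or malformed evidence code."""


class Strength(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Verdict(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"


PATHOGENIC_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = frozenset(["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)])

_DEFAULT_STRENGTH = {"PVS": Strength.VERY_STRONG, "PS": Strength.STRONG,
                     "PM": Strength.MODERATE, "PP": Strength.SUPPORTING}


def _default_strength(code: str) -> Strength:
    prefix = code[:3] if code.startswith("PVS") else code[:2]
    return _DEFAULT_STRENGTH[prefix]


@dataclass(frozen=True)
class EvidenceSet:
    """A set of pathogenic-side codes, with optional per-code strength
    overrides (``{"PVS1": Strength.MODERATE}``)."""

    codes: frozenset[str]
    overrides: Mapping[str, Strength] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in self.codes:
            if code not in PATHOGENIC_CODES and code not in BENIGN_CODES:
                raise AcmgError(
                    f"unknown ACMG code {code!r}; valid codes: "
                    f"{', '.join(sorted(PATHOGENIC_CODES | BENIGN_CODES))}"
                )
        for code in self.overrides:
            if code not in self.codes:
                raise AcmgError(f"strength override for absent code {code!r}")

    def strength_counts(self) -> dict[Strength, int]:
        counts = {s: 0 for s in Strength}
        for code in self.codes:
            if code in BENIGN_CODES:
                continue  # excluded from pathogenic-side combining
            counts[self.overrides.get(code, _default_strength(code))] += 1
        return counts


@dataclass(frozen=True)
class Classification:
    value: Verdict
    rule_fired: str


_CODE_SPLIT_RE = re.compile(r"[;,]")


def parse_codes(cell: str) -> EvidenceSet:
    """Parse a delimited code list (``"PM2; PVS1, pp4"``): separators are
    ``;`` or ``,``, whitespace ignored, case-insensitive. A trailing
    strength tag (``PVS1_Moderate``) becomes an override."""
    codes: set[str] = set()
    overrides: dict[str, Strength] = {}
    for token in _CODE_SPLIT_RE.split(cell or ""):
        token = token.strip()
        if not token:
            continue
        if "_" in token:
            code_part, strength_part = token.split("_", 1)
            code = code_part.upper()
            try:
                overrides[code] = Strength[strength_part.upper().replace("-", "_")]
            except KeyError:
                raise AcmgError(f"unknown strength tag in {token!r}") from None
        else:
            code = token.upper()
        codes.add(code)
    return EvidenceSet(frozenset(codes), overrides)


# Combining rules of the 2015 guideline, written as minimal requirement
# tuples (very_strong, strong, moderate, supporting); a clause fires when
# every component of the evidence meets or exceeds it.
_PATHOGENIC_CLAUSES: tuple[tuple[str, tuple[int, int, int, int]], ...] = (
    ("P-Ia: 1 VS + >=1 S", (1, 1, 0, 0)),
    ("P-Ib: 1 VS + >=2 M", (1, 0, 2, 0)),
    ("P-Ic: 1 VS + 1 M + 1 P", (1, 0, 1, 1)),
    ("P-Id: 1 VS + >=2 P", (1, 0, 0, 2)),
    ("P-II: >=2 S", (0, 2, 0, 0)),
    ("P-IIIa: 1 S + >=3 M", (0, 1, 3, 0)),
    ("P-IIIb: 1 S + 2 M + >=2 P", (0, 1, 2, 2)),
    ("P-IIIc: 1 S + 1 M + >=4 P", (0, 1, 1, 4)),
)
_LIKELY_CLAUSES: tuple[tuple[str, tuple[int, int, int, int]], ...] = (
    ("LP-I: 1 VS + 1 M", (1, 0, 1, 0)),
    ("LP-II: 1 S + 1 M", (0, 1, 1, 0)),
    ("LP-III: 1 S + >=2 P", (0, 1, 0, 2)),
    ("LP-IV: >=3 M", (0, 0, 3, 0)),
    ("LP-V: 2 M + >=2 P", (0, 0, 2, 2)),
    ("LP-VI: 1 M + >=4 P", (0, 0, 1, 4)),
)


def _meets(counts: dict[Strength, int], req: tuple[int, int, int, int]) -> bool:
    return (
        counts[Strength.VERY_STRONG] >= req[0]
        and counts[Strength.STRONG] >= req[1]
        and counts[Strength.MODERATE] >= req[2]
        and counts[Strength.SUPPORTING] >= req[3]
    )


def combine(evidence: EvidenceSet | str | Iterable[str]) -> Classification:
    """Combine pathogenic-side evidence into a classification.

    Each clause is a minimal count requirement over the four strength
    levels; the highest class with a satisfied clause wins, so adding
    evidence can never lower the verdict.
    """
    if isinstance(evidence, str):
        evidence = parse_codes(evidence)
    elif not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(frozenset(c.upper() for c in evidence))
    counts = evidence.strength_counts()
    for name, req in _PATHOGENIC_CLAUSES:
        if _meets(counts, req):
            return Classification(Verdict.PATHOGENIC, name)
    for name, req in _LIKELY_CLAUSES:
        if _meets(counts, req):
            return Classification(Verdict.LIKELY_PATHOGENIC, name)
    return Classification(Verdict.VUS, "no combining rule satisfied")


def classify_table(rows: pd.DataFrame, codes_column: str = "acmg_codes") -> pd.DataFrame:
    """Classify every row of a variant table that carries evidence codes.

    Rows whose code cell is empty (or a bare database ID with no codes)
    are skipped. The result frame has one row per coded input row with
    columns ``cdna``, ``codes``, ``classification``, ``rule_fired`` and a
    boolean ``vus_flag`` marking rows that combine to VUS — an internal
    inconsistency for a table that claims to contain only P/LP variants,
    reported rather than raised.
    """
    records = []
    for row in rows.itertuples():
        cell = getattr(row, codes_column, None)
        if cell is None or (isinstance(cell, float) and pd.isna(cell)):
            continue
        cell = str(cell).strip()
        if not cell or cell == ".":
            continue
        ev = parse_codes(cell)
        if not ev.codes:
            continue
        cls = combine(ev)
        records.append(
            {
                "cdna": getattr(row, "cdna", ""),
                "codes": ";".join(sorted(ev.codes)),
                "classification": cls.value.value,
                "rule_fired": cls.rule_fired,
                "vus_flag": cls.value is Verdict.VUS,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["cdna", "codes", "classification", "rule_fired", "vus_flag"]
    )
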