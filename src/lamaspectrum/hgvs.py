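"""Parsing of HGVS-style coding-DNA and protein descriptions, and
consequence classification.

The grammar covers the dialect found in clinical variant tables for a
single transcript: ``c.`` descriptions with optional intronic offsets
(``c.8245-2A>G``), small deletions/duplications/insertions/delins, and
exon-level MLPA events written as ``del ex 57,58`` or ``ex 40 del``.
Protein descriptions use 3-letter amino-acid codes (``p.(Arg1706Ter)``,
``p.(Asp2513IlefsTer34)``, ``p.?``).

Genomic (``g.``) and RNA (``r.``) descriptions, reference-sequence
validation and 3'-normalisation are out of scope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "HgvsParseError",
    "CdnaKind",
    "ProteinKind",
    "Consequence",
    "CdnaEvent",
    "ProteinEvent",
    "VariantDescription",
    "parse_cdna",
    "parse_protein",
    "format_cdna",
    "format_protein",
    "net_length_change",
    "classify_consequence",
    "describe_variant",
]


class HgvsParseError(ValueError):
    """Raised when a variant description cannot be parsed.

    The message names the offending token so table readers can report
    file/line context around it.
    """


class CdnaKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    DELINS = "delins"
    EXON_LEVEL_DEL = "exon_level_del"
    EXON_LEVEL_DUP = "exon_level_dup"


class ProteinKind(str, enum.Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    DELINS = "delins"
    UNKNOWN = "unknown"


class Consequence(str, enum.Enum):
    """The five consequence classes of a LoF-dominated recessive spectrum,
    plus an in-frame fallback."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    GROSS_DEL_DUP = "gross_del_dup"
    MISSENSE = "missense"
    INFRAME_OTHER = "inframe_other"


# 3-letter amino-acid codes (20 standard + Ter for stop).
AA3 = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser "
    "Thr Trp Tyr Val Ter".split()
)

_NT = frozenset("ACGT")


@dataclass(frozen=True)
class CdnaEvent:
    """A parsed coding-DNA event.

    Positions are HGVS coding-DNA coordinates (1-based, inclusive);
    intronic positions are (anchor, offset) pairs where the anchor is the
    nearest exonic base and the offset is the signed distance into the
    intron. Single-position events have ``end_* == start_*``.
    """

    kind: CdnaKind
    start_anchor: int = 0
    start_offset: int = 0
    end_anchor: int = 0
    end_offset: int = 0
    ref_seq: str = ""
    alt_seq: str = ""
    exon_span: tuple[int, ...] = ()
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.kind in (CdnaKind.EXON_LEVEL_DEL, CdnaKind.EXON_LEVEL_DUP):
            if not self.exon_span:
                raise ValueError("exon-level event requires a non-empty exon span")
        else:
            if self.exon_span:
                raise ValueError("exon_span only valid for exon-level events")
            if (self.start_anchor, self.start_offset) > (self.end_anchor, self.end_offset):
                raise ValueError(
                    f"start {(self.start_anchor, self.start_offset)} after "
                    f"end {(self.end_anchor, self.end_offset)}"
                )
        for seq in (self.ref_seq, self.alt_seq):
            bad = set(seq) - _NT
            if bad:
                raise ValueError(f"non-ACGT base(s) {sorted(bad)} in {seq!r}")

    @property
    def is_exon_level(self) -> bool:
        return self.kind in (CdnaKind.EXON_LEVEL_DEL, CdnaKind.EXON_LEVEL_DUP)

    @property
    def is_intronic(self) -> bool:
        """True if either endpoint carries a nonzero intronic offset."""
        return not self.is_exon_level and (self.start_offset != 0 or self.end_offset != 0)

    def canonical(self) -> str:
        return format_cdna(self)


@dataclass(frozen=True)
class ProteinEvent:
    """A parsed protein-level description (3-letter amino-acid codes)."""

    kind: ProteinKind
    ref_aa: str = ""
    position: int = 0
    alt_aa: str = ""
    ter_offset: int | None = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.ter_offset is not None and self.kind is not ProteinKind.FRAMESHIFT:
            raise ValueError("ter_offset only valid for frameshift events")

    def canonical(self) -> str:
        return format_protein(self)


@dataclass(frozen=True)
class VariantDescription:
    """A variant as described in a clinical table: paired cDNA and protein
    events, the table's region label, and the derived consequence class."""

    cdna: CdnaEvent
    protein: ProteinEvent
    region_label: str = ""
    consequence: Consequence = field(init=False)
    ambiguous_class: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "consequence", classify_consequence(self.cdna, self.protein))
        object.__setattr__(self, "ambiguous_class", _is_ambiguous(self.cdna, self.protein))

    @property
    def key(self) -> str:
        """Canonical cDNA string; the identity of a variant in a spectrum."""
        return self.cdna.canonical()


# --------------------------------------------------------------------------
# cDNA grammar
# --------------------------------------------------------------------------

_POS_RE = re.compile(r"(\d+)([+-]\d+)?")
_EXON_LEVEL_RE = re.compile(
    r"^(?:(del|dup)\s*ex\s*([\d\s,]+)|ex\s*([\d\s,]+?)\s*(del|dup))$", re.IGNORECASE
)


def _parse_position(text: str) -> tuple[int, int]:
    m = _POS_RE.fullmatch(text)
    if not m:
        raise HgvsParseError(f"malformed cDNA position {text!r}")
    return int(m.group(1)), int(m.group(2) or 0)


def _check_bases(seq: str, raw: str) -> str:
    bad = set(seq.upper()) - _NT
    if bad:
        raise HgvsParseError(f"invalid base(s) {''.join(sorted(bad))!r} in {raw!r}")
    return seq.upper()


def parse_cdna(text: str) -> CdnaEvent:
    """Parse an HGVS-like coding-DNA description.

    Accepts a case-insensitive ``c.`` prefix, intronic offsets, ranges,
    the event keywords ``>`` (substitution), ``del``, ``dup``, ``ins``,
    ``delins`` (with or without explicit sequences), and exon-level MLPA
    tokens (``del ex 14``, ``ex 40 del``, ``del ex 57,58``).

    Raises :class:`HgvsParseError` on malformed positions, unknown event
    keywords or non-ACGT bases.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError("empty cDNA description")
    raw = text
    s = text.strip()

    m = _EXON_LEVEL_RE.match(s)
    if m:
        kw = (m.group(1) or m.group(4)).lower()
        nums = m.group(2) or m.group(3)
        try:
            span = tuple(sorted(int(tok) for tok in re.split(r"[,\s]+", nums.strip()) if tok))
        except ValueError:
            raise HgvsParseError(f"malformed exon list {nums!r} in {raw!r}") from None
        if not span or any(n < 1 for n in span):
            raise HgvsParseError(f"malformed exon list {nums!r} in {raw!r}")
        kind = CdnaKind.EXON_LEVEL_DEL if kw == "del" else CdnaKind.EXON_LEVEL_DUP
        return CdnaEvent(kind=kind, exon_span=span, raw=raw)

    if not s[:2].lower() == "c.":
        raise HgvsParseError(f"expected 'c.' prefix or exon-level token in {raw!r}")
    body = s[2:].replace(" ", "")
    if not body:
        raise HgvsParseError(f"empty cDNA body in {raw!r}")

    # position or range before the first event keyword / substitution base
    m = re.match(r"^(\d+[+-]?\d*)(?:_(\d+[+-]?\d*))?(.*)$", body)
    if not m:
        raise HgvsParseError(f"malformed cDNA position in {raw!r}")
    start_a, start_o = _parse_position(m.group(1))
    if m.group(2) is not None:
        end_a, end_o = _parse_position(m.group(2))
    else:
        end_a, end_o = start_a, start_o
    if (start_a, start_o) > (end_a, end_o):
        raise HgvsParseError(f"inverted range in {raw!r}")
    rest = m.group(3)
    if not rest:
        raise HgvsParseError(f"missing event keyword in {raw!r}")

    common = dict(
        start_anchor=start_a, start_offset=start_o, end_anchor=end_a, end_offset=end_o, raw=raw
    )

    sub = re.fullmatch(r"([A-Za-z])>([A-Za-z])", rest)
    if sub:
        if (start_a, start_o) != (end_a, end_o):
            raise HgvsParseError(f"substitution over a range in {raw!r}")
        ref = _check_bases(sub.group(1), raw)
        alt = _check_bases(sub.group(2), raw)
        return CdnaEvent(kind=CdnaKind.SUBSTITUTION, ref_seq=ref, alt_seq=alt, **common)

    delins = re.fullmatch(r"del([A-Za-z]*)ins([A-Za-z]+)", rest, re.IGNORECASE)
    if delins:
        ref = _check_bases(delins.group(1), raw)
        alt = _check_bases(delins.group(2), raw)
        return CdnaEvent(kind=CdnaKind.DELINS, ref_seq=ref, alt_seq=alt, **common)

    simple = re.fullmatch(r"(del|dup|ins)([A-Za-z]*)", rest, re.IGNORECASE)
    if simple:
        kw = simple.group(1).lower()
        seq = _check_bases(simple.group(2), raw)
        kind = {"del": CdnaKind.DELETION, "dup": CdnaKind.DUPLICATION, "ins": CdnaKind.INSERTION}[kw]
        if kind is CdnaKind.INSERTION:
            if not seq:
                raise HgvsParseError(f"insertion without inserted sequence in {raw!r}")
            return CdnaEvent(kind=kind, alt_seq=seq, **common)
        return CdnaEvent(kind=kind, ref_seq=seq, **common)

    raise HgvsParseError(f"unknown event keyword {rest!r} in {raw!r}")


def _format_position(anchor: int, offset: int) -> str:
    return f"{anchor}{offset:+d}" if offset else str(anchor)


def format_cdna(e: CdnaEvent) -> str:
    """Canonical HGVS-style string for a cDNA event (lowercase ``c.``)."""
    if e.kind is CdnaKind.EXON_LEVEL_DEL:
        return "del ex " + ",".join(str(n) for n in e.exon_span)
    if e.kind is CdnaKind.EXON_LEVEL_DUP:
        return "dup ex " + ",".join(str(n) for n in e.exon_span)
    start = _format_position(e.start_anchor, e.start_offset)
    end = _format_position(e.end_anchor, e.end_offset)
    pos = start if (e.start_anchor, e.start_offset) == (e.end_anchor, e.end_offset) else f"{start}_{end}"
    if e.kind is CdnaKind.SUBSTITUTION:
        return f"c.{pos}{e.ref_seq}>{e.alt_seq}"
    if e.kind is CdnaKind.DELETION:
        return f"c.{pos}del{e.ref_seq}"
    if e.kind is CdnaKind.DUPLICATION:
        return f"c.{pos}dup{e.ref_seq}"
    if e.kind is CdnaKind.INSERTION:
        return f"c.{pos}ins{e.alt_seq}"
    return f"c.{pos}del{e.ref_seq}ins{e.alt_seq}"


# --------------------------------------------------------------------------
# protein grammar
# --------------------------------------------------------------------------

_PROT_CORE_RE = re.compile(
    r"^([A-Z][a-z]{2})(\d+)((?:[A-Z][a-z]{2})+)(?:fsTer(\d+))?$|"
    r"^([A-Z][a-z]{2})(\d+)delins((?:[A-Z][a-z]{2})+)$"
)


def _split_aa(seq: str, raw: str) -> list[str]:
    codes = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for code in codes:
        if code not in AA3:
            raise HgvsParseError(f"unknown amino-acid code {code!r} in {raw!r}")
    return codes


def parse_protein(text: str) -> ProteinEvent:
    """Parse an HGVS-like protein description.

    ``p.?`` maps to the *unknown* kind. Surrounding parentheses and stray
    internal whitespace are tolerated (``p. (Lys1556GlufsTer3)``).
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError("empty protein description")
    raw = text
    s = re.sub(r"\s+", "", text)
    if not s[:2].lower() == "p.":
        raise HgvsParseError(f"expected 'p.' prefix in {raw!r}")
    body = s[2:].strip("()")
    if body == "?":
        return ProteinEvent(kind=ProteinKind.UNKNOWN, raw=raw)

    m = _PROT_CORE_RE.match(body)
    if not m:
        raise HgvsParseError(f"malformed protein description {raw!r}")

    if m.group(5):  # explicit delins form: Ref123delinsXxxYyy
        ref = _split_aa(m.group(5), raw)[0]
        _split_aa(m.group(7), raw)
        return ProteinEvent(
            kind=ProteinKind.DELINS, ref_aa=ref, position=int(m.group(6)), alt_aa=m.group(7), raw=raw
        )

    ref = _split_aa(m.group(1), raw)[0]
    if ref == "Ter":
        raise HgvsParseError(f"reference residue cannot be Ter in {raw!r}")
    pos = int(m.group(2))
    alt_codes = _split_aa(m.group(3), raw)
    fs = m.group(4)
    if fs is not None:
        if len(alt_codes) != 1 or alt_codes[0] == "Ter":
            raise HgvsParseError(f"malformed frameshift description {raw!r}")
        return ProteinEvent(
            kind=ProteinKind.FRAMESHIFT,
            ref_aa=ref,
            position=pos,
            alt_aa=alt_codes[0],
            ter_offset=int(fs),
            raw=raw,
        )
    if len(alt_codes) == 1:
        kind = ProteinKind.STOP_GAIN if alt_codes[0] == "Ter" else ProteinKind.MISSENSE
        return ProteinEvent(kind=kind, ref_aa=ref, position=pos, alt_aa=alt_codes[0], raw=raw)
    # multi-residue replacement without the delins keyword, e.g. Ser2567delinsArgCysProTer
    # is handled above; anything else multi-residue is a delins spelled inline
    return ProteinEvent(kind=ProteinKind.DELINS, ref_aa=ref, position=pos, alt_aa=m.group(3), raw=raw)


def format_protein(e: ProteinEvent) -> str:
    """Canonical protein string (``p.`` prefix, parenthesised prediction)."""
    if e.kind is ProteinKind.UNKNOWN:
        return "p.?"
    if e.kind is ProteinKind.FRAMESHIFT:
        return f"p.({e.ref_aa}{e.position}{e.alt_aa}fsTer{e.ter_offset})"
    if e.kind is ProteinKind.DELINS and "delins" in e.raw.replace(" ", ""):
        return f"p.({e.ref_aa}{e.position}delins{e.alt_aa})"
    return f"p.({e.ref_aa}{e.position}{e.alt_aa})"


# --------------------------------------------------------------------------
# length arithmetic and consequence classification
# --------------------------------------------------------------------------


def _span_length(e: CdnaEvent) -> int:
    """Number of reference bases covered by the event's position range."""
    if e.start_anchor == e.end_anchor:
        return e.end_offset - e.start_offset + 1
    if e.start_offset == 0 and e.end_offset == 0:
        return e.end_anchor - e.start_anchor + 1
    raise HgvsParseError(
        f"cannot measure span crossing exon/intron boundary in {e.raw!r}"
    )


def net_length_change(e: CdnaEvent) -> int:
    """Signed change in sequence length caused by a small cDNA event.

    Substitutions return 0; deletions ``-span``; duplications ``+span``;
    insertions ``+len(alt)``; delins ``len(alt) - span``. Exon-level
    events have no base-pair span and are rejected.
    """
    if e.is_exon_level:
        raise HgvsParseError(f"net length change undefined for exon-level event {e.raw!r}")
    if e.kind is CdnaKind.SUBSTITUTION:
        return 0
    if e.kind is CdnaKind.INSERTION:
        return len(e.alt_seq)
    span = len(e.ref_seq) if e.ref_seq else _span_length(e)
    if e.ref_seq and (e.start_anchor, e.start_offset) != (e.end_anchor, e.end_offset):
        declared = _span_length(e)
        if declared != len(e.ref_seq):
            raise HgvsParseError(
                f"declared span ({declared}) disagrees with ref length "
                f"({len(e.ref_seq)}) in {e.raw!r}"
            )
    if e.kind is CdnaKind.DELETION:
        return -span
    if e.kind is CdnaKind.DUPLICATION:
        return +span
    return len(e.alt_seq) - span  # delins


def classify_consequence(cdna: CdnaEvent, protein: ProteinEvent) -> Consequence:
    """Assign one of the five spectrum classes by a fixed precedence ladder.

    Precedence (first match wins):

    1. exon-level deletion/duplication -> ``gross_del_dup``
    2. any nonzero intronic offset in the cDNA description -> ``splice``
    3. protein frameshift (``fsTerN``) -> ``frameshift``
    4. cDNA delins (small indel, non-frameshift protein) -> ``frameshift``
    5. protein stop gain -> ``nonsense``
    6. single amino-acid substitution -> ``missense``
    7. otherwise -> ``inframe_other``

    The ladder is deterministic and total: every parseable pair maps to
    exactly one class.
    """
    if cdna.is_exon_level:
        return Consequence.GROSS_DEL_DUP
    if cdna.is_intronic:
        return Consequence.SPLICE
    if protein.kind is ProteinKind.FRAMESHIFT:
        return Consequence.FRAMESHIFT
    if cdna.kind is CdnaKind.DELINS:
        return Consequence.FRAMESHIFT
    if protein.kind is ProteinKind.STOP_GAIN:
        return Consequence.NONSENSE
    if protein.kind is ProteinKind.MISSENSE:
        return Consequence.MISSENSE
    return Consequence.INFRAME_OTHER


def _is_ambiguous(cdna: CdnaEvent, protein: ProteinEvent) -> bool:
    """Flag in-frame stop-gain indels whose nonsense-vs-frameshift grouping
    is a labelling convention rather than a biological fact."""
    if cdna.is_exon_level or cdna.is_intronic:
        return False
    if cdna.kind not in (CdnaKind.DELINS, CdnaKind.INSERTION, CdnaKind.DUPLICATION):
        return False
    stops = protein.kind is ProteinKind.STOP_GAIN or (
        protein.kind is ProteinKind.DELINS and protein.alt_aa.endswith("Ter")
    )
    try:
        inframe = net_length_change(cdna) % 3 == 0
    except HgvsParseError:
        return False
    return stops and inframe


def describe_variant(cdna_text: str, protein_text: str, region_label: str = "") -> VariantDescription:
    """Parse both descriptions and classify; convenience wrapper."""
    return VariantDescription(
        cdna=parse_cdna(cdna_text), protein=parse_protein(protein_text), region_label=region_label
    )
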