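"""Table readers/writers, the packaged variant-table fixture, and the
pipeline orchestrator.

TSV dialect: tab-separated, UTF-8, mandatory header, ``.`` for missing
values. HGVS cells are stored verbatim in files and normalised only in
memory, so the packaged fixture stays diff-able against its published
source table (each record keeps its original row number in
``source_row``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

from . import acmg, spectrum as spectrum_mod
from .fisher import compare_frequencies
from .genemodel import GeneModel, crosscheck_labels
from .hgvs import HgvsParseError, describe_variant
from .prevalence import FounderInputs, bootstrap_ci, estimate

__all__ = [
    "TableFormatError",
    "STUDY_INPUTS",
    "load_fixture",
    "read_variant_table",
    "read_cohort",
    "read_gene_model",
    "AnalysisReport",
    "write_report",
    "run_pipeline",
]

NA = "."

# Built-in published study inputs: the founder variant's population counts
# (national frequency database and gnomAD v2.1.1 controls) and the cohort
# founder-allele counts used for the two prevalence estimates.
STUDY_INPUTS = {
    "founder_cdna": "c.7536del",
    "gdb_counts": (106, 241_524),
    "gnomad_counts": (5, 250_958),
    "founder_alleles": 27,
    "chromosomes_severe": 166,  # 2 x 83 severe-form cases
    "chromosomes_all": 180,  # 2 x 90 cases, both forms
}


class TableFormatError(ValueError):
    """Structured table-validation error naming file and line."""


def _require_columns(df: pd.DataFrame, required: set[str], path: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False, encoding="utf-8"
    )


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a variant table.

    Mandatory columns: ``region_label``, ``cdna``, ``protein``,
    ``allele_count``, ``acmg_codes``, ``db_id``. Every HGVS cell is parsed
    (errors carry the 1-based data line number); counts must be positive
    integers. Unknown columns are preserved.
    """
    df = _read_tsv(path)
    _require_columns(
        df, {"region_label", "cdna", "protein", "allele_count", "acmg_codes", "db_id"}, str(path)
    )
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            count = int(row.allele_count)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}, line {i}: allele_count {row.allele_count!r} is not an integer"
            ) from None
        if count < 1:
            raise TableFormatError(f"{path}, line {i}: allele_count must be >= 1, got {count}")
        try:
            describe_variant(row.cdna, row.protein)
        except HgvsParseError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
        codes = getattr(row, "acmg_codes", None)
        if isinstance(codes, str) and codes.strip():
            acmg.parse_codes(codes)  # raises AcmgError on bad tokens
    df["allele_count"] = df["allele_count"].astype(int)
    df["region_label"] = df["region_label"].fillna("")
    return df


def load_fixture() -> pd.DataFrame:
    """The packaged 75-variant national-cohort table (90 unrelated
    patients, 180 chromosomes)."""
    with resources.as_file(
        resources.files("lamaspectrum.data") / "table1_variants.tsv"
    ) as p:
        return read_variant_table(p)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a genotype table: ``patient_id``, ``sex``, ``phenotype``,
    ``allele1_cdna``, ``allele2_cdna``, ``zygosity``."""
    df = _read_tsv(path)
    _require_columns(
        df,
        {"patient_id", "sex", "phenotype", "allele1_cdna", "allele2_cdna", "zygosity"},
        str(path),
    )
    for i, row in enumerate(df.itertuples(), start=1):
        zyg = (row.zygosity or "").strip().lower()
        if zyg not in ("hom", "het", "unknown", ""):
            raise TableFormatError(
                f"{path}, line {i}: zygosity must be hom|het|unknown, got {row.zygosity!r}"
            )
        for cell in (row.allele1_cdna, row.allele2_cdna):
            if isinstance(cell, str) and cell.strip():
                try:
                    from .hgvs import parse_cdna

                    parse_cdna(cell)
                except HgvsParseError as exc:
                    raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return df


def read_gene_model(path: str | Path, transcript_id: str = "custom") -> GeneModel:
    """Read an exon-boundary table (``exon_index``, ``cdna_start``,
    ``cdna_end``) into a :class:`GeneModel`."""
    df = _read_tsv(path)
    _require_columns(df, {"exon_index", "cdna_start", "cdna_end"}, str(path))
    try:
        return GeneModel.from_frame(df.astype({"exon_index": int, "cdna_start": int, "cdna_end": int}),
                                    transcript_id=transcript_id)
    except ValueError as exc:
        raise TableFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# analysis report
# --------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Full pipeline output; serialises losslessly to JSON. Fractions are
    stored at full precision — display rounding happens only in renderers."""

    spectrum: dict[str, Any] = field(default_factory=dict)
    type_distribution: dict[str, Any] = field(default_factory=dict)
    top_variants: list[dict[str, Any]] = field(default_factory=list)
    acmg: dict[str, Any] = field(default_factory=dict)
    prevalence: dict[str, Any] = field(default_factory=dict)
    comparisons: list[dict[str, Any]] = field(default_factory=list)
    cohort: dict[str, Any] = field(default_factory=dict)
    gene_model: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: AnalysisReport, path: str | Path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(report.to_json() + "\n", encoding="utf-8")
    elif fmt in ("tsv", "text"):
        lines = []
        lines.append("# type distribution (distinct variants)")
        for k, v in report.type_distribution.get("counts", {}).items():
            frac = report.type_distribution.get("fractions", {}).get(k, 0.0)
            lines.append(f"{k}\t{v}\t{100 * frac:.1f}%")
        lines.append("# recurrent variants")
        for tv in report.top_variants:
            lines.append(f"{tv['cdna']}\t{tv['count']}\t{100 * tv['share']:.2f}%")
        for name, est in report.prevalence.items():
            lines.append(f"# prevalence [{name}]")
            lines.append(f"one_in\t{est['one_in_display']}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def run_pipeline(
    variant_table: str | Path | pd.DataFrame,
    cohort: str | Path | pd.DataFrame | None = None,
    gene_model: str | Path | GeneModel | None = None,
    n_patients: int | None = 90,
    founder_cdna: str | None = None,
    min_recurrent: int = 9,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AnalysisReport:
    """Run all stages on a variant table (plus optional cohort and gene
    model); stages with missing inputs are skipped.

    Stage order: spectrum -> type distribution -> recurrent variants ->
    ACMG classification -> founder prevalence (built-in published
    population counts unless the founder variant is absent from the
    table) -> population-frequency comparison.
    """
    report = AnalysisReport()
    provenance: dict[str, Any] = {"seed": seed}
    if isinstance(variant_table, (str, Path)):
        provenance["variant_table_sha256"] = _sha256(variant_table)
        rows = read_variant_table(variant_table)
    else:
        rows = variant_table

    spec = spectrum_mod.build_spectrum(rows, n_patients=n_patients)
    counts, fractions = spectrum_mod.type_distribution(spec)
    top, cumulative = spectrum_mod.top_variants(spec, min_count=min_recurrent)
    report.spectrum = {
        "n_distinct_variants": spec.n_distinct,
        "total_alleles": spec.total_alleles,
        "n_patients": spec.n_patients,
    }
    report.type_distribution = {
        "counts": {k.value: v for k, v in counts.items()},
        "fractions": {k.value: v for k, v in fractions.items()},
        "ambiguous_class": sorted(v.key for v, _ in spec.entries if v.ambiguous_class),
    }
    report.top_variants = [
        {"cdna": v.key, "count": c, "share": share} for v, c, share in top
    ]
    report.spectrum["cumulative_top_share"] = cumulative

    classified = acmg.classify_table(rows)
    if len(classified):
        report.acmg = {
            "n_classified": int(len(classified)),
            "n_pathogenic": int((classified["classification"] == "pathogenic").sum()),
            "n_likely_pathogenic": int(
                (classified["classification"] == "likely_pathogenic").sum()
            ),
            "vus_flagged": classified.loc[classified["vus_flag"], "cdna"].tolist(),
        }

    founder = founder_cdna or STUDY_INPUTS["founder_cdna"]
    founder_count = spec.count_of(founder)
    if founder_count is not None:
        alt, total = STUDY_INPUTS["gdb_counts"]
        report.prevalence = {}
        for name, A in (
            ("severe_form", STUDY_INPUTS["chromosomes_severe"]),
            ("all_forms", spec.total_alleles),
        ):
            inputs = FounderInputs.from_counts(alt, total, founder_count, A)
            est = bootstrap_ci(inputs, n_boot=n_boot, seed=seed) if n_boot else estimate(inputs)
            report.prevalence[name] = {
                "founder": founder,
                "a_founder": founder_count,
                "A_total": A,
                "q_pop": inputs.q_pop,
                **{
                    k: getattr(est, k)
                    for k in (
                        "f", "Q", "prevalence", "one_in", "one_in_display",
                        "per_million", "carrier_freq", "ci", "ci_level", "n_boot",
                    )
                },
            }
        cmp_ = compare_frequencies(
            STUDY_INPUTS["gdb_counts"], STUDY_INPUTS["gnomad_counts"],
            labels=("national_db", "gnomad_controls"),
        )
        report.comparisons = [
            {
                "variant": founder,
                "labels": list(cmp_["table"].labels),
                "freq_1": cmp_["freq_1"],
                "freq_2": cmp_["freq_2"],
                "table": [cmp_["table"].a, cmp_["table"].b, cmp_["table"].c, cmp_["table"].d],
                "p_two_sided": cmp_["result"].p_two_sided,
                "odds_ratio": cmp_["result"].odds_ratio,
            }
        ]

    if cohort is not None:
        if isinstance(cohort, (str, Path)):
            provenance["cohort_sha256"] = _sha256(cohort)
            cohort = read_cohort(cohort)
        report.cohort = spectrum_mod.summarize_cohort(cohort)

    if gene_model is not None:
        if isinstance(gene_model, (str, Path)):
            provenance["gene_model_sha256"] = _sha256(gene_model)
            gene_model = read_gene_model(gene_model)
        variants = [
            describe_variant(r.cdna, r.protein, r.region_label) for r in rows.itertuples()
        ]
        mismatches = crosscheck_labels(gene_model, variants)
        report.gene_model = {
            "transcript_id": gene_model.transcript_id,
            "n_exons": gene_model.n_exons,
            "label_mismatches": [
                {"cdna": c, "stated": s, "computed": comp} for c, s, comp in mismatches
            ],
        }

    report.provenance = provenance
    return report
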