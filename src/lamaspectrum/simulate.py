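"""Synthetic biallelic recessive cohorts with a founder allele.

The generator emulates the statistical structure the analysis assumes: a
pool of distinct pathogenic variants on a toy transcript, one designated
founder allele carried by a set fraction ``f`` of patient chromosomes,
patients carrying two pathogenic chromosomes (identical-by-descent with a
configurable consanguinity probability), and a population sample in which
the founder allele is seen at frequency ``true_Q * f``.

Defaults mirror the cohort the pipeline was built around: 90 unrelated
patients (180 chromosomes), a 75-variant pool mixing
nonsense/frameshift/splice/gross-deletion/missense classes at
0.400/0.293/0.214/0.053/0.040, founder share f = 0.15, total pathogenic
allele frequency Q = 0.0029 and a population sample of 241,524
chromosomes.

All randomness flows through one ``numpy`` generator seeded from the
config, so every artefact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hgvs import Consequence, VariantDescription, describe_variant

__all__ = ["SimulationConfig", "VariantPool", "generate_variant_pool",
           "generate_cohort", "generate_population_counts"]

_DEFAULT_MIXTURE = {
    Consequence.NONSENSE: 0.400,
    Consequence.FRAMESHIFT: 0.293,
    Consequence.SPLICE: 0.214,
    Consequence.GROSS_DEL_DUP: 0.053,
    Consequence.MISSENSE: 0.040,
}

_AA = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
       "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val"]
_NT = ["A", "C", "G", "T"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_patients: int = 90
    class_mixture: dict[Consequence, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    founder_share_f: float = 0.15
    n_pool_variants: int = 75
    true_Q: float = 0.0029
    pop_sample_size: int = 241_524
    consanguinity_rate: float = 0.05
    p_female: float = 43 / 90
    p_severe: float = 83 / 90
    n_exons: int = 65
    exon_length: int = 140
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_pool_variants < 1:
            raise ValueError("n_patients and n_pool_variants must be >= 1")
        if not 0.0 < self.founder_share_f <= 1.0:
            raise ValueError("founder_share_f must be in (0, 1]")
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if not 0.0 <= self.true_Q <= 1.0:
            raise ValueError("true_Q must be in [0, 1]")
        if self.pop_sample_size < 1:
            raise ValueError("pop_sample_size must be >= 1")

    @property
    def transcript_length(self) -> int:
        return self.n_exons * self.exon_length

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass(frozen=True)
class VariantPool:
    variants: tuple[VariantDescription, ...]
    founder_key: str

    @property
    def founder(self) -> VariantDescription:
        return next(v for v in self.variants if v.key == self.founder_key)


def _aa_at(rng: np.random.Generator, exclude: str | None = None) -> str:
    while True:
        aa = _AA[rng.integers(len(_AA))]
        if aa != exclude:
            return aa


def _make_variant(
    cls: Consequence, pos: int, exon: int, cfg: SimulationConfig, rng: np.random.Generator
) -> VariantDescription:
    """One synthetic variant of the requested class at a reserved cDNA
    position (or exon, for gross deletions)."""
    aa_pos = max(1, (pos + 2) // 3)
    ref_aa = _aa_at(rng)
    if cls is Consequence.NONSENSE:
        ref, alt = rng.choice(_NT, size=2, replace=False)
        return describe_variant(f"c.{pos}{ref}>{alt}", f"p.({ref_aa}{aa_pos}Ter)")
    if cls is Consequence.FRAMESHIFT:
        ter = int(rng.integers(2, 60))
        return describe_variant(
            f"c.{pos}del", f"p.({ref_aa}{aa_pos}{_aa_at(rng, ref_aa)}fsTer{ter})"
        )
    if cls is Consequence.SPLICE:
        # anchor at a donor (exon end, +offset) or acceptor (exon start, -offset)
        donor = bool(rng.integers(2)) and exon < cfg.n_exons
        ref, alt = rng.choice(_NT, size=2, replace=False)
        if donor or exon == 1:
            anchor = exon * cfg.exon_length
            offset = int(rng.integers(1, 6))
        else:
            anchor = (exon - 1) * cfg.exon_length + 1
            offset = -int(rng.integers(1, 6))
        return describe_variant(f"c.{anchor}{offset:+d}{ref}>{alt}", "p.?")
    if cls is Consequence.GROSS_DEL_DUP:
        return describe_variant(f"del ex {exon}", "p.?")
    if cls is Consequence.MISSENSE:
        ref, alt = rng.choice(_NT, size=2, replace=False)
        return describe_variant(
            f"c.{pos}{ref}>{alt}", f"p.({ref_aa}{aa_pos}{_aa_at(rng, ref_aa)})"
        )
    raise ValueError(f"cannot synthesise class {cls}")


def generate_variant_pool(cfg: SimulationConfig) -> VariantPool:
    """Draw the distinct-variant pool from the class mixture.

    The first pool slot is the designated founder, always a single-base
    frameshift deletion (the archetypal founder allele). Every generated
    string round-trips through the HGVS grammar; cDNA keys are unique by
    construction (positions and exons are sampled without replacement).
    """
    rng = cfg.rng(stream=1)
    classes = list(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in classes])
    drawn = rng.choice(len(classes), size=cfg.n_pool_variants - 1, p=probs)

    # reserve unique cDNA positions (splice sites live near boundaries and
    # get unique anchors through unique exon draws below)
    n_pos = cfg.n_pool_variants
    positions = rng.choice(
        np.arange(2, cfg.transcript_length - 1), size=n_pos, replace=False
    )
    exons = rng.permutation(np.arange(1, cfg.n_exons + 1))

    variants: list[VariantDescription] = []
    seen: set[str] = set()
    founder = _make_variant(
        Consequence.FRAMESHIFT, int(positions[0]), int(exons[0]), cfg, rng
    )
    variants.append(founder)
    seen.add(founder.key)
    slot = 1
    for idx in drawn:
        cls = classes[int(idx)]
        for _ in range(1000):
            v = _make_variant(cls, int(positions[slot % n_pos]), int(exons[slot % cfg.n_exons]), cfg, rng)
            slot += 1
            if v.key not in seen:
                break
        else:  # pragma: no cover - would need a saturated toy transcript
            raise RuntimeError("could not draw a unique variant; enlarge the transcript")
        seen.add(v.key)
        variants.append(v)
    return VariantPool(tuple(variants), founder.key)


def _draw_allele(pool: VariantPool, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """One patient chromosome: founder with probability f, else uniform
    over the non-founder pool (so the founder's marginal share is exactly f)."""
    if rng.random() < cfg.founder_share_f or len(pool.variants) == 1:
        return pool.founder_key
    others = len(pool.variants) - 1
    return pool.variants[1 + int(rng.integers(others))].key


def generate_cohort(
    cfg: SimulationConfig, pool: VariantPool | None = None
) -> tuple[pd.DataFrame, dict]:
    """Genotype table for ``n_patients`` biallelic patients plus the
    ground truth used to generate it.

    With probability ``consanguinity_rate`` a patient is homozygous by
    descent (one allele drawn, then duplicated); otherwise the two
    chromosomes are drawn independently. Either way each chromosome is
    the founder allele with probability ``f``.
    """
    if pool is None:
        pool = generate_variant_pool(cfg)
    rng = cfg.rng(stream=2)
    records = []
    counts: dict[str, int] = {}
    for i in range(1, cfg.n_patients + 1):
        if rng.random() < cfg.consanguinity_rate:
            a1 = a2 = _draw_allele(pool, cfg, rng)
        else:
            a1, a2 = _draw_allele(pool, cfg, rng), _draw_allele(pool, cfg, rng)
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
        records.append(
            {
                "patient_id": f"P{i:03d}",
                "sex": "F" if rng.random() < cfg.p_female else "M",
                "phenotype": "MDC1A" if rng.random() < cfg.p_severe else "LGMD",
                "allele1_cdna": a1,
                "allele2_cdna": a2,
                "zygosity": "hom" if a1 == a2 else "het",
            }
        )
    table = pd.DataFrame.from_records(records)
    truth = {
        "founder_key": pool.founder_key,
        "founder_share_f": cfg.founder_share_f,
        "true_Q": cfg.true_Q,
        "founder_allele_count": counts.get(pool.founder_key, 0),
        "total_alleles": 2 * cfg.n_patients,
        "allele_counts": counts,
        "seed": cfg.seed,
    }
    return table, truth


def generate_population_counts(cfg: SimulationConfig) -> tuple[int, int]:
    """Founder-allele count in a population sample: the founder's
    population frequency is ``true_Q * f``, so
    ``alt ~ Binomial(pop_sample_size, true_Q * f)``."""
    rng = cfg.rng(stream=3)
    p = cfg.true_Q * cfg.founder_share_f
    alt = int(rng.binomial(cfg.pop_sample_size, p))
    return alt, cfg.pop_sample_size
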