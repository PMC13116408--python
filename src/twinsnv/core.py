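"""Shared domain types and elementary genotype arithmetic.

Everything downstream (filtering, discordance detection, panel validation,
the simulator) is expressed in terms of the types defined here: a biallelic
SNV locus, the read support observed for it in one replicate, a diploid
genotype call, and the acceptance regime applied to calls.

Conventions:

* Coordinates are 1-based, as in VCF.
* Genotypes are collapsed to the unphased diploid biallelic ontology
  ``{hom_ref, het, hom_alt, missing}``; ``0/1``, ``1|0`` and ``0|1`` are all
  ``het``.
* Heterozygote balance (Hb) is the alternate-allele fraction
  ``alt / (ref + alt)``; reads supporting neither configured allele are
  excluded from the denominator.
* Homozygote noise is the fraction of reads *not* supporting the called
  allele, ``1 - called / dp``, with all reads in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "BASES",
    "Genotype",
    "Locus",
    "ReadSupport",
    "GenotypeCall",
    "FilterConfig",
    "UndefinedBalanceError",
    "UndefinedNoiseError",
    "NoiseNotApplicableError",
    "heterozygote_balance",
    "noise_fraction",
]

BASES = frozenset("ACGT")


class UndefinedBalanceError(ValueError):
    """Hb requested for a call with zero ref+alt supporting reads."""


class UndefinedNoiseError(ValueError):
    """Noise requested for a call with zero total depth."""


class NoiseNotApplicableError(ValueError):
    """Noise requested for a non-homozygous call."""


class Genotype(str, Enum):
    """Unphased diploid biallelic genotype."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def is_hom(self) -> bool:
        return self in (Genotype.HOM_REF, Genotype.HOM_ALT)

    def is_variant(self) -> bool:
        """True for genotypes that carry at least one alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True, slots=True)
class Locus:
    """A biallelic SNV position: 1-based coordinate plus its two alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele!r}")

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.pos}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True, slots=True)
class ReadSupport:
    """Per-replicate read counts at a locus.

    ``other_count`` holds reads supporting neither configured allele
    (miscalls, or the DP-minus-AD excess when ingesting VCF).
    """

    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def dp(self) -> int:
        """Total depth: ref + alt + other."""
        return self.ref_count + self.alt_count + self.other_count

    @property
    def allelic_depth(self) -> int:
        """Reads supporting either configured allele (the Hb denominator)."""
        return self.ref_count + self.alt_count


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One locus's diploid call in one replicate, with read support and GQ."""

    locus: Locus
    genotype: Genotype
    support: ReadSupport
    gq: int

    def __post_init__(self) -> None:
        if self.gq < 0:
            raise ValueError(f"gq must be non-negative, got {self.gq}")


def heterozygote_balance(support: ReadSupport) -> float:
    """Alternate-allele fraction ``alt / (ref + alt)``.

    Reads supporting other bases are excluded from the denominator.

    Raises
    ------
    UndefinedBalanceError
        If no read supports either configured allele; callers must treat the
        genotype as unacceptable.
    """
    allelic = support.allelic_depth
    if allelic == 0:
        raise UndefinedBalanceError("no reads support either allele; Hb undefined")
    return support.alt_count / allelic


def noise_fraction(call: GenotypeCall) -> float:
    """Fraction of reads not supporting the called homozygous allele.

    Defined only for ``hom_ref`` / ``hom_alt`` calls with positive depth.
    """
    if not call.genotype.is_hom():
        raise NoiseNotApplicableError(
            f"noise is defined for homozygous calls only, got {call.genotype.value}"
        )
    dp = call.support.dp
    if dp == 0:
        raise UndefinedNoiseError("zero depth; noise undefined")
    called = (
        call.support.ref_count
        if call.genotype is Genotype.HOM_REF
        else call.support.alt_count
    )
    return 1.0 - called / dp


@dataclass(frozen=True)
class FilterConfig:
    """One genotype acceptance regime.

    ``hb_low``/``hb_high`` bound the heterozygote balance of het calls
    (inclusive on both sides); ``None`` disables the Hb filter.
    ``noise_max`` is a strict upper bound on homozygote noise
    (accept iff noise < noise_max); ``None`` disables it.
    """

    dp_min: int
    gq_min: int
    hb_low: float | None = None
    hb_high: float | None = None
    noise_max: float | None = None
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if (self.hb_low is None) != (self.hb_high is None):
            raise ValueError("hb_low and hb_high must be set together")
        if self.hb_low is not None:
            if not (0.0 <= self.hb_low <= self.hb_high <= 1.0):
                raise ValueError(
                    f"require 0 <= hb_low <= hb_high <= 1, got "
                    f"[{self.hb_low}, {self.hb_high}]"
                )
        if self.noise_max is not None and not (0.0 <= self.noise_max <= 1.0):
            raise ValueError(f"noise_max must be in [0, 1], got {self.noise_max}")

    @property
    def has_hb_filter(self) -> bool:
        return self.hb_low is not None

    def with_hb(self, low: float | None, high: float | None) -> "FilterConfig":
        """Copy of this config with the Hb window replaced (None disables)."""
        return FilterConfig(
            dp_min=self.dp_min,
            gq_min=self.gq_min,
            hb_low=low,
            hb_high=high,
            noise_max=self.noise_max,
            biallelic_only=self.biallelic_only,
        )

    def to_dict(self) -> dict:
        return {
            "dp_min": self.dp_min,
            "gq_min": self.gq_min,
            "hb": None if self.hb_low is None else [self.hb_low, self.hb_high],
            "noise_max": self.noise_max,
            "biallelic_only": self.biallelic_only,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FilterConfig":
        hb = data.get("hb")
        return cls(
            dp_min=int(data["dp_min"]),
            gq_min=int(data["gq_min"]),
            hb_low=None if hb is None else float(hb[0]),
            hb_high=None if hb is None else float(hb[1]),
            noise_max=(
                None if data.get("noise_max") is None else float(data["noise_max"])
            ),
            biallelic_only=bool(data.get("biallelic_only", True)),
        )
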