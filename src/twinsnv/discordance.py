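"""Cross-sample genotype comparison, the Hb stringency sweep, and coverage.

The comparison domain is the set of loci with an accepted consensus genotype
in BOTH samples where at least one sample carries a variant (non-hom-ref)
genotype; hom-ref/hom-ref loci are vacuous and excluded.  The sweep re-runs
consensus building, domain construction and discordance detection for each
Hb window while holding dp/gq thresholds fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import FilterConfig, Genotype, Locus, ReadSupport
from .filtering import ConsensusGenotype, consensus_map
from .vcf_io import SampleCallSet

__all__ = [
    "DiscordantLocus",
    "SweepScheme",
    "SweepResult",
    "CoverageSummary",
    "ComparisonResult",
    "DEFAULT_SCHEMES",
    "comparison_domain",
    "find_discordances",
    "compare_samples",
    "hb_sweep",
    "coverage_summary",
    "read_depth_track",
]


@dataclass(frozen=True, slots=True)
class DiscordantLocus:
    """A locus whose trace and reference consensus genotypes differ."""

    locus: Locus
    trace_genotype: Genotype
    reference_genotype: Genotype
    pattern: str  # hom_vs_het | het_vs_hom | hom_vs_hom
    trace_support: tuple[ReadSupport, ...]
    trace_gq: tuple[int, ...]
    reference_support: tuple[ReadSupport, ...]
    reference_gq: tuple[int, ...]


@dataclass(frozen=True, slots=True)
class SweepScheme:
    """One Hb window in a stringency sweep; ``None`` bounds = no Hb filter."""

    label: str
    hb_low: float | None = None
    hb_high: float | None = None


#: The four windows evaluated in the stringency sweep, widest to narrowest.
DEFAULT_SCHEMES = (
    SweepScheme("none", None, None),
    SweepScheme("0.2:0.8", 0.2, 0.8),
    SweepScheme("0.4:0.6", 0.4, 0.6),
    SweepScheme("0.45:0.55", 0.45, 0.55),
)


@dataclass(frozen=True)
class SweepResult:
    """Retention / comparison / discordance counts for one Hb scheme."""

    scheme: SweepScheme
    retained_trace: int  # consensus genotypes in the trace sample
    retained_reference: int
    retained_combined: int  # loci with consensus in both samples
    compared_loci: int  # comparison-domain size
    discordant: tuple[DiscordantLocus, ...]

    @property
    def discordant_loci(self) -> int:
        return len(self.discordant)


@dataclass(frozen=True)
class CoverageSummary:
    covered_positions: int
    denominator: int
    breadth: float
    mean_depth: float | None  # None when nothing is covered

    @property
    def breadth_percent(self) -> int:
        """Breadth rounded to a whole percent, as conventionally reported."""
        return round(self.breadth * 100)


def _classify_pattern(trace: Genotype, reference: Genotype) -> str:
    if trace.is_hom() and reference is Genotype.HET:
        return "hom_vs_het"
    if trace is Genotype.HET and reference.is_hom():
        return "het_vs_hom"
    if trace.is_hom() and reference.is_hom():
        return "hom_vs_hom"
    raise ValueError(f"unclassifiable pattern: {trace} vs {reference}")


def comparison_domain(
    trace: Mapping[Locus, ConsensusGenotype],
    reference: Mapping[Locus, ConsensusGenotype],
) -> set[Locus]:
    """Loci with accepted consensus in both samples and a variant in >=1."""
    domain: set[Locus] = set()
    for locus, trace_consensus in trace.items():
        reference_consensus = reference.get(locus)
        if reference_consensus is None:
            continue
        if (
            trace_consensus.genotype.is_variant()
            or reference_consensus.genotype.is_variant()
        ):
            domain.add(locus)
    return domain


def find_discordances(
    trace: Mapping[Locus, ConsensusGenotype],
    reference: Mapping[Locus, ConsensusGenotype],
    domain: Iterable[Locus],
) -> list[DiscordantLocus]:
    """One record per domain locus whose consensus genotypes differ.

    Results are returned in deterministic (chrom, pos) order.
    """
    records: list[DiscordantLocus] = []
    for locus in sorted(domain, key=lambda l: l.sort_key):
        trace_consensus = trace[locus]
        reference_consensus = reference[locus]
        if trace_consensus.genotype == reference_consensus.genotype:
            continue
        records.append(
            DiscordantLocus(
                locus=locus,
                trace_genotype=trace_consensus.genotype,
                reference_genotype=reference_consensus.genotype,
                pattern=_classify_pattern(
                    trace_consensus.genotype, reference_consensus.genotype
                ),
                trace_support=trace_consensus.per_replicate_support,
                trace_gq=trace_consensus.per_replicate_gq,
                reference_support=reference_consensus.per_replicate_support,
                reference_gq=reference_consensus.per_replicate_gq,
            )
        )
    return records


@dataclass(frozen=True)
class ComparisonResult:
    """Full output of one trace-vs-reference comparison run."""

    config: FilterConfig
    trace_consensus: dict[Locus, ConsensusGenotype]
    reference_consensus: dict[Locus, ConsensusGenotype]
    domain: set[Locus]
    discordant: list[DiscordantLocus]
    stage_counts: dict


def _variant_count(consensus: Mapping[Locus, ConsensusGenotype]) -> int:
    return sum(1 for c in consensus.values() if c.genotype.is_variant())


def compare_samples(
    trace_replicates: Sequence[SampleCallSet],
    reference_replicates: Sequence[SampleCallSet],
    config: FilterConfig,
) -> ComparisonResult:
    """Run consensus building, domain construction and discordance detection.

    ``stage_counts`` mirrors the pipeline steps: loci with calls in all
    replicates, variants concordant in both replicates under dp/gq alone,
    variants additionally passing the Hb window, compared loci, and
    discordant loci.
    """
    trace_calls = [r.calls for r in trace_replicates]
    reference_calls = [r.calls for r in reference_replicates]

    # dp/gq-only pass, for the pre-Hb stage count
    base_only = config.with_hb(None, None)
    trace_base, _ = consensus_map(trace_calls, base_only)
    reference_base, _ = consensus_map(reference_calls, base_only)

    trace_consensus, trace_reasons = consensus_map(trace_calls, config)
    reference_consensus, reference_reasons = consensus_map(reference_calls, config)
    domain = comparison_domain(trace_consensus, reference_consensus)
    discordant = find_discordances(trace_consensus, reference_consensus, domain)

    stage_counts = {
        "loci_with_calls_all_replicates": {
            "trace": len(
                set.intersection(*(set(c) for c in trace_calls))
            ) if trace_calls else 0,
            "reference": len(
                set.intersection(*(set(c) for c in reference_calls))
            ) if reference_calls else 0,
        },
        "variants_concordant_pre_hb": {
            "trace": _variant_count(trace_base),
            "reference": _variant_count(reference_base),
        },
        "variants_passing_hb": {
            "trace": _variant_count(trace_consensus),
            "reference": _variant_count(reference_consensus),
        },
        "consensus_genotypes": {
            "trace": len(trace_consensus),
            "reference": len(reference_consensus),
        },
        "no_consensus_reasons": {
            "trace": trace_reasons,
            "reference": reference_reasons,
        },
        "compared_loci": len(domain),
        "discordant_loci": len(discordant),
    }
    return ComparisonResult(
        config=config,
        trace_consensus=trace_consensus,
        reference_consensus=reference_consensus,
        domain=domain,
        discordant=discordant,
        stage_counts=stage_counts,
    )


def hb_sweep(
    trace_replicates: Sequence[SampleCallSet],
    reference_replicates: Sequence[SampleCallSet],
    schemes: Sequence[SweepScheme],
    base_config: FilterConfig,
) -> list[SweepResult]:
    """Re-run the comparison once per Hb scheme, dp/gq held at base values."""
    if not schemes:
        raise ValueError("scheme list must be non-empty")
    labels = [s.label for s in schemes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"scheme labels must be unique, got {labels}")
    trace_calls = [r.calls for r in trace_replicates]
    reference_calls = [r.calls for r in reference_replicates]

    results: list[SweepResult] = []
    for scheme in schemes:
        config = base_config.with_hb(scheme.hb_low, scheme.hb_high)
        trace_consensus, _ = consensus_map(trace_calls, config)
        reference_consensus, _ = consensus_map(reference_calls, config)
        domain = comparison_domain(trace_consensus, reference_consensus)
        discordant = find_discordances(trace_consensus, reference_consensus, domain)
        results.append(
            SweepResult(
                scheme=scheme,
                retained_trace=len(trace_consensus),
                retained_reference=len(reference_consensus),
                retained_combined=sum(
                    1 for locus in trace_consensus if locus in reference_consensus
                ),
                compared_loci=len(domain),
                discordant=tuple(discordant),
            )
        )
    return results


def coverage_summary(
    depths_a: Mapping,
    depths_b: Mapping,
    dp_min: int,
    denominator: int,
) -> CoverageSummary:
    """Breadth and mean depth over positions covered in both replicates.

    A position counts as covered when its depth is >= ``dp_min`` in both
    inputs; mean depth averages the two replicate depths over covered
    positions.  ``denominator`` is the genome-size normaliser for breadth.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    covered = 0
    depth_total = 0.0
    for position, depth_a in depths_a.items():
        depth_b = depths_b.get(position)
        if depth_b is None:
            continue
        if depth_a >= dp_min and depth_b >= dp_min:
            covered += 1
            depth_total += (depth_a + depth_b) / 2.0
    return CoverageSummary(
        covered_positions=covered,
        denominator=denominator,
        breadth=covered / denominator,
        mean_depth=depth_total / covered if covered else None,
    )


def read_depth_track(path) -> dict:
    """Parse a per-position depth track into ``{key: depth}``.

    Accepted dialects, tab- or space-separated, ``#`` comments ignored:

    * ``pos  depth``                    -> keyed by int position
    * ``chrom  pos  depth``             -> keyed by (chrom, pos)
    * ``chrom  start  end  depth`` (BED, 0-based half-open) -> one entry per
      position in the interval, keyed by (chrom, 1-based pos)
    """
    depths: dict = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 2:
                depths[int(fields[0])] = float(fields[1])
            elif len(fields) == 3:
                depths[(fields[0], int(fields[1]))] = float(fields[2])
            elif len(fields) == 4:
                chrom, start, end, depth = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
                for position in range(start + 1, end + 1):
                    depths[(chrom, position)] = depth
            else:
                raise ValueError(f"unrecognised depth-track line: {line!r}")
    return depths
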