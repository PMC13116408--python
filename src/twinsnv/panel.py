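"""Targeted-panel confirmation of candidate discordant loci.

Candidates surviving the shotgun comparison are re-genotyped under the
stricter targeted regime (DP >= 100, GQ >= 10, het Hb in [0.3, 0.7],
homozygote noise < 0.05) and each receives exactly one verdict:

* ``confirmed_discordant`` — accepted consensus genotypes in both samples,
  and they differ;
* ``rejected_concordant`` — accepted consensus genotypes in both samples,
  and they agree;
* ``inconclusive`` — anything else (dropped from the panel, allele
  mismatch, or no accepted consensus in at least one sample).  Absence of
  evidence in one sample cannot confirm a difference.

Identity-SNP control loci are validated by the same machinery but never
influence the case verdict; any control discordance flags the run as
suspect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .core import FilterConfig, Genotype, Locus
from .filtering import ConsensusGenotype, replicate_consensus
from .vcf_io import SampleCallSet

__all__ = [
    "PanelDesign",
    "LocusVerdict",
    "CaseSummary",
    "PanelValidationResult",
    "validate_candidates",
    "validate_panel",
    "case_verdict",
    "read_panel_design",
    "write_panel_design",
    "write_verdicts",
    "NO_DIFFERENCE_CAVEAT",
]

#: Wording attached to a negative case outcome: a negative result cannot
#: separate "same donor" from "co-twin with no detectable difference".
NO_DIFFERENCE_CAVEAT = (
    "No SNV difference detected: the trace may come from the reference "
    "donor, or from an identical co-twin indistinguishable by the applied "
    "methods."
)


@dataclass(frozen=True)
class PanelDesign:
    """Which candidate loci made it onto the panel, and the controls."""

    target_loci: tuple[Locus, ...]
    dropped_loci: tuple[Locus, ...] = ()
    control_loci: tuple[Locus, ...] = ()
    dropped_reason: str = "undesignable"

    def __post_init__(self) -> None:
        overlap = set(self.target_loci) & set(self.dropped_loci)
        if overlap:
            raise ValueError(f"loci both targeted and dropped: {sorted(overlap, key=lambda l: l.sort_key)}")


@dataclass(frozen=True, slots=True)
class LocusVerdict:
    locus: Locus
    verdict: str  # confirmed_discordant | rejected_concordant | inconclusive
    trace_genotype: Genotype | None
    reference_genotype: Genotype | None
    reason: str


@dataclass(frozen=True)
class CaseSummary:
    outcome: str  # distinguishable | no_detectable_difference
    n_confirmed: int
    n_rejected: int
    n_inconclusive: int
    zero_candidates: bool
    caveat: str | None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_confirmed_discordant": self.n_confirmed,
            "n_rejected_concordant": self.n_rejected,
            "n_inconclusive": self.n_inconclusive,
            "zero_candidates": self.zero_candidates,
            "caveat": self.caveat,
        }


@dataclass(frozen=True)
class PanelValidationResult:
    target_verdicts: list[LocusVerdict]
    control_verdicts: list[LocusVerdict]
    run_suspect: bool  # any control locus discordant


def _position_index(callsets: Sequence[SampleCallSet]) -> dict[tuple[str, int], Locus]:
    index: dict[tuple[str, int], Locus] = {}
    for callset in callsets:
        for locus in callset.calls:
            index[(locus.chrom, locus.pos)] = locus
    return index


def _sample_consensus(
    locus: Locus, callsets: Sequence[SampleCallSet], config: FilterConfig
):
    calls = [cs.calls.get(locus) for cs in callsets]
    if any(call is None for call in calls):
        return None, "insufficient_replicates"
    result = replicate_consensus(calls, config)
    if isinstance(result, ConsensusGenotype):
        return result, None
    return None, result.reason


def _verdict_for_locus(
    locus: Locus,
    trace_callsets: Sequence[SampleCallSet],
    reference_callsets: Sequence[SampleCallSet],
    config: FilterConfig,
    position_index: Mapping[tuple[str, int], Locus],
) -> LocusVerdict:
    panel_locus = position_index.get((locus.chrom, locus.pos))
    if panel_locus is None:
        return LocusVerdict(locus, "inconclusive", None, None, "no_panel_data")
    if panel_locus != locus:
        return LocusVerdict(
            locus, "inconclusive", None, None,
            f"allele_mismatch:panel_has_{panel_locus.ref_allele}>{panel_locus.alt_allele}",
        )
    trace, trace_reason = _sample_consensus(locus, trace_callsets, config)
    reference, reference_reason = _sample_consensus(locus, reference_callsets, config)
    if trace is None or reference is None:
        parts = []
        if trace_reason:
            parts.append(f"trace:{trace_reason}")
        if reference_reason:
            parts.append(f"reference:{reference_reason}")
        return LocusVerdict(
            locus, "inconclusive",
            trace.genotype if trace else None,
            reference.genotype if reference else None,
            "no_consensus(" + ",".join(parts) + ")",
        )
    if trace.genotype == reference.genotype:
        return LocusVerdict(
            locus, "rejected_concordant", trace.genotype, reference.genotype,
            "accepted_identical_genotypes",
        )
    return LocusVerdict(
        locus, "confirmed_discordant", trace.genotype, reference.genotype,
        "accepted_differing_genotypes",
    )


def validate_candidates(
    candidates: Sequence[Locus],
    trace_callsets: Sequence[SampleCallSet],
    reference_callsets: Sequence[SampleCallSet],
    config: FilterConfig,
    design: PanelDesign,
) -> list[LocusVerdict]:
    """One verdict per candidate locus, in (chrom, pos) order."""
    dropped = set(design.dropped_loci)
    targets = set(design.target_loci)
    index = _position_index(list(trace_callsets) + list(reference_callsets))
    verdicts: list[LocusVerdict] = []
    for locus in sorted(candidates, key=lambda l: l.sort_key):
        if locus in dropped or locus not in targets:
            verdicts.append(
                LocusVerdict(locus, "inconclusive", None, None, "not_in_panel")
            )
            continue
        verdicts.append(
            _verdict_for_locus(locus, trace_callsets, reference_callsets, config, index)
        )
    return verdicts


def validate_panel(
    candidates: Sequence[Locus],
    trace_callsets: Sequence[SampleCallSet],
    reference_callsets: Sequence[SampleCallSet],
    config: FilterConfig,
    design: PanelDesign,
) -> PanelValidationResult:
    """Validate candidates and controls; flag the run if a control misbehaves."""
    target_verdicts = validate_candidates(
        candidates, trace_callsets, reference_callsets, config, design
    )
    index = _position_index(list(trace_callsets) + list(reference_callsets))
    control_verdicts = [
        _verdict_for_locus(locus, trace_callsets, reference_callsets, config, index)
        for locus in sorted(design.control_loci, key=lambda l: l.sort_key)
    ]
    run_suspect = any(v.verdict == "confirmed_discordant" for v in control_verdicts)
    return PanelValidationResult(target_verdicts, control_verdicts, run_suspect)


def case_verdict(verdicts: Sequence[LocusVerdict]) -> CaseSummary:
    """Fold per-locus verdicts into the case-level outcome."""
    n_confirmed = sum(1 for v in verdicts if v.verdict == "confirmed_discordant")
    n_rejected = sum(1 for v in verdicts if v.verdict == "rejected_concordant")
    n_inconclusive = sum(1 for v in verdicts if v.verdict == "inconclusive")
    if n_confirmed > 0:
        return CaseSummary(
            outcome="distinguishable",
            n_confirmed=n_confirmed,
            n_rejected=n_rejected,
            n_inconclusive=n_inconclusive,
            zero_candidates=False,
            caveat=None,
        )
    return CaseSummary(
        outcome="no_detectable_difference",
        n_confirmed=0,
        n_rejected=n_rejected,
        n_inconclusive=n_inconclusive,
        zero_candidates=len(verdicts) == 0,
        caveat=NO_DIFFERENCE_CAVEAT,
    )


_DESIGN_COLUMNS = ["chrom", "pos", "ref", "alt", "role"]
_ROLES = {"target", "control", "dropped"}


def write_panel_design(design: PanelDesign, path: str | Path) -> None:
    rows = (
        [(locus, "target") for locus in design.target_loci]
        + [(locus, "control") for locus in design.control_loci]
        + [(locus, "dropped") for locus in design.dropped_loci]
    )
    rows.sort(key=lambda item: (item[0].sort_key, item[1]))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_DESIGN_COLUMNS)
        for locus, role in rows:
            writer.writerow(
                [locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele, role]
            )


def read_panel_design(path: str | Path) -> PanelDesign:
    targets: list[Locus] = []
    controls: list[Locus] = []
    dropped: list[Locus] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            role = row["role"]
            if role not in _ROLES:
                raise ValueError(f"unknown panel role {role!r} in {path}")
            locus = Locus(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
            )
            {"target": targets, "control": controls, "dropped": dropped}[role].append(
                locus
            )
    return PanelDesign(
        target_loci=tuple(targets),
        dropped_loci=tuple(dropped),
        control_loci=tuple(controls),
    )


_VERDICT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "verdict",
    "trace_genotype", "reference_genotype", "reason",
]


def write_verdicts(verdicts: Sequence[LocusVerdict], path: str | Path) -> None:
    ordered = sorted(verdicts, key=lambda v: v.locus.sort_key)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_VERDICT_COLUMNS)
        for v in ordered:
            writer.writerow([
                v.locus.chrom, v.locus.pos, v.locus.ref_allele, v.locus.alt_allele,
                v.verdict,
                v.trace_genotype.value if v.trace_genotype else "NA",
                v.reference_genotype.value if v.reference_genotype else "NA",
                v.reason,
            ])
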