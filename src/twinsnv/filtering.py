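"""Per-replicate genotype acceptance and within-sample replicate consensus.

A genotype enters any downstream comparison only if (a) every replicate's
call passes the active :class:`~twinsnv.core.FilterConfig` and (b) all
replicate genotypes are identical.  Hb is evaluated per replicate, never on
pooled counts, so replicate-level imbalance is not masked.

Rejection reasons are evaluated in a fixed order —
``missing, depth, quality, balance, noise`` — so rejection statistics are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .core import (
    FilterConfig,
    Genotype,
    GenotypeCall,
    Locus,
    ReadSupport,
    UndefinedBalanceError,
    heterozygote_balance,
    noise_fraction,
)

__all__ = [
    "REASON_ORDER",
    "SHOTGUN",
    "TARGETED",
    "PRESETS",
    "AcceptanceDecision",
    "ConsensusGenotype",
    "NoConsensus",
    "accept_genotype",
    "replicate_consensus",
    "consensus_map",
    "load_filter_config",
    "save_filter_config",
]

#: Fixed evaluation order for rejection reason codes.
REASON_ORDER = ("missing", "depth", "quality", "balance", "noise")

#: Shotgun acceptance regime: DP >= 8, GQ >= 10, het Hb in [0.4, 0.6], no
#: homozygote noise filter.
SHOTGUN = FilterConfig(dp_min=8, gq_min=10, hb_low=0.4, hb_high=0.6)

#: Targeted-panel regime: DP >= 100, GQ >= 10, het Hb in [0.3, 0.7],
#: homozygote noise < 0.05.
TARGETED = FilterConfig(dp_min=100, gq_min=10, hb_low=0.3, hb_high=0.7, noise_max=0.05)

PRESETS: Mapping[str, FilterConfig] = {"shotgun": SHOTGUN, "targeted": TARGETED}


@dataclass(frozen=True, slots=True)
class AcceptanceDecision:
    """Outcome of applying a FilterConfig to a single call."""

    accepted: bool
    reason: str | None  # first failed criterion, None when accepted

    def __bool__(self) -> bool:
        return self.accepted


_ACCEPT = AcceptanceDecision(True, None)


def accept_genotype(call: GenotypeCall, config: FilterConfig) -> AcceptanceDecision:
    """Apply one acceptance regime to one replicate call.

    Accepted iff all of: genotype present; ``dp >= dp_min``; ``gq >= gq_min``;
    for hets, Hb inside the configured window (when one is configured); for
    homozygotes, noise strictly below ``noise_max`` (when configured).
    """
    if call.genotype is Genotype.MISSING:
        return AcceptanceDecision(False, "missing")
    if call.support.dp < config.dp_min:
        return AcceptanceDecision(False, "depth")
    if call.gq < config.gq_min:
        return AcceptanceDecision(False, "quality")
    if call.genotype is Genotype.HET and config.has_hb_filter:
        try:
            hb = heterozygote_balance(call.support)
        except UndefinedBalanceError:
            return AcceptanceDecision(False, "balance")
        if not (config.hb_low <= hb <= config.hb_high):
            return AcceptanceDecision(False, "balance")
    if call.genotype.is_hom() and config.noise_max is not None:
        if call.support.dp == 0:
            return AcceptanceDecision(False, "noise")
        if not (noise_fraction(call) < config.noise_max):
            return AcceptanceDecision(False, "noise")
    return _ACCEPT


@dataclass(frozen=True, slots=True)
class ConsensusGenotype:
    """A genotype accepted identically in every replicate of one sample."""

    locus: Locus
    genotype: Genotype
    n_replicates: int
    per_replicate_support: tuple[ReadSupport, ...]
    per_replicate_gq: tuple[int, ...]


@dataclass(frozen=True, slots=True)
class NoConsensus:
    """Why a locus yielded no consensus genotype for a sample."""

    locus: Locus
    reason: str  # replicate_failed_filter | replicate_discordant | insufficient_replicates


def replicate_consensus(
    calls: Sequence[GenotypeCall], config: FilterConfig
) -> ConsensusGenotype | NoConsensus:
    """Build the consensus genotype for one locus from replicate calls.

    Every replicate must individually pass ``config`` and all genotypes must
    be identical; otherwise a :class:`NoConsensus` is returned.  Filter
    failure takes precedence over genotype disagreement in the reported
    reason.  The result does not depend on replicate order.
    """
    if not calls:
        raise ValueError("replicate_consensus requires at least one call")
    locus = calls[0].locus
    for call in calls[1:]:
        if call.locus != locus:
            raise ValueError(
                f"replicate calls at differing loci: {locus} vs {call.locus}"
            )
    if len(calls) < 2:
        return NoConsensus(locus, "insufficient_replicates")
    if not all(accept_genotype(call, config) for call in calls):
        return NoConsensus(locus, "replicate_failed_filter")
    genotypes = {call.genotype for call in calls}
    if len(genotypes) > 1:
        return NoConsensus(locus, "replicate_discordant")
    return ConsensusGenotype(
        locus=locus,
        genotype=calls[0].genotype,
        n_replicates=len(calls),
        per_replicate_support=tuple(call.support for call in calls),
        per_replicate_gq=tuple(call.gq for call in calls),
    )


def consensus_map(
    replicate_calls: Sequence[Mapping[Locus, GenotypeCall]],
    config: FilterConfig,
) -> tuple[dict[Locus, ConsensusGenotype], dict[str, int]]:
    """Consensus genotypes for one sample across its replicate call maps.

    A locus absent from any replicate counts as ``insufficient_replicates``.
    Returns the consensus mapping and a tally of no-consensus reasons.
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least two replicates per sample")
    reasons = {reason: 0 for reason in
               ("replicate_failed_filter", "replicate_discordant",
                "insufficient_replicates")}
    loci: set[Locus] = set()
    for calls in replicate_calls:
        loci.update(calls)
    consensus: dict[Locus, ConsensusGenotype] = {}
    for locus in loci:
        per_rep = [calls.get(locus) for calls in replicate_calls]
        if any(call is None for call in per_rep):
            reasons["insufficient_replicates"] += 1
            continue
        result = replicate_consensus(per_rep, config)
        if isinstance(result, ConsensusGenotype):
            consensus[locus] = result
        else:
            reasons[result.reason] += 1
    return consensus, reasons


def load_filter_config(path: str | Path) -> FilterConfig:
    """Read a FilterConfig from a JSON file, or resolve a preset name."""
    name = str(path)
    if name in PRESETS:
        return PRESETS[name]
    with open(path) as handle:
        return FilterConfig.from_dict(json.load(handle))


def save_filter_config(config: FilterConfig, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(config.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
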