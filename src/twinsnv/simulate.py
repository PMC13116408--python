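"""Synthetic MZ-twin case generator.

Produces germline diploid genotypes shared by both twins, twin-specific
post-zygotic heterozygous mutations (constitutional: alt fraction 0.5 in
every tissue of that twin), tissue-specific somatic variants with skewed
alt-read fractions, and per-replicate read counts, then genotypes the
counts with a binomial-likelihood caller so the emitted VCFs carry
realistic GT/AD/DP/GQ fields.

Randomness is governed by a single seed; every stage draws from a
deterministically derived substream, so adding a stage never perturbs
earlier draws and replicates of the same tissue differ only by read
sampling.

Read-count model for a site with true alt fraction ``f`` and per-read
miscall probability ``e``::

    depth  ~ Poisson(mean_depth)
    p_alt   = f(1-e) + (1-f) e/3      (miscalls uniform over the 3 other bases)
    p_other = 2e/3
    p_ref   = 1 - p_alt - p_other
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .core import BASES, Genotype, GenotypeCall, Locus, ReadSupport
from .vcf_io import SampleCallSet, write_vcf

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulationResult",
    "simulate_twin_pair",
    "simulate_panel",
    "select_control_loci",
    "sample_read_support",
    "genotype_quality_from_counts",
    "write_simulation",
    "TRUTH_COLUMNS",
]

_BASE_ORDER = "ACGT"
_GT_CODES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING)
_GQ_CAP = 99


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic twin-pair case.

    ``n_postzygotic`` plants an exact per-twin count of constitutional
    mutations instead of a Poisson(``lambda_postzygotic``) draw.  Setting
    ``trace_twin == reference_twin`` emulates both samples coming from the
    same individual.
    """

    n_loci: int = 10_000
    p_het: float = 0.15
    p_hom_alt: float = 0.10
    lambda_postzygotic: float = 14.0
    n_postzygotic: tuple[int, int] | None = None
    n_somatic: int = 50
    somatic_fraction_low: float = 0.05
    somatic_fraction_high: float = 0.20
    mean_depth_trace: float = 39.7
    mean_depth_reference: float = 25.8
    error_rate: float = 0.002
    n_replicates: int = 2
    panel_depth: float = 500.0
    undesignable_rate: float = 0.0
    trace_twin: int = 0
    reference_twin: int = 1
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if not (0.0 <= self.p_het <= 1.0 and 0.0 <= self.p_hom_alt <= 1.0):
            raise ValueError("genotype probabilities must lie in [0, 1]")
        if self.p_het + self.p_hom_alt > 1.0:
            raise ValueError("p_het + p_hom_alt must not exceed 1")
        if not (
            0.0
            <= self.somatic_fraction_low
            <= self.somatic_fraction_high
            <= 1.0
        ):
            raise ValueError("somatic fraction bounds must satisfy 0 <= low <= high <= 1")
        if min(self.mean_depth_trace, self.mean_depth_reference, self.panel_depth) <= 0:
            raise ValueError("mean depths must be positive")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.lambda_postzygotic < 0 or self.n_somatic < 0:
            raise ValueError("variant counts must be non-negative")
        if not (0.0 <= self.undesignable_rate <= 1.0):
            raise ValueError("undesignable_rate must lie in [0, 1]")
        if self.trace_twin not in (0, 1) or self.reference_twin not in (0, 1):
            raise ValueError("twin indices must be 0 or 1")

    def to_dict(self) -> dict:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        if data["n_postzygotic"] is not None:
            data["n_postzygotic"] = list(data["n_postzygotic"])
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        if kwargs.get("n_postzygotic") is not None:
            kwargs["n_postzygotic"] = tuple(int(x) for x in kwargs["n_postzygotic"])
        return cls(**kwargs)


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one simulated variant."""

    locus: Locus
    category: str  # germline | post_zygotic_twin1 | post_zygotic_twin2 | somatic
    twin1_genotype: Genotype
    twin2_genotype: Genotype
    sample_id: str  # affected sample for somatic records, "" otherwise
    alt_fraction: float


@dataclass
class SimulationResult:
    """Everything one simulation run produced, in memory."""

    config: SimulationConfig
    loci: list[Locus]
    twin_genotypes: np.ndarray  # shape (2, n_loci), values 0/1/2
    sample_twins: dict[str, int]  # sample id -> twin index
    sample_alt_fraction: dict[str, np.ndarray]  # tissue-level truth per sample
    truth: list[TruthRecord]
    callsets: dict[str, list[SampleCallSet]]  # sample id -> replicate call sets
    contig_lengths: dict[str, int]

    @property
    def locus_index(self) -> dict[Locus, int]:
        return {locus: i for i, locus in enumerate(self.loci)}


def _stage_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one named simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _read_probabilities(f, error_rate):
    p_alt = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
    p_other = 2.0 * error_rate / 3.0
    return p_alt, p_other


def _draw_counts(rng, depth, f, error_rate):
    """Vectorised three-way read split; returns (ref, alt, other) arrays."""
    depth = np.asarray(depth)
    f = np.broadcast_to(np.asarray(f, dtype=float), depth.shape)
    p_alt, p_other = _read_probabilities(f, error_rate)
    alt = rng.binomial(depth, p_alt)
    remainder = depth - alt
    denom = 1.0 - p_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(denom > 0, np.clip(p_other / denom, 0.0, 1.0), 0.0)
    other = rng.binomial(remainder, q)
    ref = depth - alt - other
    return ref, alt, other


def _call_genotypes(ref, alt, error_rate):
    """Vectorised binomial-likelihood genotype caller.

    Likelihood of genotype g is Binom(alt; ref+alt, p(g)) with
    p in {e/3, 0.5, 1-e}; the call is the argmax and GQ is
    round(10*log10(L_best/L_second)) capped at 99.  Zero-depth sites are
    missing with GQ 0.
    """
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n = ref + alt
    probs = (error_rate / 3.0, 0.5, 1.0 - error_rate)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = np.stack([binom.logpmf(alt, n, p) for p in probs])
    loglik = np.nan_to_num(loglik, nan=-np.inf, posinf=-np.inf)
    order = np.argsort(loglik, axis=0)
    best_idx = order[-1]
    l_best = np.take_along_axis(loglik, order[-1:][:], axis=0)[0]
    l_second = np.take_along_axis(loglik, order[-2:-1][:], axis=0)[0]
    with np.errstate(invalid="ignore", over="ignore"):
        gq = 10.0 / math.log(10.0) * (l_best - l_second)
    gq = np.where(np.isfinite(gq), gq, float(_GQ_CAP))
    gq = np.clip(np.round(gq), 0, _GQ_CAP).astype(np.int64)

    # argsort is ascending and stable; prefer the lower genotype index on
    # exact likelihood ties so uninformative sites call hom_ref with GQ 0
    ties = np.isclose(
        np.take_along_axis(loglik, best_idx[None, :], axis=0)[0], loglik
    )
    genotype = np.argmax(ties, axis=0).astype(np.int8)
    gq = np.where(ties.sum(axis=0) > 1, 0, gq)
    return genotype, gq


def sample_read_support(
    true_alt_fraction: float,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
    *,
    fixed_depth: int | None = None,
) -> ReadSupport:
    """Draw one replicate's read counts for a site.

    Depth is Poisson(``mean_depth``) unless ``fixed_depth`` is given.
    """
    if not (0.0 <= true_alt_fraction <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if mean_depth <= 0 and fixed_depth is None:
        raise ValueError("mean_depth must be positive")
    depth = fixed_depth if fixed_depth is not None else int(rng.poisson(mean_depth))
    ref, alt, other = _draw_counts(
        rng, np.array([depth]), np.array([true_alt_fraction]), error_rate
    )
    return ReadSupport(int(ref[0]), int(alt[0]), int(other[0]))


def genotype_quality_from_counts(
    support: ReadSupport, error_rate: float
) -> tuple[Genotype, int]:
    """Call a genotype and GQ from one replicate's read counts."""
    if support.dp == 0:
        return Genotype.MISSING, 0
    genotype, gq = _call_genotypes(
        np.array([support.ref_count]), np.array([support.alt_count]), error_rate
    )
    return _GT_CODES[int(genotype[0])], int(gq[0])


def _build_callset(
    sample_id: str,
    replicate_id: str,
    loci: Sequence[Locus],
    ref,
    alt,
    other,
    genotype,
    gq,
    contig_lengths: dict[str, int],
) -> SampleCallSet:
    dp = ref + alt + other
    calls: dict[Locus, GenotypeCall] = {}
    for i, locus in enumerate(loci):
        gt = Genotype.MISSING if dp[i] == 0 else _GT_CODES[genotype[i]]
        calls[locus] = GenotypeCall(
            locus=locus,
            genotype=gt,
            support=ReadSupport(int(ref[i]), int(alt[i]), int(other[i])),
            gq=0 if gt is Genotype.MISSING else int(gq[i]),
        )
    return SampleCallSet(
        sample_id=sample_id,
        replicate_id=replicate_id,
        calls=calls,
        contig_lengths=dict(contig_lengths),
    )


def simulate_twin_pair(config: SimulationConfig) -> SimulationResult:
    """Generate one full synthetic twin case (truth + replicate call sets)."""
    n = config.n_loci
    seed = config.seed

    # stage 0: loci and germline genotypes, shared by both twins
    rng = _stage_rng(seed, 0)
    positions = 1_000 + 100 * np.arange(n, dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    loci = [
        Locus(
            chrom=config.chrom,
            pos=int(positions[i]),
            ref_allele=_BASE_ORDER[ref_idx[i]],
            alt_allele=_BASE_ORDER[alt_idx[i]],
        )
        for i in range(n)
    ]
    contig_lengths = {config.chrom: int(positions[-1]) + 1_000}

    u = rng.random(n)
    germline = np.zeros(n, dtype=np.int8)
    germline[u < config.p_hom_alt] = 2
    germline[(u >= config.p_hom_alt) & (u < config.p_hom_alt + config.p_het)] = 1
    twin_genotypes = np.vstack([germline.copy(), germline.copy()])

    # stage 1: post-zygotic constitutional mutations, one substream per twin
    postzygotic_idx: list[np.ndarray] = []
    taken = np.zeros(n, dtype=bool)
    for twin in (0, 1):
        rng_pz = _stage_rng(seed, 1, twin)
        if config.n_postzygotic is not None:
            count = config.n_postzygotic[twin]
        else:
            count = int(rng_pz.poisson(config.lambda_postzygotic))
        available = np.flatnonzero(
            (twin_genotypes[0] == 0) & (twin_genotypes[1] == 0) & ~taken
        )
        if count > available.size:
            raise ValueError(
                f"cannot place {count} post-zygotic mutations: only "
                f"{available.size} hom-ref loci available"
            )
        chosen = rng_pz.choice(available, size=count, replace=False)
        twin_genotypes[twin, chosen] = 1
        taken[chosen] = True
        postzygotic_idx.append(np.sort(chosen))

    samples = [
        ("trace", config.trace_twin, config.mean_depth_trace),
        ("reference", config.reference_twin, config.mean_depth_reference),
    ]

    # stage 2: tissue-specific somatic variants, one substream per sample
    gt_to_fraction = np.array([0.0, 0.5, 1.0])
    sample_alt_fraction: dict[str, np.ndarray] = {}
    somatic: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sample_idx, (sample_id, twin, _) in enumerate(samples):
        rng_som = _stage_rng(seed, 2, sample_idx)
        fractions = gt_to_fraction[twin_genotypes[twin]].copy()
        available = np.flatnonzero((twin_genotypes[twin] == 0) & ~taken)
        if config.n_somatic > available.size:
            raise ValueError(
                f"cannot place {config.n_somatic} somatic variants: only "
                f"{available.size} hom-ref loci available"
            )
        chosen = rng_som.choice(available, size=config.n_somatic, replace=False)
        taken[chosen] = True
        order = np.argsort(chosen)
        chosen = chosen[order]
        drawn = rng_som.uniform(
            config.somatic_fraction_low, config.somatic_fraction_high,
            size=config.n_somatic,
        )[order]
        fractions[chosen] = drawn
        sample_alt_fraction[sample_id] = fractions
        somatic[sample_id] = (chosen, drawn)

    # truth table
    truth: list[TruthRecord] = []
    gt_codes = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}
    for i in np.flatnonzero(germline != 0):
        truth.append(
            TruthRecord(
                locus=loci[i],
                category="germline",
                twin1_genotype=gt_codes[int(germline[i])],
                twin2_genotype=gt_codes[int(germline[i])],
                sample_id="",
                alt_fraction=float(gt_to_fraction[germline[i]]),
            )
        )
    for twin, indices in enumerate(postzygotic_idx):
        for i in indices:
            truth.append(
                TruthRecord(
                    locus=loci[i],
                    category=f"post_zygotic_twin{twin + 1}",
                    twin1_genotype=gt_codes[int(twin_genotypes[0, i])],
                    twin2_genotype=gt_codes[int(twin_genotypes[1, i])],
                    sample_id="",
                    alt_fraction=0.5,
                )
            )
    for sample_id, (indices, fractions) in somatic.items():
        for i, fraction in zip(indices, fractions):
            truth.append(
                TruthRecord(
                    locus=loci[i],
                    category="somatic",
                    twin1_genotype=Genotype.HOM_REF,
                    twin2_genotype=Genotype.HOM_REF,
                    sample_id=sample_id,
                    alt_fraction=float(fraction),
                )
            )
    truth.sort(key=lambda r: (r.locus.sort_key, r.category, r.sample_id))

    # stage 3: replicate read counts and genotype calls
    callsets: dict[str, list[SampleCallSet]] = {}
    for sample_idx, (sample_id, _, mean_depth) in enumerate(samples):
        fractions = sample_alt_fraction[sample_id]
        replicates = []
        for rep in range(config.n_replicates):
            rng_reads = _stage_rng(seed, 3, sample_idx, rep)
            depth = rng_reads.poisson(mean_depth, size=n)
            ref, alt, other = _draw_counts(rng_reads, depth, fractions, config.error_rate)
            genotype, gq = _call_genotypes(ref, alt, config.error_rate)
            replicates.append(
                _build_callset(
                    sample_id, f"rep{rep + 1}", loci,
                    ref, alt, other, genotype, gq, contig_lengths,
                )
            )
        callsets[sample_id] = replicates

    return SimulationResult(
        config=config,
        loci=loci,
        twin_genotypes=twin_genotypes,
        sample_twins={sid: twin for sid, twin, _ in samples},
        sample_alt_fraction=sample_alt_fraction,
        truth=truth,
        callsets=callsets,
        contig_lengths=contig_lengths,
    )


def simulate_panel(
    result: SimulationResult,
    panel_loci: Sequence[Locus],
    *,
    depth: float | None = None,
    error_rate: float | None = None,
) -> dict[str, list[SampleCallSet]]:
    """Re-sequence a subset of loci at panel depth for both samples.

    True alt fractions are re-used from the shotgun simulation (same
    tissues), so somatic skew persists at high depth.  Draws come from a
    dedicated substream of the simulation seed.
    """
    config = result.config
    depth = config.panel_depth if depth is None else depth
    error_rate = config.error_rate if error_rate is None else error_rate
    index = result.locus_index
    try:
        indices = np.array([index[locus] for locus in panel_loci], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"panel locus not in simulation: {exc.args[0]}") from exc

    panel: dict[str, list[SampleCallSet]] = {}
    for sample_idx, sample_id in enumerate(result.callsets):
        fractions = result.sample_alt_fraction[sample_id][indices]
        replicates = []
        for rep in range(config.n_replicates):
            rng = _stage_rng(config.seed, 4, sample_idx, rep)
            dp = rng.poisson(depth, size=indices.size)
            ref, alt, other = _draw_counts(rng, dp, fractions, error_rate)
            genotype, gq = _call_genotypes(ref, alt, error_rate)
            replicates.append(
                _build_callset(
                    sample_id, f"panel_rep{rep + 1}", list(panel_loci),
                    ref, alt, other, genotype, gq, result.contig_lengths,
                )
            )
        panel[sample_id] = replicates
    return panel


def select_control_loci(result: SimulationResult, n_controls: int) -> list[Locus]:
    """Pick identity-control loci: germline hets shared by both twins."""
    candidates = np.flatnonzero(
        (result.twin_genotypes[0] == 1) & (result.twin_genotypes[1] == 1)
    )
    # exclude post-zygotic hets (they differ between twins by construction,
    # so both-het loci here are germline or coincidental double mutations)
    if n_controls > candidates.size:
        raise ValueError(
            f"requested {n_controls} control loci, only {candidates.size} "
            "shared het loci available"
        )
    rng = _stage_rng(result.config.seed, 5)
    chosen = np.sort(rng.choice(candidates, size=n_controls, replace=False))
    return [result.loci[i] for i in chosen]


TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "category",
    "twin1_gt", "twin2_gt", "sample", "alt_fraction",
]


def write_simulation(
    result: SimulationResult,
    out_dir: str | Path,
    *,
    panel: Mapping[str, Sequence[SampleCallSet]] | None = None,
) -> list[Path]:
    """Write VCFs, truth table and a config echo; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for sample_id, replicates in result.callsets.items():
        for rep_idx, callset in enumerate(replicates, start=1):
            path = out_dir / f"{sample_id}_rep{rep_idx}.vcf"
            write_vcf(callset, path)
            written.append(path)
    if panel is not None:
        for sample_id, replicates in panel.items():
            for rep_idx, callset in enumerate(replicates, start=1):
                path = out_dir / f"panel_{sample_id}_rep{rep_idx}.vcf"
                write_vcf(callset, path)
                written.append(path)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as handle:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for rec in result.truth:
            handle.write(
                f"{rec.locus.chrom}\t{rec.locus.pos}\t{rec.locus.ref_allele}\t"
                f"{rec.locus.alt_allele}\t{rec.category}\t"
                f"{rec.twin1_genotype.value}\t{rec.twin2_genotype.value}\t"
                f"{rec.sample_id}\t{rec.alt_fraction:.6f}\n"
            )
    written.append(truth_path)

    config_path = out_dir / "simulation_config.json"
    with open(config_path, "w") as handle:
        json.dump(result.config.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    written.append(config_path)
    return written
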