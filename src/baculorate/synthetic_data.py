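"""Fully synthetic inputs with the statistical structure the analysis assumes.

The generator produces everything the pipeline consumes, with no external
data: a reference sequence with stop-free CDS intervals flanking a neutral
insert, true neutral mutations from the passage simulator, sequencing-error
artifacts (a configurable fraction recurring across all lineages, the rest
lineage-private), ancestral variants present in the ancestor and all
lineages, and heavy-tailed coverage tracks so the coverage-extreme trim is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ExperimentDesign, SimulationParams, simulate_experiment
from .selection_spectrum import RegionAnnotation, _BASES, _translate

__all__ = [
    "NoiseConfig",
    "generate_reference_fixture",
    "generate_experiment_truth",
    "generate_variant_tables",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Sequencing-noise model of the synthetic variant tables.

    ``error_rate`` is the per-site probability that an artifact variant is
    emitted in a lineage; ``shared_fraction`` of artifact identities recur
    in every lineage (read-mapping errors tied to the reference), the rest
    are lineage-private.  Coverage is negative-binomial-shaped around
    ``mean_coverage`` (about 5500x in the emulated experiment) with 1% of
    positions halved/doubled to create trimmable extremes.
    """

    error_rate: float = 2e-4
    shared_fraction: float = 0.5
    mean_coverage: float = 5500.0
    coverage_dispersion: float = 10.0
    ancestral_variant_count: int = 5
    artifact_frequency_range: tuple[float, float] = (0.005, 0.02)
    fail_filter_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("error_rate", "shared_fraction", "fail_filter_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS of the given length (multiple of 3)."""
    codons = []
    n_codons = length // 3
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if _translate(codon) != "*":
            codons.append(codon)
    return "".join(codons)


def generate_reference_fixture(
    g_neutral: int = 11646,
    g_genome: int = 145465,
    n_genes: int = 20,
    seed: int = 0,
) -> RegionAnnotation:
    """Random reference with CDS intervals, intergenic gaps and one insert.

    Layout mirrors a viral genome carrying a neutral insert: ``n_genes``
    stop-free CDS intervals with intergenic spacers, then the neutral
    insert, then intergenic sequence to ``g_genome``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA57A]))
    coding_budget = g_genome - g_neutral
    gene_len = 3 * max(1, coding_budget // max(1, (2 * n_genes)) // 3)
    if n_genes * gene_len + g_neutral > g_genome:
        raise ValueError("infeasible layout: genes plus insert exceed genome length")
    gap = (coding_budget - n_genes * gene_len) // (n_genes + 1) if n_genes else coding_budget
    parts: list[str] = []
    intervals: list[tuple] = []
    pos = 1

    def emit_intergenic(length: int) -> None:
        nonlocal pos
        if length <= 0:
            return
        parts.append("".join(rng.choice(list(_BASES), size=length)))
        intervals.append((pos, pos + length - 1, "intergenic", "+", 0))
        pos += length

    for k in range(n_genes):
        emit_intergenic(gap)
        strand = "+" if k % 2 == 0 else "-"
        cds = _random_cds(gene_len, rng)
        seq = cds if strand == "+" else _revcomp(cds)
        parts.append(seq)
        intervals.append((pos, pos + gene_len - 1, "CDS", strand, 0))
        pos += gene_len
    emit_intergenic(gap if n_genes else 0)
    parts.append("".join(rng.choice(list(_BASES), size=g_neutral)))
    intervals.append((pos, pos + g_neutral - 1, "neutral-insert", "+", 0))
    pos += g_neutral
    emit_intergenic(g_genome - pos + 1)
    return RegionAnnotation(reference="".join(parts), intervals=tuple(intervals))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_experiment_truth(
    params: SimulationParams,
    design: ExperimentDesign,
    n_lineages: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """True mutation-frequency vectors for independent lineages."""
    root = np.random.SeedSequence([seed, 0x72074])
    lineages = [chr(ord("A") + i) for i in range(n_lineages)]
    return {
        lin: simulate_experiment(params, design, np.random.default_rng(ss))
        for lin, ss in zip(lineages, root.spawn(n_lineages))
    }


def _variant_row(lineage, position, ref, alt, freq, rng, noise, passes=True):
    if passes:
        read_count = int(rng.integers(20, 200))
        fr_balance = float(rng.uniform(0.2, 0.5))
    else:  # deliberately fails one base filter
        if rng.random() < 0.5:
            read_count = int(rng.integers(1, 11))
            fr_balance = float(rng.uniform(0.2, 0.5))
        else:
            read_count = int(rng.integers(20, 200))
            fr_balance = float(rng.uniform(0.0, 0.05))
    return {
        "lineage": lineage,
        "position": int(position),
        "ref": ref,
        "alt": alt,
        "frequency": float(freq),
        "read_count": read_count,
        "fr_balance": fr_balance,
        "type": "SNV",
    }


def _random_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def generate_variant_tables(
    truth: dict[str, np.ndarray],
    noise: NoiseConfig,
    annotation: RegionAnnotation,
    seed: int = 0,
    offset: int = 0,
    min_emit_frequency: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Variant tables, ancestral calls and coverage tracks from truth.

    Returns ``(variants, ancestor, coverage)``.  True mutations are emitted
    at their simulated frequencies (above ``min_emit_frequency``) with
    filter-passing quality fields; artifacts at uniform frequencies in
    ``artifact_frequency_range`` with a ``fail_filter_fraction`` failing the
    base filters; ancestral variants appear in the ancestor table and every
    lineage.  ``offset`` places the simulated region at ``offset + 1`` on
    the reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AB1E5]))
    ref_seq = annotation.reference
    g = len(next(iter(truth.values())))
    lineages = sorted(truth)
    rows: list[dict] = []

    for lin in lineages:
        freqs = truth[lin]
        for i in np.flatnonzero(freqs > min_emit_frequency):
            position = offset + int(i) + 1
            ref = ref_seq[position - 1]
            rows.append(
                _variant_row(lin, position, ref, _random_alt(ref, rng), freqs[i], rng, noise)
            )

    # artifact identities: shared across all lineages or lineage-private
    n_artifacts = rng.binomial(g, noise.error_rate)
    lo, hi = noise.artifact_frequency_range
    for _ in range(n_artifacts):
        position = offset + int(rng.integers(0, g)) + 1
        ref = ref_seq[position - 1]
        alt = _random_alt(ref, rng)
        shared = rng.random() < noise.shared_fraction
        targets = lineages if shared else [lineages[int(rng.integers(0, len(lineages)))]]
        for lin in targets:
            passes = rng.random() >= noise.fail_filter_fraction
            rows.append(
                _variant_row(lin, position, ref, alt, rng.uniform(lo, hi), rng, noise, passes)
            )

    # ancestral variants: present in the ancestor and carried by every lineage
    anc_rows: list[dict] = []
    for _ in range(noise.ancestral_variant_count):
        position = offset + int(rng.integers(0, g)) + 1
        ref = ref_seq[position - 1]
        alt = _random_alt(ref, rng)
        freq = rng.uniform(lo, hi)
        anc_rows.append(_variant_row("ancestor", position, ref, alt, freq, rng, noise))
        for lin in lineages:
            rows.append(_variant_row(lin, position, ref, alt, freq, rng, noise))

    columns = ["lineage", "position", "ref", "alt", "frequency",
               "read_count", "fr_balance", "type"]
    variants = pd.DataFrame(rows, columns=columns)
    ancestor = pd.DataFrame(anc_rows, columns=columns)

    # negative-binomial coverage with forced extremes so the 1% trim bites
    n_ref = len(ref_seq)
    coverage: dict[str, np.ndarray] = {}
    disp, mean = noise.coverage_dispersion, noise.mean_coverage
    p = disp / (disp + mean)
    for lin in lineages + ["ancestor"]:
        depth = rng.negative_binomial(disp, p, size=n_ref).astype(float)
        n_extreme = max(1, int(0.005 * n_ref))
        idx = rng.choice(n_ref, size=2 * n_extreme, replace=False)
        depth[idx[:n_extreme]] *= 16.0
        depth[idx[n_extreme:]] /= 16.0
        coverage[lin] = depth
    return variants, ancestor, coverage
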