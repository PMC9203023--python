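"""Selection and mutation-spectrum analyses.

SNVs are classified as synonymous, nonsynonymous, intergenic or
neutral-insert against a reference sequence with interval annotation.
Per-site substitution rates (dS, dN, dI) use Nei-Gojobori-style site
counting with no transition/transversion bias (all nine single-nucleotide
changes of a codon weighted equally); dN/dS and dI/dS ratios get percentile
bootstrap confidence intervals over mutation records and a one-sample
t-test of the per-lineage log10 ratios against 0 (ratio 1 = neutrality).
The spectrum summary tallies the 12 substitution types and the
transition/transversion ratio.  A one-sample Kolmogorov-Smirnov test
against the uniform distribution quantifies positional clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "RegionAnnotation",
    "SelectionRates",
    "SpectrumSummary",
    "classify_mutations",
    "ng86_site_counts",
    "selection_rates",
    "spectrum_summary",
    "ks_uniform_test",
]

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class RegionAnnotation:
    """Reference sequence plus labelled intervals.

    ``intervals`` is a list of ``(start, end, category, strand, frame)``
    with 1-based closed coordinates, category in
    {"CDS", "intergenic", "neutral-insert"}, strand "+" or "-", and frame
    the 0-based offset of the first complete codon.
    """

    reference: str
    intervals: tuple

    def __post_init__(self) -> None:
        n = len(self.reference)
        for start, end, category, strand, frame in self.intervals:
            if not 1 <= start <= end <= n:
                raise ValueError(f"interval ({start}, {end}) outside reference of length {n}")
            if category == "CDS" and (end - start + 1 - frame) % 3 != 0:
                raise ValueError(
                    f"CDS ({start}, {end}) length not divisible by 3 after frame {frame}"
                )

    def cds_codons(self, start: int, end: int, strand: str, frame: int) -> list[str]:
        """Codons of one CDS interval, on its coding strand."""
        seq = self.reference[start - 1 : end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        seq = seq[frame:]
        codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
        for k, codon in enumerate(codons[:-1]):
            if _translate(codon) == "*":
                raise ValueError(
                    f"internal stop codon {codon} at codon {k} of CDS ({start}, {end})"
                )
        return codons


@dataclass
class SelectionRates:
    rates: dict[str, float]
    ratios: dict[str, float | None]
    ci95: dict[str, tuple[float, float] | None]
    p_values: dict[str, float | None]
    counts: dict[str, int]
    sites: dict[str, float]


@dataclass
class SpectrumSummary:
    counts: pd.DataFrame
    n_transitions: int
    n_transversions: int
    ratio: float
    ci95: tuple[float, float] | None


_CODON_TABLE = standard_dna_table.forward_table


def _translate(codon: str) -> str:
    return _CODON_TABLE.get(codon, "*")


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each of the codon's 9 single-nucleotide changes is weighted equally;
    changes to stop codons count as nonsynonymous.
    """
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _translate(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def ng86_site_counts(annotation: RegionAnnotation) -> dict[str, float]:
    """Per-class site totals.

    CDS intervals contribute Nei-Gojobori synonymous/nonsynonymous site
    counts; intergenic and neutral-insert intervals contribute their
    lengths.
    """
    sites = {"synonymous": 0.0, "nonsynonymous": 0.0, "intergenic": 0.0, "neutral-insert": 0.0}
    for start, end, category, strand, frame in annotation.intervals:
        if category == "CDS":
            for codon in annotation.cds_codons(start, end, strand, frame):
                s, n = _codon_site_fractions(codon)
                sites["synonymous"] += s
                sites["nonsynonymous"] += n
        else:
            sites[category] += end - start + 1
    return sites


def _classify_one(position: int, alt: str, annotation: RegionAnnotation) -> str | None:
    for start, end, category, strand, frame in annotation.intervals:
        if not start <= position <= end:
            continue
        if category != "CDS":
            return category
        offset = position - start
        if strand == "-":
            offset = (end - start) - offset
            alt = str(Seq(alt).reverse_complement())
        offset -= frame
        if offset < 0:
            return "intergenic"  # upstream of the first complete codon
        codon_idx, codon_pos = divmod(offset, 3)
        codons = annotation.cds_codons(start, end, strand, frame)
        if codon_idx >= len(codons):
            return "intergenic"
        codon = codons[codon_idx]
        mutant = codon[:codon_pos] + alt + codon[codon_pos + 1 :]
        return "synonymous" if _translate(mutant) == _translate(codon) else "nonsynonymous"
    return None


def classify_mutations(records: pd.DataFrame, annotation: RegionAnnotation) -> pd.DataFrame:
    """Add a ``mutation_class`` column to a table of SNVs.

    Positions inside a CDS are translated (strand- and frame-aware) to
    decide synonymous vs nonsynonymous; otherwise the interval category
    applies.  Positions covered by overlapping intervals take the first in
    annotation order (a warning is emitted).
    """
    classes = []
    for position, alt in zip(records["position"], records["alt"]):
        covering = [
            iv for iv in annotation.intervals if iv[0] <= position <= iv[1]
        ]
        if len(covering) > 1:
            warnings.warn(
                f"position {position} covered by {len(covering)} intervals; using the first",
                stacklevel=2,
            )
        label = _classify_one(int(position), str(alt), annotation)
        if label is None:
            raise ValueError(f"position {position} not covered by any annotation interval")
        classes.append(label)
    out = records.copy()
    out["mutation_class"] = classes
    return out


def _ratios_from_counts(counts: dict[str, float], sites: dict[str, float]):
    rates = {cls: counts.get(cls, 0) / sites[cls] if sites[cls] > 0 else np.nan for cls in sites}
    dS = rates["synonymous"]
    ratios: dict[str, float | None] = {}
    for name, num in (("dN/dS", "nonsynonymous"), ("dI/dS", "intergenic"),
                      ("dI_insert/dS", "neutral-insert")):
        ratios[name] = None if (not np.isfinite(dS) or dS == 0) else rates[num] / dS
    return rates, ratios


def selection_rates(
    classified: pd.DataFrame,
    sites: dict[str, float],
    n_boot: int = 1000,
    seed: int = 0,
) -> SelectionRates:
    """dN/dS and dI/dS point estimates, bootstrap CIs and t-tests.

    CIs are percentile bootstrap over mutation records; the t-test compares
    per-lineage log10 ratios against 0 and is flagged not-performable
    (``None``) whenever any lineage has a zero count in either class.
    """
    counts = classified["mutation_class"].value_counts().to_dict()
    rates, ratios = _ratios_from_counts(counts, sites)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1E]))
    ci95: dict[str, tuple[float, float] | None] = {}
    boot_vals = {name: [] for name in ratios}
    n = len(classified)
    if n:
        labels = classified["mutation_class"].to_numpy()
        for _ in range(n_boot):
            resampled = labels[rng.integers(0, n, size=n)]
            cls_counts = pd.Series(resampled).value_counts().to_dict()
            _, boot_ratios = _ratios_from_counts(cls_counts, sites)
            for name, val in boot_ratios.items():
                if val is not None:
                    boot_vals[name].append(val)
    for name, vals in boot_vals.items():
        if ratios[name] is None or len(vals) < max(2, n_boot // 2):
            ci95[name] = None
        else:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            ci95[name] = (float(lo), float(hi))

    p_values: dict[str, float | None] = {}
    numerator_of = {"dN/dS": "nonsynonymous", "dI/dS": "intergenic",
                    "dI_insert/dS": "neutral-insert"}
    for name, num_cls in numerator_of.items():
        per_lineage = []
        performable = ratios[name] is not None
        for _, grp in classified.groupby("lineage"):
            c = grp["mutation_class"].value_counts().to_dict()
            num = c.get(num_cls, 0) / sites[num_cls] if sites[num_cls] > 0 else 0.0
            den = c.get("synonymous", 0) / sites["synonymous"] if sites["synonymous"] > 0 else 0.0
            if num == 0 or den == 0:
                performable = False
                break
            per_lineage.append(np.log10(num / den))
        if performable and len(per_lineage) >= 2:
            p_values[name] = float(stats.ttest_1samp(per_lineage, 0.0).pvalue)
        else:
            p_values[name] = None

    return SelectionRates(
        rates=rates,
        ratios=ratios,
        ci95=ci95,
        p_values=p_values,
        counts={cls: int(counts.get(cls, 0)) for cls in sites},
        sites=sites,
    )


def spectrum_summary(records: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> SpectrumSummary:
    """Substitution-type table and transition/transversion ratio.

    A->G, G->A, C->T and T->C are transitions; the other eight types are
    transversions.  With zero transversions the ratio is flagged infinite
    and the CI suppressed.
    """
    refs = records["ref"].to_numpy()
    alts = records["alt"].to_numpy()
    table = pd.DataFrame(0, index=list(_BASES), columns=list(_BASES))
    for r, a in zip(refs, alts):
        table.loc[r, a] += 1
    is_ts = np.array([(r, a) in _TRANSITIONS for r, a in zip(refs, alts)])
    n_ts, n_tv = int(is_ts.sum()), int((~is_ts).sum())
    ratio = np.inf if n_tv == 0 else n_ts / n_tv
    ci = None
    if n_tv > 0 and len(records) > 0 and n_boot > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5BEC]))
        boots = []
        for _ in range(n_boot):
            rs = is_ts[rng.integers(0, len(is_ts), size=len(is_ts))]
            tv = len(rs) - rs.sum()
            if tv > 0:
                boots.append(rs.sum() / tv)
        if len(boots) >= 2:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return SpectrumSummary(
        counts=table, n_transitions=n_ts, n_transversions=n_tv, ratio=float(ratio), ci95=ci
    )


def ks_uniform_test(positions, region_start: int, region_end: int) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of positional uniformity within a region.

    Positions are rescaled to (0, 1) over the closed region and compared
    two-sided against the standard uniform distribution.
    """
    positions = np.asarray(positions, dtype=float)
    inside = positions[(positions >= region_start) & (positions <= region_end)]
    if inside.size < 2:
        raise ValueError("need at least 2 positions inside the region")
    span = region_end - region_start + 1
    scaled = (inside - region_start + 0.5) / span
    res = stats.kstest(scaled, "uniform")
    return float(res.statistic), float(res.pvalue)
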