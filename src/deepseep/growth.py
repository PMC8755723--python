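"""Codon-usage-bias prediction of minimal generation times.

Fast-growing prokaryotes show strong codon-usage bias in constitutively,
highly expressed genes (ribosomal proteins) relative to the rest of the gene
pool, because translational selection optimizes those genes for the tRNA
pool. The bias statistic here is the mean, over amino-acid families with at
least two synonymous codons observed in both gene sets, of half the L1
distance between the family's codon-frequency vectors — 0 when the ribosomal
genes use codons exactly like the background, 1 when the two usages are
disjoint.

The bias-to-generation-time map is a log-linear calibration
``ln(d_hours) = a - b * bias`` with defaults a = ln(40), b = ln(100), so a
fully unbiased genome maps to 40 h and a maximally biased one to 0.4 h,
spanning the range typical of environmental surveys. These constants are this
package's calibration, exposed in the API, not fitted values of any external
tool; downstream comparisons rely on the strictly monotone bias->time
relationship rather than on absolute hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .codons import FAMILIES, STANDARD_CODE, STOP_CODONS

DEFAULT_A = math.log(40.0)
DEFAULT_B = math.log(100.0)
DEFAULT_SD_LN = 0.25


@dataclass
class CodonUsageProfile:
    """Synonymous codon counts pooled over a gene set (59 informative codons)."""

    counts: dict[str, int]
    codon_count: int
    internal_stops: int = 0
    uniform_prior_families: tuple[str, ...] = ()

    def family_frequencies(self, aa: str) -> np.ndarray:
        codons = FAMILIES[aa]
        c = np.array([self.counts.get(cod, 0) for cod in codons], dtype=float)
        total = c.sum()
        if total == 0:
            return np.full(len(codons), 1.0 / len(codons))  # uniform prior
        return c / total

    def observed_families(self) -> set[str]:
        return {aa for aa in FAMILIES
                if any(self.counts.get(c, 0) for c in FAMILIES[aa])}


@dataclass(frozen=True)
class GrowthPrediction:
    genome_id: str | None
    bias: float
    min_generation_time: float       # hours
    sd: float                        # hours, delta-method from the ln-scale sd
    temperature_C: float | None = None

    def summary(self) -> str:
        t = ("" if self.temperature_C is None
             else f"\ntemperature        {self.temperature_C} C (recorded, no numeric effect)")
        return (f"Minimal generation time prediction\n{'-' * 40}\n"
                f"genome             {self.genome_id}\n"
                f"codon-usage bias   {self.bias:.4f}\n"
                f"min. gen. time     {self.min_generation_time:.3f} h "
                f"(sd {self.sd:.3f} h){t}")


def codon_usage(genes: Iterable[str]) -> CodonUsageProfile:
    """Pool synonymous codon counts over coding sequences.

    Each sequence is trimmed to a multiple of 3 from its start; ATG/TGG and
    the terminal stop carry no synonymous information and are skipped, while
    internal stop codons are counted and flagged (a frame-quality signal)
    but excluded from the profile.
    """
    counts: dict[str, int] = {}
    internal_stops = 0
    n_genes = 0
    total = 0
    for seq in genes:
        n_genes += 1
        s = seq.upper().replace("U", "T")
        n_codons = len(s) // 3
        for k in range(n_codons):
            codon = s[3 * k:3 * k + 3]
            aa = STANDARD_CODE.get(codon)
            if aa is None:
                continue  # ambiguous bases
            if codon in STOP_CODONS:
                if k < n_codons - 1:
                    internal_stops += 1
                continue
            if aa in ("M", "W"):
                continue
            counts[codon] = counts.get(codon, 0) + 1
            total += 1
    if n_genes == 0:
        raise ValueError("at least one gene is required")
    unobserved = tuple(sorted(
        aa for aa in FAMILIES if not any(counts.get(c, 0) for c in FAMILIES[aa])
    ))
    return CodonUsageProfile(counts=counts, codon_count=total,
                             internal_stops=internal_stops,
                             uniform_prior_families=unobserved)


def codon_bias(highly_expressed: CodonUsageProfile,
               background: CodonUsageProfile) -> float:
    """Mean family-wise half-L1 distance between two usage profiles, in [0, 1].

    Only amino-acid families with >= 2 synonymous codons that are observed in
    both profiles contribute; the statistic is symmetric in its arguments.
    """
    shared = (highly_expressed.observed_families()
              & background.observed_families())
    shared = {aa for aa in shared if len(FAMILIES[aa]) >= 2}
    if not shared:
        raise ValueError("no amino-acid family observed in both gene sets")
    dists = [0.5 * np.abs(highly_expressed.family_frequencies(aa)
                          - background.family_frequencies(aa)).sum()
             for aa in sorted(shared)]
    return float(np.mean(dists))


def genome_bias(genome) -> float:
    """Codon bias of a synthetic genome: ribosomal genes vs all other genes."""
    rib = genome.gene_sequences(ribosomal=True)
    rest = genome.gene_sequences(ribosomal=False)
    if not rib or not rest:
        raise ValueError("genome needs both ribosomal and non-ribosomal genes")
    return codon_bias(codon_usage(rib), codon_usage(rest))


def predict_min_generation_time(
    bias: float,
    calibration: tuple[float, float] = (DEFAULT_A, DEFAULT_B),
    temperature_C: float | None = None,
    sd_ln: float = DEFAULT_SD_LN,
    genome_id: str | None = None,
) -> GrowthPrediction:
    """Map a codon-usage bias to a minimal generation time in hours.

    ``ln(d) = a - b * bias``; the reported sd is the delta-method transform
    of the residual scale on the ln axis (sd_hours = d * sd_ln). Temperature
    is recorded as metadata with no numerical effect.
    """
    if not (0.0 <= bias <= 1.0):
        raise ValueError("bias must be in [0, 1]")
    a, b = calibration
    d_hours = math.exp(a - b * bias)
    return GrowthPrediction(genome_id=genome_id, bias=float(bias),
                            min_generation_time=d_hours,
                            sd=d_hours * sd_ln, temperature_C=temperature_C)


def compare_clades(group_a: Sequence[float], group_b: Sequence[float]):
    """Two-sided Mann-Whitney U comparison of two clades' generation times."""
    from .stats import group_tests
    return group_tests(group_a, group_b, kind="mann_whitney_u")
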