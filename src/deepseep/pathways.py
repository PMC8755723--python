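"""Relative abundance of chemolithoautotrophic pathways from key-enzyme hits.

Per sample, a pathway's abundance is the sum of library-size-normalized
coverages of the scaffolds carrying its selected key enzyme. Scaffold
coverages are normalized by the total base pairs sequenced in the library
(expressed per Gbp for readable magnitudes — any positive constant cancels in
the Z-scaled view). When several key enzymes diagnose one pathway, the enzyme
with the highest frequency of hits in that assembly is selected (ties broken
lexicographically); the alternative of summing over all of a pathway's
enzymes is available via ``sum_mode="all"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

HIT_COLUMNS = ("scaffold_id", "enzyme", "pathway", "sample_id", "coverage")


def normalize_abundance(scaffold_coverage: float, total_bp: float) -> float:
    """Coverage per Gbp sequenced: coverage / (total_bp / 1e9)."""
    if scaffold_coverage < 0:
        raise ValueError("scaffold_coverage must be >= 0")
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    return scaffold_coverage / (total_bp / 1e9)


def select_key_enzyme(hits: pd.DataFrame, frequency: str = "hits") -> str:
    """Pick the representative key enzyme for one pathway in one assembly.

    ``frequency="hits"`` (default) counts distinct scaffold hits per enzyme;
    ``frequency="coverage"`` ranks by summed coverage instead. Ties go to the
    lexicographically smallest enzyme name, deterministically.
    """
    if hits.empty:
        raise ValueError("at least one hit is required")
    if frequency == "hits":
        ranking = hits.groupby("enzyme")["scaffold_id"].nunique()
    elif frequency == "coverage":
        ranking = hits.groupby("enzyme")["coverage"].sum()
    else:
        raise ValueError("frequency must be 'hits' or 'coverage'")
    best = ranking.max()
    return sorted(ranking[ranking == best].index)[0]


@dataclass
class PathwayAbundanceMatrix:
    """Pathways x samples abundances with a Z-scaled view.

    ``raw`` holds normalized abundances; ``zscored`` standardizes each pathway
    row to mean 0 / sd 1 (sample sd, n-1); rows with zero variance are zeroed
    and listed in ``zero_variance_pathways``. ``chosen_enzyme`` records which
    key enzyme represented each pathway in each sample.
    """

    raw: pd.DataFrame
    chosen_enzyme: pd.DataFrame

    @property
    def zscored(self) -> pd.DataFrame:
        return zscore_rows(self.raw)[0]

    @property
    def zero_variance_pathways(self) -> list[str]:
        return zscore_rows(self.raw)[1]


def pathway_matrix(
    hits: pd.DataFrame,
    total_bp: Mapping[str, float] | pd.Series,
    enzyme_to_pathway: Mapping[str, str] | None = None,
    sum_mode: str = "selected",
    frequency: str = "hits",
) -> PathwayAbundanceMatrix:
    """Build the pathway x sample abundance matrix from per-scaffold hits.

    ``hits`` needs columns scaffold_id, enzyme, pathway, sample_id, coverage
    (one row per enzyme hit on a scaffold in a sample). ``total_bp`` maps
    sample_id to sequenced bases. With ``sum_mode="selected"`` only the
    selected key enzyme's scaffolds are summed per pathway; with ``"all"``
    every key enzyme of the pathway contributes. Samples appearing in
    ``total_bp`` but without hits yield all-zero columns.
    """
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns: {missing}")
    if sum_mode not in ("selected", "all"):
        raise ValueError("sum_mode must be 'selected' or 'all'")
    total_bp = pd.Series(dict(total_bp), dtype=float)

    if enzyme_to_pathway is not None:
        known = hits["pathway"].isin(set(enzyme_to_pathway.values()))
        if not known.all():
            bad = sorted(hits.loc[~known, "pathway"].unique())
            raise ValueError(f"unknown pathway labels: {bad}")
        mismatch = hits["enzyme"].map(enzyme_to_pathway) != hits["pathway"]
        if mismatch.any():
            bad = sorted(hits.loc[mismatch, "enzyme"].unique())
            raise ValueError(f"enzymes mapped to conflicting pathways: {bad}")
    else:
        # the enzyme->pathway map must be many-to-one within the run
        amb = hits.groupby("enzyme")["pathway"].nunique()
        if (amb > 1).any():
            raise ValueError(
                f"enzymes mapped to conflicting pathways: {sorted(amb[amb > 1].index)}")

    unknown_samples = sorted(set(hits["sample_id"]) - set(total_bp.index))
    if unknown_samples:
        raise ValueError(f"samples without total_bp: {unknown_samples}")

    pathways = sorted(hits["pathway"].unique())
    samples = sorted(total_bp.index)
    raw = pd.DataFrame(0.0, index=pathways, columns=samples)
    chosen_rows = []
    for (sample, pathway), grp in hits.groupby(["sample_id", "pathway"]):
        enzyme = select_key_enzyme(grp, frequency=frequency)
        sel = grp if sum_mode == "all" else grp[grp["enzyme"] == enzyme]
        abundance = sum(
            normalize_abundance(c, total_bp[sample]) for c in sel["coverage"]
        )
        raw.loc[pathway, sample] = abundance
        chosen_rows.append({"sample_id": sample, "pathway": pathway,
                            "chosen_enzyme": enzyme})
    return PathwayAbundanceMatrix(raw=raw, chosen_enzyme=pd.DataFrame(chosen_rows))


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each row to mean 0 / sample sd 1 (ddof=1).

    Zero-variance rows become all-zero and are returned in the flag list.
    Requires at least two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scaling needs at least 2 samples")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    flat = sds <= 0
    safe_sd = sds.where(~flat, 1.0)
    z = matrix.sub(means, axis=0).div(safe_sd, axis=0)
    z.loc[flat] = 0.0
    return z, sorted(matrix.index[flat])


def rps3_diversity(abundances) -> float:
    """Shannon-Wiener index H = -sum(p ln p) over rpS3-scaffold abundances."""
    a = np.asarray(list(abundances), dtype=float)
    if a.size == 0 or np.any(a < 0):
        raise ValueError("abundances must be non-negative and non-empty")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundances sum to zero")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())
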