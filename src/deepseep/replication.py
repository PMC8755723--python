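"""In situ replication index (iRep/PTR-style) estimation from coverage trends.

Actively replicating bacterial populations carry replication forks that start
at the origin and proceed toward the terminus, so sequencing coverage decays
from ori to ter. The index of replication estimates the ori/ter coverage
ratio — 1.0 means no active forks, 2.0 means on average one full extra fork —
from the sorted distribution of log2 window coverages, so neither the origin
position nor scaffold order needs to be known.

The estimator refuses genomes flagged as archaeal: archaea can initiate
replication from multiple origins, which distorts the ori→ter coverage trend
and makes the index non-comparable across genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps


class ArchaealGenomeError(ValueError):
    """Raised when the estimator is applied to an archaeal genome unforced."""


@dataclass
class CoverageProfile:
    """Per-position read depth along one genome or scaffold."""

    genome_id: str
    depth: np.ndarray
    domain: str = "Bacteria"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    @property
    def length(self) -> int:
        return self.depth.size

    def mean(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class ReplicationEstimate:
    """Fitted replication index with OLS diagnostics and a QC verdict.

    ``status`` is "ok" for a successful fit and "no-coverage" when the profile
    had no mapped reads at all; in the latter case ``irep`` is None (never
    silently 1.0).
    """

    genome_id: str | None
    irep: float | None
    r_squared: float | None
    n_windows: int
    windows_retained_fraction: float
    qc_pass: bool
    mismatch_tolerance: float = 0.02
    status: str = "ok"
    slope: float | None = None
    sample_id: str | None = None

    def summary(self) -> str:
        lines = [
            "Replication index estimate",
            "-" * 40,
            f"genome            {self.genome_id}",
            f"status            {self.status}",
            f"iRep              {self.irep if self.irep is None else f'{self.irep:.4f}'}",
            f"r^2               {self.r_squared if self.r_squared is None else f'{self.r_squared:.4f}'}",
            f"windows (total)   {self.n_windows}",
            f"retained fraction {self.windows_retained_fraction:.3f}",
            f"QC pass           {self.qc_pass}",
            f"mismatch tol.     {self.mismatch_tolerance:.0%} (input provenance)",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class FractionReplicating:
    percent: float
    sub_unity: bool = False

    def __float__(self) -> float:  # allow use in arithmetic/formatting
        return self.percent


def window_coverage(
    profile: CoverageProfile | np.ndarray | Sequence[float],
    window_bp: int,
    slide_bp: int | None = None,
    circular: bool = True,
) -> np.ndarray:
    """Mean depth in sliding windows along the profile.

    Windows start every ``slide_bp`` from position 0; on a circular genome the
    final windows wrap around the origin, on a linear scaffold any partial
    tail window is dropped.
    """
    depth = profile.depth if isinstance(profile, CoverageProfile) else np.asarray(profile, dtype=float)
    length = depth.size
    if slide_bp is None:
        slide_bp = window_bp
    if window_bp <= 0 or slide_bp <= 0:
        raise ValueError("window_bp and slide_bp must be positive")
    if window_bp > length:
        raise ValueError(f"window_bp={window_bp} exceeds profile length {length}")
    if slide_bp > window_bp:
        raise ValueError("slide_bp must not exceed window_bp")

    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([depth, depth]))])
    starts = np.arange(0, length, slide_bp)
    if not circular:
        starts = starts[starts + window_bp <= length]
    ends = starts + window_bp
    return (csum[ends] - csum[starts]) / window_bp


def estimate_irep(
    windows: Iterable[float],
    trim_fraction: float = 0.05,
    min_r2: float = 0.90,
    min_retained: float = 0.75,
    min_windows: int = 20,
    genome_id: str | None = None,
    sample_id: str | None = None,
    mismatch_tolerance: float = 0.02,
) -> ReplicationEstimate:
    """Fit the replication index from window coverage means.

    Window means are sorted ascending; zero-coverage windows are excluded
    before the log transform (they count against retention), the extreme
    ``trim_fraction`` of windows is discarded from each tail, and log2 mean
    coverage is regressed by OLS on the rank fraction in [0, 1]. The rank
    fraction uses the midpoint plotting position (i + 0.5)/n — the expected
    uniform quantile of the i-th of n order statistics — and is assigned over
    the full sorted set *before* trimming, so neither trimming nor the finite
    window count shrinks the fitted slope. The index is 2**slope.
    """
    w = np.asarray(list(windows), dtype=float)
    n_total = w.size
    if n_total == 0 or not np.all(np.isfinite(w)):
        raise ValueError("windows must be a non-empty finite sequence")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")

    nonzero = w[w > 0]
    if nonzero.size == 0:
        return ReplicationEstimate(
            genome_id=genome_id, irep=None, r_squared=None, n_windows=n_total,
            windows_retained_fraction=0.0, qc_pass=False, status="no-coverage",
            mismatch_tolerance=mismatch_tolerance, sample_id=sample_id,
        )

    srt = np.sort(nonzero)
    n = srt.size
    # midpoint plotting positions over the full (untrimmed) sorted set
    x = (np.arange(n, dtype=float) + 0.5) / n
    k = int(math.floor(trim_fraction * n))
    sl = slice(k, n - k) if k > 0 else slice(None)
    x_fit, y_vals = x[sl], srt[sl]
    if y_vals.size < min_windows:
        raise ValueError(
            f"only {y_vals.size} usable windows after trimming; need >= {min_windows}"
        )
    y_fit = np.log2(y_vals)

    if np.ptp(y_fit) < 1e-12 or np.ptp(x_fit) < 1e-12:
        # perfectly flat profile: zero slope; r^2 reported as 1.0 by convention
        slope, r2 = 0.0, 1.0
    else:
        res = _sps.linregress(x_fit, y_fit)
        slope, r2 = float(res.slope), float(res.rvalue) ** 2

    retained = y_vals.size / n_total
    return ReplicationEstimate(
        genome_id=genome_id,
        irep=float(2.0 ** slope),
        r_squared=r2,
        n_windows=n_total,
        windows_retained_fraction=retained,
        qc_pass=bool(r2 >= min_r2 and retained >= min_retained),
        mismatch_tolerance=mismatch_tolerance,
        slope=slope,
        sample_id=sample_id,
    )


class ReplicationIndexModel:
    """Replication-index model for one genome bin in one sample.

    Parameters
    ----------
    coverage
        A single :class:`CoverageProfile` (treated as a closed circular
        genome) or a list of profiles (scaffolds of one bin; windows are
        computed per scaffold, scaffolds shorter than one window are skipped,
        and all windows are pooled before sorting).
    window_bp, slide_bp
        Window geometry; the defaults (5 kb non-overlapping) are conventional
        for coverage-trend fitting and are exposed in the CLI/config.
    trim_fraction, min_r2, min_retained
        Tail trim per side and the QC floors on the OLS fit.
    """

    def __init__(
        self,
        coverage: CoverageProfile | Sequence[CoverageProfile],
        window_bp: int = 5000,
        slide_bp: int | None = None,
        trim_fraction: float = 0.05,
        min_r2: float = 0.90,
        min_retained: float = 0.75,
        min_windows: int = 20,
        mismatch_tolerance: float = 0.02,
        sample_id: str | None = None,
    ) -> None:
        self.profiles = [coverage] if isinstance(coverage, CoverageProfile) else list(coverage)
        if not self.profiles:
            raise ValueError("at least one coverage profile is required")
        self.window_bp = window_bp
        self.slide_bp = window_bp if slide_bp is None else slide_bp
        self.trim_fraction = trim_fraction
        self.min_r2 = min_r2
        self.min_retained = min_retained
        self.min_windows = min_windows
        self.mismatch_tolerance = mismatch_tolerance
        self.sample_id = sample_id

    def fit(self, force: bool = False) -> ReplicationEstimate:
        domains = {p.domain for p in self.profiles}
        if any(d.lower().startswith("archaea") for d in domains) and not force:
            raise ArchaealGenomeError(
                "archaeal genomes can replicate from multiple origins; the "
                "ori->ter coverage-trend index is not comparable for them "
                "(pass force=True to override)"
            )
        single = len(self.profiles) == 1
        pooled: list[np.ndarray] = []
        for p in self.profiles:
            if p.length < self.window_bp:
                if single:
                    raise ValueError("window larger than genome")
                continue  # short scaffold skipped
            pooled.append(
                window_coverage(p, self.window_bp, self.slide_bp, circular=single)
            )
        if not pooled:
            raise ValueError("no scaffold is long enough for one window")
        return estimate_irep(
            np.concatenate(pooled),
            trim_fraction=self.trim_fraction,
            min_r2=self.min_r2,
            min_retained=self.min_retained,
            min_windows=self.min_windows,
            genome_id=self.profiles[0].genome_id,
            sample_id=self.sample_id,
            mismatch_tolerance=self.mismatch_tolerance,
        )


def average_irep(estimates: Iterable[ReplicationEstimate]) -> float | None:
    """Mean index over QC-passing estimates of one genome across samples.

    Estimates failing QC (or with no coverage) are excluded; if none pass,
    None is returned and propagated rather than a fabricated value.
    """
    vals = [e.irep for e in estimates if e.qc_pass and e.irep is not None]
    return float(np.mean(vals)) if vals else None


def fraction_replicating(irep: float) -> FractionReplicating:
    """Interpret a replication index as the percent of the population
    carrying an active replication fork: (irep - 1) x 100.

    Indices below 1 (possible under noise) are reported as 0% with the
    ``sub_unity`` flag set rather than as a negative percentage.
    """
    if not np.isfinite(irep):
        raise ValueError("irep must be finite")
    if irep < 1.0:
        return FractionReplicating(0.0, sub_unity=True)
    return FractionReplicating((irep - 1.0) * 100.0)
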