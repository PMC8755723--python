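"""Seeded synthetic communities with known ground truth.

Everything downstream (replication-index estimation, codon-bias growth
prediction, scaffold taxonomy, pathway abundance, biogeography) is exercised
against data produced here, where the generative parameters — the true
ori/ter coverage ratio, the injected codon-bias strength, the per-protein
lineages, the ANI decay per km — are known exactly.

The model choices the generators encode:

* circular genomes with the replication origin fixed at position 0 and the
  terminus at L/2; expected coverage decays piecewise-exponentially
  (log-linearly) with circular distance from the origin, which is exactly the
  replication-fork model the coverage-trend estimator assumes;
* counting noise is Poisson (reads as counts); no GC bias is simulated;
* codon bias is injected by sampling ribosomal-gene codons from a mixture
  (1 - s) * background + s * optimized, where the optimized table prefers one
  fixed codon per amino-acid family and s is the bias strength in [0, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import FAMILIES, OPTIMIZED_CODON
from .replication import CoverageProfile

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_LINEAGE = (
    "Bacteria", "Synthetobacterota", "Synthetia", "Synthetales",
    "Synthetaceae", "Synthetobacter", "Synthetobacter fictus",
)

ALTIARCHAEAL_LINEAGE = (
    "Archaea", "Altiarchaeota", "Altiarchaeia", "Altiarchaeales",
    "Altiarchaeaceae", "Ca. Altiarchaeum", "Ca. Altiarchaeum fictum",
)

#: toy key-enzyme -> chemolithoautotrophic pathway map used by the panels
ENZYME_PATHWAYS: dict[str, str] = {
    "acsB": "Wood-Ljungdahl",
    "cdhA": "Wood-Ljungdahl",
    "coxL": "CO oxidation",
    "cooS": "CO oxidation",
    "rbcL": "Calvin-Benson-Bassham",
    "hydA": "Hydrogen oxidation",
    "hybC": "Hydrogen oxidation",
    "soxB": "Sulfur oxidation",
    "dsrA": "Sulfate reduction",
    "amoA": "Ammonia oxidation",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"parameter '{name}': {message}")


@dataclass
class GeneModel:
    """A protein-coding gene on a synthetic genome (0-based, half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    is_ribosomal: bool = False
    protein_lineage: tuple[str, ...] | None = None
    enzyme_label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SyntheticGenome:
    genome_id: str
    sequence: str
    ori_position: int
    ter_position: int
    genes: list[GeneModel] = field(default_factory=list)
    true_ptr: float = 1.0
    true_bias: float = 0.0
    lineage: tuple[str, ...] = DEFAULT_LINEAGE
    length: int | None = None
    background_usage: dict[str, np.ndarray] | None = None
    ribosomal_usage: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.length is None:
            self.length = len(self.sequence)
        if self.sequence and self.length != len(self.sequence):
            raise ValueError("length inconsistent with sequence")
        if self.true_ptr < 1.0:
            raise ValueError("true_ptr must be >= 1")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"gene {g.gene_id} extends past genome end")

    def coding_sequence(self, gene: GeneModel) -> str:
        cds = self.sequence[gene.start:gene.end]
        return _revcomp(cds) if gene.strand == "-" else cds

    def gene_sequences(self, ribosomal: bool | None = None) -> list[str]:
        """Coding sequences, optionally restricted to (non-)ribosomal genes."""
        genes = self.genes
        if ribosomal is not None:
            genes = [g for g in genes if g.is_ribosomal == ribosomal]
        return [self.coding_sequence(g) for g in genes]


@dataclass
class SitePanel:
    """One ecosystem: genomes, coverage, annotations, metadata."""

    site_id: str
    depth_m: float
    latitude: float
    longitude: float
    sample_type: str
    oxygen: str
    high_co2: bool
    genomes: list[SyntheticGenome]
    coverage: dict[str, CoverageProfile]
    enzyme_hits: pd.DataFrame
    total_bp: float

    def __post_init__(self) -> None:
        _require(self.depth_m >= 0, "depth_m", "must be >= 0")
        _require(-90 <= self.latitude <= 90, "latitude", "must be in [-90, 90]")
        _require(-180 <= self.longitude <= 180, "longitude", "must be in [-180, 180]")
        _require(self.total_bp > 0, "total_bp", "must be > 0")


@dataclass
class BiogeoPanel:
    genomes: list[SyntheticGenome]
    coordinates: pd.DataFrame           # site_id, latitude, longitude
    true_ani: pd.DataFrame              # exact linear-law ground truth (%)
    expected_ani: pd.DataFrame          # realizable expectation from the fitted loads (%)
    substitutions: dict[str, int]       # per-genome substitution count vs ancestor
    ancestor: str


def _family_tables(rng: np.random.Generator, bias_strength: float):
    """Background (Dirichlet) and ribosomal (mixture) per-family codon tables."""
    background: dict[str, np.ndarray] = {}
    ribosomal: dict[str, np.ndarray] = {}
    for aa, codons in sorted(FAMILIES.items()):
        bg = rng.dirichlet(np.full(len(codons), 5.0))
        opt = np.array([1.0 if c == OPTIMIZED_CODON[aa] else 0.0 for c in codons])
        background[aa] = bg
        ribosomal[aa] = (1.0 - bias_strength) * bg + bias_strength * opt
    return background, ribosomal


def _sample_cds(rng: np.random.Generator, n_codons: int,
                tables: dict[str, np.ndarray]) -> str:
    aas = sorted(FAMILIES)
    idx = rng.integers(0, len(aas), size=n_codons)
    codons = ["ATG"]
    for i in idx:
        aa = aas[i]
        fam = FAMILIES[aa]
        codons.append(fam[rng.choice(len(fam), p=tables[aa])])
    codons.append("TAA")
    return "".join(codons)


def generate_genome(
    seed: int,
    length: int = 100_000,
    gc: float = 0.5,
    n_genes: int = 40,
    ribosomal_count: int = 8,
    bias_strength: float = 0.0,
    true_ptr: float = 1.0,
    lineage: Sequence[str] = DEFAULT_LINEAGE,
    genome_id: str | None = None,
    mean_gene_codons: int = 300,
) -> SyntheticGenome:
    """Generate one circular genome with genes and injected codon bias.

    Ribosomal genes sample their synonymous codons from the mixture
    ``(1 - bias_strength) * background + bias_strength * optimized``; all
    other genes sample from the background table. Byte-identical output for a
    fixed seed.
    """
    for name, val in (("length", length), ("gc", gc), ("n_genes", n_genes),
                      ("ribosomal_count", ribosomal_count),
                      ("bias_strength", bias_strength), ("true_ptr", true_ptr)):
        _require(np.isfinite(val), name, "must be finite")
    _require(length >= 50_000, "length", "must be >= 50,000 bp")
    _require(0 < gc < 1, "gc", "must be in (0, 1)")
    _require(ribosomal_count >= 1, "ribosomal_count", "must be >= 1")
    _require(n_genes >= ribosomal_count, "n_genes", "must be >= ribosomal_count")
    _require(0 <= bias_strength <= 1, "bias_strength", "must be in [0, 1]")
    _require(true_ptr >= 1, "true_ptr", "must be >= 1")

    rng = np.random.default_rng(seed)
    gid = genome_id or f"synthg_{seed}"
    background, ribosomal = _family_tables(rng, bias_strength)

    lengths = rng.integers(mean_gene_codons - 100, mean_gene_codons + 101, size=n_genes)
    coding_bp = int(np.sum(3 * (lengths + 2)))
    slack = length - coding_bp
    _require(slack >= n_genes + 1, "n_genes",
             f"genes need {coding_bp} bp but genome is {length} bp")
    gaps = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    rib_idx = set(rng.choice(n_genes, size=ribosomal_count, replace=False).tolist())
    strands = rng.choice(list("+-"), size=n_genes)

    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n_genes):
        gap = int(gaps[i])
        if gap:
            parts.append("".join(bases[rng.choice(4, size=gap, p=base_p)]))
            pos += gap
        is_rib = i in rib_idx
        cds = _sample_cds(rng, int(lengths[i]), ribosomal if is_rib else background)
        parts.append(_revcomp(cds) if strands[i] == "-" else cds)
        genes.append(GeneModel(
            gene_id=f"{gid}_g{i + 1:04d}",
            start=pos, end=pos + len(cds), strand=str(strands[i]),
            is_ribosomal=is_rib, protein_lineage=tuple(lineage),
        ))
        pos += len(cds)
    tail = int(gaps[n_genes])
    if tail:
        parts.append("".join(bases[rng.choice(4, size=tail, p=base_p)]))

    sequence = "".join(parts)
    assert len(sequence) == length
    return SyntheticGenome(
        genome_id=gid, sequence=sequence, ori_position=0,
        ter_position=length // 2, genes=genes, true_ptr=float(true_ptr),
        true_bias=float(bias_strength), lineage=tuple(lineage),
        background_usage=background, ribosomal_usage=ribosomal,
    )


def simulate_coverage(
    genome: SyntheticGenome | int,
    mean_depth: float,
    true_ptr: float | None = None,
    seed: int | None = None,
    noise: str = "poisson",
) -> CoverageProfile:
    """Simulate per-position depth with an ori->ter exponential gradient.

    The expected depth at circular distance d from the origin (d in [0, L/2],
    measured along either arm) is c0 * ptr**(1 - 2d/L); the profile is
    rescaled so its mean equals ``mean_depth`` exactly, which preserves the
    ori/ter ratio. ``noise="none"`` returns the expectation itself;
    ``noise="poisson"`` draws per-position counts.
    """
    if isinstance(genome, SyntheticGenome):
        length = genome.length
        gid = genome.genome_id
        ptr = genome.true_ptr if true_ptr is None else true_ptr
        domain = genome.lineage[0] if genome.lineage else "Bacteria"
    else:
        length = int(genome)
        gid = f"sim_{length}"
        ptr = 1.0 if true_ptr is None else true_ptr
        domain = "Bacteria"
    _require(mean_depth > 0, "mean_depth", "must be > 0")
    _require(ptr >= 1, "true_ptr", "must be >= 1")
    _require(noise in ("poisson", "none"), "noise", "must be 'poisson' or 'none'")

    pos = np.arange(length)
    d = np.minimum(pos, length - pos)            # circular distance from ori at 0
    u = 1.0 - 2.0 * d / length                   # 1 at ori, 0 at ter
    shape = ptr ** u
    expected = mean_depth * shape / shape.mean()
    if noise == "none":
        depth = expected
    else:
        rng = np.random.default_rng(seed)
        depth = rng.poisson(expected).astype(float)
    return CoverageProfile(genome_id=gid, depth=depth, domain=domain)


def generate_site_panel(
    seed: int,
    n_sites: int = 12,
    depth_range: tuple[float, float] = (0.0, 3000.0),
    irep_slope: float = -1.3e-4,
    irep_noise_sd: float = 0.1,
    high_co2_offset: float = 0.3,
    n_high_co2: int = 2,
    base_irep: float = 1.5,
    genomes_per_site: int = 4,
    genome_length: int = 120_000,
    mean_depth: float = 50.0,
    noise: str = "poisson",
    with_sequences: bool = False,
) -> list[SitePanel]:
    """Generate a multi-site community panel with a depth-dependent
    replication effect.

    Each genome's true ori/ter ratio is
    ``base_irep + irep_slope * depth + high_co2_offset * [high-CO2 site]
    + N(0, irep_noise_sd)``, floored at 1.0. Sites span ``depth_range``
    evenly; ``n_high_co2`` sites are flagged as CO2-impacted at random
    (independently of depth). With ``with_sequences=False`` (default) the
    genomes carry only ids/lengths/ground truth, which is all the
    replication and statistics layers consume.
    """
    _require(n_sites >= 3, "n_sites", "must be >= 3")
    _require(irep_noise_sd >= 0, "irep_noise_sd", "must be >= 0")
    _require(0 <= n_high_co2 <= n_sites, "n_high_co2", "must be in [0, n_sites]")
    rng = np.random.default_rng(seed)

    depths = np.linspace(depth_range[0], depth_range[1], n_sites)
    co2_sites = set(rng.choice(n_sites, size=n_high_co2, replace=False).tolist())
    sample_types = rng.choice(["fluid", "sediment", "soil", "rock"], size=n_sites)
    oxy = rng.choice(["oxic", "anoxic"], size=n_sites, p=[0.25, 0.75])
    lats = rng.uniform(-60, 60, size=n_sites)
    lons = rng.uniform(-180, 180, size=n_sites)
    enzymes = sorted(ENZYME_PATHWAYS)

    panels: list[SitePanel] = []
    for s in range(n_sites):
        site_id = f"site{s + 1:02d}"
        high = s in co2_sites
        genomes: list[SyntheticGenome] = []
        coverage: dict[str, CoverageProfile] = {}
        hit_rows = []
        for g in range(genomes_per_site):
            ptr = (base_irep + irep_slope * depths[s]
                   + (high_co2_offset if high else 0.0)
                   + rng.normal(0.0, irep_noise_sd))
            ptr = max(1.0, float(ptr))
            gid = f"{site_id}_genome{g + 1}"
            if with_sequences:
                genome = generate_genome(
                    seed=int(rng.integers(2**31)), length=genome_length,
                    true_ptr=ptr, genome_id=gid,
                )
            else:
                genome = SyntheticGenome(
                    genome_id=gid, sequence="", ori_position=0,
                    ter_position=genome_length // 2, true_ptr=ptr,
                    length=genome_length,
                )
            genomes.append(genome)
            coverage[gid] = simulate_coverage(
                genome_length, mean_depth=mean_depth, true_ptr=ptr,
                seed=int(rng.integers(2**31)), noise=noise,
            )
            coverage[gid].genome_id = gid
            for enz in rng.choice(enzymes, size=int(rng.integers(1, 4)), replace=False):
                hit_rows.append({
                    "scaffold_id": f"{gid}_scf1", "enzyme": str(enz),
                    "pathway": ENZYME_PATHWAYS[str(enz)], "sample_id": site_id,
                    "coverage": float(rng.lognormal(np.log(mean_depth), 0.5)),
                    "score": float(rng.uniform(60, 400)),
                })
        panels.append(SitePanel(
            site_id=site_id, depth_m=float(depths[s]),
            latitude=float(lats[s]), longitude=float(lons[s]),
            sample_type=str(sample_types[s]), oxygen=str(oxy[s]),
            high_co2=high, genomes=genomes, coverage=coverage,
            enzyme_hits=pd.DataFrame(hit_rows),
            total_bp=float(rng.uniform(2e9, 8e9)),
        ))
    return panels


def panel_metadata(panels: Sequence[SitePanel]) -> pd.DataFrame:
    return pd.DataFrame([
        {"site_id": p.site_id, "depth_m": p.depth_m, "latitude": p.latitude,
         "longitude": p.longitude, "sample_type": p.sample_type,
         "oxygen": p.oxygen, "high_co2": p.high_co2, "total_bp": p.total_bp}
        for p in panels
    ])


def panel_truth(panels: Sequence[SitePanel]) -> pd.DataFrame:
    """Tidy per-genome ground-truth table (genome_id, site_id, depth, true_ptr)."""
    return pd.DataFrame([
        {"genome_id": g.genome_id, "site_id": p.site_id, "depth_m": p.depth_m,
         "high_co2": p.high_co2, "true_ptr": g.true_ptr}
        for p in panels for g in p.genomes
    ])


def generate_biogeo_panel(
    seed: int,
    n_genomes: int = 10,
    coordinates: pd.DataFrame | Sequence[tuple[float, float]] | None = None,
    ani_decay: float = 0.002,
    genome_length: int = 50_000,
) -> BiogeoPanel:
    """Genomes descended from one ancestor with distance-dependent divergence.

    The target pairwise identity is ``100 - ani_decay * distance_km``, clamped
    at 75%. Each genome i is mutated independently of the others at a fraction
    p_i of sites (substituted bases drawn uniformly from the three
    alternatives), so the expected pairwise divergence is
    ``p_i + p_j - (4/3) p_i p_j``: sites hit in both genomes agree again with
    probability 1/3. The
    per-genome loads p_i are fitted to the target matrix by bounded least
    squares — exact for a single pair, least-squares for general geometries
    where pairwise star-tree loads cannot reproduce an arbitrary distance
    matrix. Both the linear-law truth (``true_ani``) and the expectation
    realizable from the fitted loads (``expected_ani``) are returned.
    """
    from scipy.optimize import least_squares, nnls
    from .biogeo import GeoPoint, geodesic_distance

    _require(ani_decay >= 0, "ani_decay", "must be >= 0")
    _require(n_genomes >= 2, "n_genomes", "must be >= 2")
    rng = np.random.default_rng(seed)

    if coordinates is None:
        coords = pd.DataFrame({
            "site_id": [f"bg{i + 1:02d}" for i in range(n_genomes)],
            "latitude": rng.uniform(-55, 65, size=n_genomes),
            "longitude": rng.uniform(-180, 180, size=n_genomes),
        })
    elif isinstance(coordinates, pd.DataFrame):
        coords = coordinates.reset_index(drop=True).copy()
        n_genomes = len(coords)
    else:
        coords = pd.DataFrame(
            [{"site_id": f"bg{i + 1:02d}", "latitude": la, "longitude": lo}
             for i, (la, lo) in enumerate(coordinates)]
        )
        n_genomes = len(coords)
    pts = [GeoPoint(r.latitude, r.longitude) for r in coords.itertuples()]
    if len({(p.latitude, p.longitude) for p in pts}) != len(pts):
        raise ValueError("parameter 'coordinates': sites must be distinct")

    pairs = [(i, j) for i in range(n_genomes) for j in range(i + 1, n_genomes)]
    dist_km = np.array([geodesic_distance(pts[i], pts[j]) for i, j in pairs])
    target_div = np.minimum(ani_decay * dist_km, 25.0) / 100.0  # fraction

    def pair_div(p_i, p_j):
        # P(disagree) for independent uniform substitutions from one ancestor
        return p_i + p_j - (4.0 / 3.0) * p_i * p_j

    if pairs:
        # linear warm start ignoring the collision term, then the exact model
        A = np.zeros((len(pairs), n_genomes))
        for row, (i, j) in enumerate(pairs):
            A[row, i] = A[row, j] = 1.0
        warm, _ = nnls(A, target_div)
        fit = least_squares(
            lambda p: np.array([pair_div(p[i], p[j]) for i, j in pairs])
            - target_div,
            x0=np.clip(warm, 0.0, 0.4), bounds=(0.0, 0.4),
        )
        loads = fit.x
    else:
        loads = np.zeros(n_genomes)

    L = genome_length
    m = np.round(loads * L).astype(int)

    bases = np.array(list("ACGT"))
    ancestor = "".join(bases[rng.integers(0, 4, size=L)])

    gids = coords["site_id"].tolist()
    genomes: list[SyntheticGenome] = []
    subs: dict[str, int] = {}
    anc_arr = np.frombuffer(ancestor.encode(), dtype="S1")
    for i, gid in enumerate(gids):
        arr = anc_arr.copy()
        sites = rng.choice(L, size=int(m[i]), replace=False)
        for p in sites:
            old = arr[p].decode()
            choices = [b for b in "ACGT" if b != old]
            arr[p] = choices[rng.integers(0, 3)].encode()
        seq = arr.tobytes().decode()
        genomes.append(SyntheticGenome(
            genome_id=gid, sequence=seq, ori_position=0, ter_position=L // 2,
            lineage=ALTIARCHAEAL_LINEAGE,
        ))
        subs[gid] = int(m[i])

    true_ani = pd.DataFrame(np.full((n_genomes, n_genomes), 100.0),
                            index=gids, columns=gids)
    expected_ani = true_ani.copy()
    p_hat = m / L
    for (i, j), div in zip(pairs, target_div):
        true_ani.iloc[i, j] = true_ani.iloc[j, i] = 100.0 - 100.0 * div
        realized = 100.0 * (1.0 - pair_div(p_hat[i], p_hat[j]))
        expected_ani.iloc[i, j] = expected_ani.iloc[j, i] = realized

    return BiogeoPanel(genomes=genomes, coordinates=coords, true_ani=true_ani,
                       expected_ani=expected_ani, substitutions=subs,
                       ancestor=ancestor)


# ---------------------------------------------------------------------------
# plain-text writers (FASTA, samtools-depth TSV, metadata/annotation TSVs)

def write_fasta(genomes: Sequence[SyntheticGenome], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(g.sequence), id=g.genome_id, description="")
               for g in genomes]
    _write(records, str(path), "fasta")


def write_gene_fasta(genome: SyntheticGenome, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(genome.coding_sequence(g)), id=g.gene_id,
                         description=f"ribosomal={g.is_ribosomal}")
               for g in genome.genes]
    _write(records, str(path), "fasta")


def write_coverage_tsv(profile: CoverageProfile, path) -> None:
    """samtools-depth dialect: scaffold, 1-based position, depth; no header."""
    df = pd.DataFrame({
        "scaffold": profile.genome_id,
        "pos": np.arange(1, profile.length + 1),
        "depth": profile.depth,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def lineage_table(
    genomes: Sequence[SyntheticGenome],
    mislabel_fraction: float = 0.0,
    unannotated_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-protein ranked-lineage table (one scaffold per genome).

    Optionally mislabels a fraction of proteins with a decoy lineage and
    blanks another fraction, to emulate noisy real annotations.
    """
    rng = np.random.default_rng(seed)
    decoy = ("Bacteria", "Decoyphyla", "Decoyia", "Decoyales",
             "Decoyaceae", "Decoybacter", "Decoybacter falsus")
    rows = []
    for g in genomes:
        for gene in g.genes:
            lin = gene.protein_lineage or g.lineage
            u = rng.random()
            if u < unannotated_fraction:
                lin = (None,) * len(RANKS)
            elif u < unannotated_fraction + mislabel_fraction:
                lin = decoy
            rows.append({"protein_id": gene.gene_id,
                         "scaffold_id": f"{g.genome_id}_scf1",
                         **dict(zip(RANKS, lin))})
    return pd.DataFrame(rows)
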