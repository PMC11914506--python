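"""Synthetic multi-omics data with the structure the analysis assumes.

Generators for: a genome catalog (chromosomes, arms, genes); patient cohorts
whose tumor-minus-normal expression deltas correlate with a planted
aneuploidy score; cell-line proteomes with chromosome-dosage effects,
partial dosage compensation, batch offsets, replicate noise and planted
adaptation genes; luminescence growth curves; and noisy binned copy-number
profiles.  Every generator is deterministic for a seed and returns the
planted truth alongside the data, so each downstream stage can be checked
against a known answer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aadept import CohortOmics

ADAPTATION_PATTERNS = {
    # (weight at p0, weight at p50) applied to the planted shift in
    # polysomic lines.  "progressive": the initial response deepens during
    # evolution (rank-consistent across comparison groups, the pattern the
    # relevance score is built to reward); "emergent": no change at p0, the
    # shift appears only after evolution; "reversal": the p0 shift flips
    # sign by p50.
    "progressive": (1.0, 2.0),
    "emergent": (0.0, 1.0),
    "reversal": (1.0, -1.0),
}


@dataclass(frozen=True)
class GenomeCatalog:
    """Chromosome arm definitions plus a gene catalog.

    ``arms``: DataFrame (chromosome, arm, start, end), 0-based half-open;
    the two arms of a chromosome are disjoint and tile it.
    ``genes``: DataFrame (gene_id, chromosome, start, end, arm); every gene
    lies entirely within one arm.
    """

    arms: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self):
        arms = self.arms
        for (chrom,), grp in arms.groupby(["chromosome"], sort=False):
            grp = grp.sort_values("start")
            if (grp["start"] < 0).any() or (grp["start"] >= grp["end"]).any():
                raise ValueError(f"bad arm coordinates on {chrom}")
            if (grp["end"].to_numpy()[:-1] != grp["start"].to_numpy()[1:]).any():
                raise ValueError(f"arms of {chrom} do not tile the chromosome")
        merged = self.genes.merge(arms, on=["chromosome", "arm"],
                                  suffixes=("", "_arm"))
        if len(merged) != len(self.genes):
            raise ValueError("gene mapped to unknown arm")
        inside = ((merged["start"] >= merged["start_arm"])
                  & (merged["end"] <= merged["end_arm"]))
        if not inside.all():
            raise ValueError("gene not contained in its arm")

    @property
    def arm_index(self) -> list[tuple[str, str]]:
        return list(zip(self.arms["chromosome"], self.arms["arm"]))

    def arm_length(self, chromosome: str, arm: str) -> int:
        row = self.arms[(self.arms["chromosome"] == chromosome)
                        & (self.arms["arm"] == arm)].iloc[0]
        return int(row["end"] - row["start"])

    def genes_on_arm(self, chromosome: str, arm: str) -> pd.DataFrame:
        return self.genes[(self.genes["chromosome"] == chromosome)
                          & (self.genes["arm"] == arm)]


@dataclass(frozen=True)
class Karyotype:
    """Integer copy number per chromosome arm (diploid reference = 2)."""

    copy_numbers: dict = field(default_factory=dict)
    reference_cn: int = 2

    def __post_init__(self):
        if any(cn < 0 for cn in self.copy_numbers.values()):
            raise ValueError("copy numbers must be >= 0")

    def copy_number(self, chromosome: str, arm: str) -> int:
        return self.copy_numbers.get((chromosome, arm), self.reference_cn)

    def log2_ratio(self, chromosome: str, arm: str) -> float:
        cn = self.copy_number(chromosome, arm)
        with np.errstate(divide="ignore"):
            return float(np.log2(cn / self.reference_cn))

    def altered_arms(self) -> list[tuple[str, str]]:
        return [k for k, cn in self.copy_numbers.items()
                if cn != self.reference_cn]

    @classmethod
    def diploid(cls) -> "Karyotype":
        return cls()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters shared by the synthetic generators.

    effect_size is the delta change per aneuploidy-score unit for planted
    cohort genes (log2 units); noise_sd is the per-patient delta noise;
    compensation_factor c in [0, 1] scales dosage transmission to protein
    (expected fold change (1-c)*log2(dosage ratio)); adaptation_shift is the
    log2 intensity shift planted on adaptation genes in polysomic lines.
    Growth curves follow baseline + amplitude*(exp(rate*t)-1) with lognormal
    multiplicative measurement noise of the given CV.
    """

    seed: int = 0
    n_patients: int = 200
    effect_size: float = 0.2
    noise_sd: float = 1.0
    planted_gene_fraction: float = 0.05
    compensation_factor: float = 0.5
    batch_offsets: tuple = (0.0, 0.3, -0.2)
    replicate_sd: float = 0.1
    n_replicates: int = 3
    bin_size: int = 1_000_000
    adaptation_shift: float = 0.5
    adaptation_pattern: str = "progressive"
    growth_rate: float = 0.05
    growth_baseline: float = 1000.0
    growth_amplitude: float = 2000.0
    measurement_cv: float = 0.05

    def __post_init__(self):
        if self.noise_sd < 0 or self.replicate_sd < 0 or self.measurement_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 <= self.compensation_factor <= 1.0:
            raise ValueError("compensation_factor must lie in [0, 1]")
        if not 0.0 <= self.planted_gene_fraction <= 1.0:
            raise ValueError("planted_gene_fraction must lie in [0, 1]")
        if self.adaptation_pattern not in ADAPTATION_PATTERNS:
            raise ValueError(
                f"unknown adaptation_pattern {self.adaptation_pattern!r}")

    def rng(self, *tags) -> np.random.Generator:
        """Deterministic substream keyed by (seed, *tags)."""
        digest = [self.seed & 0x7FFFFFFF]
        for t in tags:
            h = hashlib.sha256(str(t).encode()).digest()
            digest.append(int.from_bytes(h[:4], "little") & 0x7FFFFFFF)
        return np.random.default_rng(np.random.SeedSequence(digest))


def make_genome(n_chromosomes: int, genes_per_arm: int,
                seed: int = 0) -> GenomeCatalog:
    """Random genome catalog: arms tiling each chromosome, sorted genes.

    Chromosome lengths are drawn between 60 and 240 Mb with the p arm taking
    30-50% of the chromosome; ``genes_per_arm`` genes of 20-200 kb are placed
    uniformly (sorted, possibly overlapping) within each arm.
    """
    if n_chromosomes < 1 or genes_per_arm < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    arm_rows, gene_rows = [], []
    for c in range(1, n_chromosomes + 1):
        chrom = str(c)
        length = int(rng.integers(60_000_000, 240_000_000))
        centromere = int(length * rng.uniform(0.3, 0.5))
        for arm, a0, a1 in (("p", 0, centromere), ("q", centromere, length)):
            arm_rows.append({"chromosome": chrom, "arm": arm,
                             "start": a0, "end": a1})
            widths = rng.integers(20_000, 200_000, size=genes_per_arm)
            max_start = (a1 - widths).clip(min=a0)
            starts = np.sort(rng.integers(a0, max_start + 1))
            for i, (s, w) in enumerate(zip(starts, widths)):
                e = min(int(s + w), a1)
                gene_rows.append({
                    "gene_id": f"G{c:02d}{arm}{i:04d}",
                    "chromosome": chrom,
                    "start": int(s), "end": int(e), "arm": arm,
                })
    return GenomeCatalog(arms=pd.DataFrame(arm_rows),
                         genes=pd.DataFrame(gene_rows))


def random_karyotype(catalog: GenomeCatalog, n_altered: int,
                     rng: np.random.Generator) -> Karyotype:
    """Karyotype with ``n_altered`` randomly chosen gained/lost arms."""
    arms = catalog.arm_index
    chosen = rng.choice(len(arms), size=n_altered, replace=False)
    cns = {}
    for idx in chosen:
        cns[arms[idx]] = int(rng.choice([1, 3, 4]))
    return Karyotype(copy_numbers=cns)


@dataclass
class SimulatedCohort:
    cohort: CohortOmics
    planted_genes: pd.Index
    karyotypes: dict


def simulate_cohort(catalog: GenomeCatalog,
                    config: SimulationConfig) -> SimulatedCohort:
    """Patient cohort whose planted genes track the aneuploidy score.

    Each patient receives a random karyotype; its aneuploidy score equals the
    number of altered arms.  A ``planted_gene_fraction`` subset of catalog
    genes gets delta = effect_size * AS + N(0, noise_sd); the rest are pure
    N(0, noise_sd) noise.
    """
    if config.n_patients < 3:
        raise ValueError("need at least 3 patients")
    rng = config.rng("cohort")
    genes = catalog.genes["gene_id"]
    n_genes = len(genes)
    n_arms = len(catalog.arm_index)
    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    karyotypes = {}
    as_values = np.empty(config.n_patients, dtype=int)
    for j, pat in enumerate(patients):
        k = int(rng.integers(0, n_arms + 1))
        karyotypes[pat] = random_karyotype(catalog, k, rng)
        as_values[j] = len(karyotypes[pat].altered_arms())
    n_planted = int(round(config.planted_gene_fraction * n_genes))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    planted = genes.iloc[np.sort(planted_idx)]
    deltas = rng.normal(0.0, config.noise_sd, size=(n_genes, config.n_patients))
    planted_mask = genes.isin(planted).to_numpy()
    deltas[planted_mask] += config.effect_size * as_values[None, :]
    cohort = CohortOmics(
        deltas=pd.DataFrame(deltas, index=pd.Index(genes, name="gene_id"),
                            columns=patients),
        aneuploidy_score=pd.Series(as_values, index=patients, dtype=int),
        ploidy=pd.Series(2.0, index=patients),
    )
    return SimulatedCohort(cohort=cohort, planted_genes=pd.Index(planted),
                           karyotypes=karyotypes)


def default_cellline_design(catalog: GenomeCatalog) -> tuple[dict, dict]:
    """A minimal evolution experiment: one parental line, two polysomic lines.

    Returns (karyotypes, parent_of): karyotypes maps (line, passage) to a
    Karyotype for passages 'p0' and 'p50'; polysomic lines carry a trisomy of
    the first chromosome's q arm or a tetrasomy of the second chromosome
    (both arms), constant across passages; the parental line stays diploid.
    """
    chroms = list(dict.fromkeys(catalog.arms["chromosome"]))
    tri = Karyotype(copy_numbers={(chroms[0], "q"): 3})
    tet_arms = {(chroms[min(1, len(chroms) - 1)], a): 4 for a in ("p", "q")}
    tet = Karyotype(copy_numbers=tet_arms)
    karyotypes = {}
    for passage in ("p0", "p50"):
        karyotypes[("WT", passage)] = Karyotype.diploid()
        karyotypes[("TRI", passage)] = tri
        karyotypes[("TET", passage)] = tet
    parent_of = {"WT": None, "TRI": "WT", "TET": "WT"}
    return karyotypes, parent_of


@dataclass
class SimulatedProteomes:
    """Log2 intensity matrix plus design, expected truth and planted genes."""

    intensities: pd.DataFrame          # proteins x samples (log2)
    sample_sheet: pd.DataFrame         # sample, line, passage, replicate, batch
    comparisons: pd.DataFrame          # name, line, passage vs ref, group
    expected_fc: pd.DataFrame          # proteins x comparisons (noise-free)
    adaptation_genes: pd.DataFrame     # gene_id, direction (+1/-1)


def simulate_cellline_proteomes(catalog: GenomeCatalog, karyotypes: dict,
                                config: SimulationConfig,
                                parent_of: dict | None = None
                                ) -> SimulatedProteomes:
    """Cell-line proteomes with dosage effects and planted adaptation genes.

    ``karyotypes`` maps (line, passage) -> Karyotype; ``parent_of`` maps each
    line to its parental reference (None for parental lines themselves).
    Genes on an arm with copy number cn get a dosage term
    (1 - c) * log2(cn/2); a planted subset of genes in polysomic lines
    additionally shifts by ±adaptation_shift, weighted per passage by the
    configured adaptation pattern.  One batch per replicate set (offsets from
    config.batch_offsets) and N(0, replicate_sd) noise are added.

    The comparison design has one row per fold-change contrast:
    group G1 = polysomic p0 vs parental p0, G2 = polysomic p50 vs its own p0,
    G3 = parental p50 vs parental p0.
    """
    if parent_of is None:
        _, parent_of = default_cellline_design(catalog)
    lines = sorted({ln for ln, _ in karyotypes})
    for line in lines:
        parent = parent_of.get(line, "missing")
        if parent == "missing" or (parent is not None and (parent, "p0") not in karyotypes):
            raise ValueError(f"line {line} lacks a parental reference")
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates per sample group")
    rng = config.rng("proteome")
    genes = catalog.genes.reset_index(drop=True)
    n_genes = len(genes)
    gene_ids = pd.Index(genes["gene_id"], name="gene_id")
    arm_keys = list(zip(genes["chromosome"], genes["arm"]))

    baseline = rng.normal(20.0, 2.0, size=n_genes)

    n_adapt = int(round(config.planted_gene_fraction * n_genes))
    adapt_idx = np.sort(rng.choice(n_genes, size=n_adapt, replace=False))
    directions = np.ones(n_adapt)
    directions[1::2] = -1.0           # sign-symmetric: half up, half down
    adapt_dir = np.zeros(n_genes)
    adapt_dir[adapt_idx] = directions
    w_p0, w_p50 = ADAPTATION_PATTERNS[config.adaptation_pattern]
    passage_weight = {"p0": w_p0, "p50": w_p50}

    c = config.compensation_factor

    def clean_signal(line: str, passage: str) -> np.ndarray:
        kt = karyotypes[(line, passage)]
        dosage = np.array([kt.log2_ratio(ch, a) for ch, a in arm_keys])
        signal = baseline + (1.0 - c) * dosage
        if parent_of.get(line) is not None:   # adaptation only in polysomic lines
            signal = signal + (adapt_dir * config.adaptation_shift
                               * passage_weight[passage])
        return signal

    sample_rows, columns, data = [], [], []
    n_batches = max(len(config.batch_offsets), 1)
    for (line, passage) in sorted(karyotypes):
        signal = clean_signal(line, passage)
        for rep in range(1, config.n_replicates + 1):
            batch = (rep - 1) % n_batches
            name = f"{line}_{passage}_r{rep}"
            noise = rng.normal(0.0, config.replicate_sd, size=n_genes)
            data.append(signal + config.batch_offsets[batch] + noise)
            columns.append(name)
            sample_rows.append({"sample": name, "line": line,
                                "passage": passage, "replicate": rep,
                                "batch": f"B{batch}"})
    intensities = pd.DataFrame(np.column_stack(data), index=gene_ids,
                               columns=columns)

    comp_rows, expected = [], {}
    for line in lines:
        parent = parent_of.get(line)
        if parent is None:
            if (line, "p50") in karyotypes:
                name = f"{line}_p50_vs_p0"
                comp_rows.append({"name": name, "group": "G3",
                                  "line_a": line, "passage_a": "p50",
                                  "line_b": line, "passage_b": "p0"})
                expected[name] = clean_signal(line, "p50") - clean_signal(line, "p0")
            continue
        name = f"{line}_p0_vs_{parent}"
        comp_rows.append({"name": name, "group": "G1",
                          "line_a": line, "passage_a": "p0",
                          "line_b": parent, "passage_b": "p0"})
        expected[name] = clean_signal(line, "p0") - clean_signal(parent, "p0")
        if (line, "p50") in karyotypes:
            name = f"{line}_p50_vs_p0"
            comp_rows.append({"name": name, "group": "G2",
                              "line_a": line, "passage_a": "p50",
                              "line_b": line, "passage_b": "p0"})
            expected[name] = clean_signal(line, "p50") - clean_signal(line, "p0")
    comparisons = pd.DataFrame(comp_rows)
    expected_fc = pd.DataFrame(expected, index=gene_ids)
    adaptation = pd.DataFrame({
        "gene_id": genes.loc[adapt_idx, "gene_id"].to_numpy(),
        "direction": directions,
    })
    return SimulatedProteomes(intensities=intensities,
                              sample_sheet=pd.DataFrame(sample_rows),
                              comparisons=comparisons,
                              expected_fc=expected_fc,
                              adaptation_genes=adaptation)


def simulate_growth_curves(config: SimulationConfig,
                           rate_by_line: dict | None = None,
                           timepoints=(0, 24, 48, 72, 96),
                           n_runs: int = 2,
                           amplitude_by_line: dict | None = None) -> pd.DataFrame:
    """Tidy luminescence table (sample, run, time_h, replicate, rlu).

    RLU(t) = baseline + amplitude * (exp(rate*t) - 1) * eps with eps
    lognormal of the configured coefficient of variation; triplicate wells
    (``config.n_replicates``) per timepoint; ``n_runs`` independent runs.
    ``amplitude_by_line`` scales a line's amplitude relative to
    ``config.growth_amplitude`` (with equal rates, the true AUC ratio of two
    lines equals their amplitude ratio).
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size < 2:
        raise ValueError("need at least 2 timepoints")
    if (timepoints < 0).any():
        raise ValueError("negative times are invalid")
    if rate_by_line is None:
        rate_by_line = {"WT_p0": config.growth_rate,
                        "TRI_p0": 0.7 * config.growth_rate,
                        "TRI_p50": config.growth_rate}
    cv = config.measurement_cv
    sigma = np.sqrt(np.log1p(cv ** 2))
    rows = []
    amplitude_by_line = amplitude_by_line or {}
    for line in sorted(rate_by_line):
        rng = config.rng("growth", line)
        rate = rate_by_line[line]
        amp = config.growth_amplitude * amplitude_by_line.get(line, 1.0)
        trend = amp * (np.exp(rate * timepoints) - 1.0)
        for run in range(1, n_runs + 1):
            for rep in range(1, config.n_replicates + 1):
                if sigma > 0:
                    eps = rng.lognormal(-0.5 * sigma ** 2, sigma,
                                        size=timepoints.size)
                else:
                    eps = np.ones(timepoints.size)
                rlu = config.growth_baseline + trend * eps
                for t, v in zip(timepoints, rlu):
                    rows.append({"sample": line, "run": f"run{run}",
                                 "time_h": t, "replicate": rep, "rlu": v})
    return pd.DataFrame(rows)


def true_auc(config: SimulationConfig, rate: float,
             timepoints=(0, 24, 48, 72, 96)) -> float:
    """Noise-free trapezoid AUC of the normalized growth trend."""
    t = np.asarray(timepoints, dtype=float)
    trend = config.growth_amplitude * (np.exp(rate * t) - 1.0)
    return float(np.trapezoid(trend - trend[0], t))


def simulate_binned_profile(karyotype: Karyotype, catalog: GenomeCatalog,
                            bin_size: int, noise_sd: float,
                            seed: int = 0) -> pd.DataFrame:
    """Binned log2 copy-number ratios: arm log2 ratio plus N(0, noise_sd).

    Bins tile each chromosome at ``bin_size``; a bin takes the log2 ratio of
    the arm containing its midpoint.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in catalog.arms.groupby("chromosome", sort=False):
        length = int(grp["end"].max())
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        mids = (starts + ends) // 2
        for s, e, m in zip(starts, ends, mids):
            arm_row = grp[(grp["start"] <= m) & (m < grp["end"])].iloc[0]
            ratio = karyotype.log2_ratio(chrom, arm_row["arm"])
            rows.append({"chromosome": chrom, "start": int(s), "end": int(e),
                         "log2_ratio": ratio})
    out = pd.DataFrame(rows)
    if noise_sd > 0:
        out["log2_ratio"] = out["log2_ratio"].to_numpy() + rng.normal(
            0.0, noise_sd, size=len(out))
    return out
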